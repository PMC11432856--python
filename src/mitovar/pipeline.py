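"""End-to-end orchestration of the analysis stages.

A single JSON configuration drives: simulation (or loading) of per-site
composition tables, consensus/SNP calling, Bray-Curtis UPGMA clustering,
PCA, neighbor-joining tree with bootstrap, CMS-gene screening of
contigs, and the coast x group association test.  A manifest records
seeds, output paths and headline counts so a run can be reproduced and
audited.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import cmsgenes, geostats, phylotree, popstruct, sitefilter, syndata

log = logging.getLogger("mitovar")


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seeds: dict[str, int]
    counts: dict[str, Any] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, default=str))


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]


def _validate(cfg: dict) -> None:
    if "outdir" not in cfg:
        raise ValueError("config must set 'outdir'")
    sim = cfg.get("simulate")
    if not sim:
        for key in ("reference", "tables_dir"):
            if key not in cfg:
                raise ValueError(
                    f"config must set '{key}' unless 'simulate' is given"
                )
            if key == "reference" and not Path(cfg[key]).exists():
                raise ValueError(f"reference path {cfg[key]!r} does not exist")
            if key == "tables_dir" and not Path(cfg[key]).is_dir():
                raise ValueError(f"tables_dir {cfg[key]!r} does not exist")


def run_pipeline(config: dict | str | Path) -> RunManifest:
    """Run every configured stage in dependency order.

    ``config`` is a dict or a path to a JSON file.  Stage failures halt
    the run with the failing stage named; outputs written so far are
    retained.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    _validate(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config_hash=_config_hash(config),
        version=__version__,
        seeds={"master": seed},
    )

    stage = "simulate"
    try:
        truth = None
        if config.get("simulate"):
            sim_kwargs = dict(config["simulate"])
            sim_kwargs.setdefault("rng_seed", seed)
            sim_cfg = syndata.SimConfig(**sim_kwargs)
            manifest.seeds["simulate"] = sim_cfg.rng_seed
            reference, haplotypes, truth = syndata.simulate_clades(sim_cfg)
            tables = syndata.make_site_tables(haplotypes, sim_cfg, reference)
            syndata.write_fasta({"mito_ref": reference}, outdir / "reference.fa")
            truth.to_json(outdir / "truth.json")
            manifest.outputs["reference"] = str(outdir / "reference.fa")
            manifest.outputs["truth"] = str(outdir / "truth.json")
        else:
            reference = next(iter(syndata.read_fasta(config["reference"]).values()))
            tables = [
                sitefilter.SiteTable.from_tsv(p)
                for p in sorted(Path(config["tables_dir"]).glob("*.tsv"))
            ]
        manifest.counts["n_accessions"] = len(tables)

        stage = "call"
        fcfg = sitefilter.FilterConfig(**config.get("filter", {}))
        cm = sitefilter.build_consensus_matrix(tables, fcfg)
        sm = sitefilter.extract_snp_sites(cm)
        manifest.counts["n_sites_retained"] = int(
            np.sum(np.all(cm.calls != sitefilter.MISSING_CODE, axis=0))
        )
        manifest.counts["n_snps"] = sm.n_sites
        sitefilter.write_snp_fasta(sm, outdir / "snps.fa")
        sitefilter.write_snp_vcf(sm, reference, outdir / "snps.vcf")
        density = sitefilter.window_snp_density(
            sm.positions, len(reference), fcfg.window_size
        )
        pd.DataFrame(
            {
                "window_start": np.arange(len(density)) * fcfg.window_size + 1,
                "n_snps": density,
            }
        ).to_csv(outdir / "snp_density.tsv", sep="\t", index=False)
        manifest.outputs["snp_fasta"] = str(outdir / "snps.fa")
        manifest.outputs["snp_vcf"] = str(outdir / "snps.vcf")

        stage = "cluster"
        ccfg = config.get("cluster", {})
        em = popstruct.encode(sm, reference)
        dm = popstruct.pairwise_bray_curtis(em)
        dg = popstruct.upgma(dm)
        k = int(ccfg.get("k", 4))
        labels = popstruct.cut_clusters(dg, k)
        dm.to_tsv(outdir / "distances.tsv")
        (outdir / "dendrogram.nwk").write_text(dg.to_newick() + "\n")
        pd.DataFrame({"accession": dm.ids, "cluster": labels}).to_csv(
            outdir / "clusters.tsv", sep="\t", index=False
        )
        manifest.counts["n_clusters"] = int(len(np.unique(labels)))
        manifest.outputs["dendrogram"] = str(outdir / "dendrogram.nwk")

        stage = "pca"
        pcfg = config.get("pca", {})
        pca_res = popstruct.pca(em, pcfg.get("n_components", 10))
        scores = pd.DataFrame(
            pca_res.scores,
            index=pca_res.accession_ids,
            columns=[f"PC{i+1}" for i in range(pca_res.scores.shape[1])],
        )
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        pd.DataFrame(
            {"component": scores.columns, "explained": pca_res.explained_ratio}
        ).to_csv(outdir / "pca_explained.tsv", sep="\t", index=False)

        stage = "tree"
        tcfg = config.get("tree", {})
        aln = phylotree.SnpAlignment(
            sm.accession_ids,
            list(sm.sequences().values()),
            tcfg.get("outgroup"),
        )
        n_reps = int(tcfg.get("bootstrap", 100))
        tree_seed = int(tcfg.get("seed", seed + 1))
        manifest.seeds["bootstrap"] = tree_seed
        tree = phylotree.bootstrap(
            aln, n_reps=n_reps, seed=tree_seed, model=tcfg.get("model", "JC69")
        )
        if aln.outgroup:
            tree = phylotree.root_with_outgroup(tree, aln.outgroup)
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        manifest.outputs["tree"] = str(outdir / "tree.nwk")
        if tree.supports:
            manifest.counts["min_bootstrap_support"] = min(tree.supports.values())

        stage = "cms"
        cms_cfg = config.get("cms")
        if cms_cfg and truth is not None and cms_cfg.get("simulate_carriers"):
            n_carriers = int(cms_cfg.get("n_carriers", 10))
            contig_len = int(cms_cfg.get("contig_length", 3000))
            rng = np.random.default_rng(seed + 2)
            query = cmsgenes.GeneQuery(
                "preSatp6_synthetic", syndata.random_contig(1161, seed + 3)
            )
            accs = sorted(truth.clade_of)
            contigs_by_acc: dict[str, dict[str, str]] = {}
            for i, acc in enumerate(accs):
                bg = syndata.random_contig(contig_len, seed + 10 + i)
                if i < n_carriers:
                    bg, ins = syndata.embed_gene(
                        bg, query.sequence, int(rng.integers(0, 4)), seed=seed + 50 + i
                    )
                    truth.cms_carriers[acc] = {
                        query.name: (ins.length, ins.mismatches)
                    }
                contigs_by_acc[acc] = {"contig1": bg}
            screen = cmsgenes.screen_cohort(contigs_by_acc, [query])
            screen.hits.to_csv(outdir / "cms_hits.tsv", sep="\t", index=False)
            truth.to_json(outdir / "truth.json")  # now includes carriers
            manifest.counts["cms_present"] = int(
                (screen.hits["label"] == "present").sum()
            )
            manifest.outputs["cms_hits"] = str(outdir / "cms_hits.tsv")
        elif cms_cfg and cms_cfg.get("contigs_dir"):
            queries = [
                cmsgenes.GeneQuery(name, seq)
                for name, seq in syndata.read_fasta(cms_cfg["queries"]).items()
            ]
            contigs_by_acc = {
                p.stem: syndata.read_fasta(p)
                for p in sorted(Path(cms_cfg["contigs_dir"]).glob("*.fa"))
            }
            screen = cmsgenes.screen_cohort(contigs_by_acc, queries)
            screen.hits.to_csv(outdir / "cms_hits.tsv", sep="\t", index=False)
            manifest.counts["cms_present"] = int(
                (screen.hits["label"] == "present").sum()
            )
            manifest.outputs["cms_hits"] = str(outdir / "cms_hits.tsv")

        stage = "geo"
        geo_cfg = config.get("geo")
        if geo_cfg:
            if geo_cfg.get("meta"):
                meta = pd.read_csv(geo_cfg["meta"], sep="\t")
                records = list(
                    zip(meta["accession"], meta["coast"], meta["clade"])
                )
                gm = None
            elif truth is not None:
                # simulated geography: coast biased by clade parity
                bias = float(geo_cfg.get("bias", 0.85))
                rng = np.random.default_rng(seed + 4)
                records = []
                gm = {}
                clade_ids = sorted(set(truth.clade_of.values()))
                for i, c in enumerate(clade_ids):
                    gm[c] = geostats.GROUP_A if i % 2 == 0 else geostats.GROUP_B
                for acc, clade in truth.clade_of.items():
                    home = (
                        "Mediterranean"
                        if gm[clade] == geostats.GROUP_A
                        else "Atlantic"
                    )
                    away = "Atlantic" if home == "Mediterranean" else "Mediterranean"
                    coast = home if rng.random() < bias else away
                    records.append((acc, coast, clade))
            else:
                raise ValueError("geo stage needs 'meta' or a simulated cohort")
            report = geostats.geographic_association(records, gm)
            (outdir / "geo_report.json").write_text(
                json.dumps(report.to_dict(), indent=1)
            )
            manifest.counts["fisher_p"] = report.p_value
            manifest.outputs["geo_report"] = str(outdir / "geo_report.json")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest.write(outdir / "manifest.json")
    manifest.outputs["manifest"] = str(outdir / "manifest.json")
    return manifest
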