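"""Synthetic cohorts with clade structure and organellar contamination.

The generator emulates the situation encountered when short reads from
whole plants are mapped onto a mitochondrial reference: most sites sit
in a mid-depth class that is genuinely mitochondrial (default mean 100),
plastid-homologous regions attract chloroplast reads at very high depth
(default mean 3000), and NUMT-only regions receive a trickle of
mis-mapped nuclear reads (default mean 5).  Haplotypes carry
clade-diagnostic SNPs plus optional accession-private SNPs under an
infinite-sites model, and contigs can receive embedded gene copies with
a controlled number of mismatches for testing presence/absence
classification rules.

Everything is a pure function of the configured seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np

from .sitefilter import BASES, BASE_INDEX, SiteTable

Interval = tuple[int, int]


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters for a synthetic cohort.

    Intervals are 0-based half-open on the reference and must be
    mutually disjoint.  Depth means must satisfy
    ``depth_numt < 20 < depth_mito < 900 < depth_plastid`` so the
    depth-window filter separates the three classes.
    """

    genome_length: int = 20_000
    n_accessions: int = 40
    n_clades: int = 4
    snps_per_clade: int = 50
    private_snp_rate: float = 1.0
    depth_mito: float = 100.0
    depth_plastid: float = 3000.0
    depth_numt: float = 5.0
    plastid_regions: tuple[Interval, ...] | None = None
    numt_regions: tuple[Interval, ...] | None = None
    heteroplasmy_rate: float = 0.01
    heteroplasmy_minor_freq: float = 0.25
    contamination_divergence: float = 0.05
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError("genome_length must be positive")
        # default contamination layout scales with the reference length:
        # two plastid-homologous blocks of 4% each, two NUMT blocks of ~2.5%
        L = self.genome_length
        if self.plastid_regions is None:
            object.__setattr__(
                self,
                "plastid_regions",
                ((int(0.10 * L), int(0.14 * L)), (int(0.60 * L), int(0.64 * L))),
            )
        if self.numt_regions is None:
            object.__setattr__(
                self,
                "numt_regions",
                ((int(0.25 * L), int(0.275 * L)), (int(0.80 * L), int(0.82 * L))),
            )
        object.__setattr__(
            self,
            "plastid_regions",
            tuple((int(lo), int(hi)) for lo, hi in self.plastid_regions),
        )
        object.__setattr__(
            self,
            "numt_regions",
            tuple((int(lo), int(hi)) for lo, hi in self.numt_regions),
        )
        if self.n_accessions < 1 or self.n_clades < 1:
            raise ValueError("need at least one accession and one clade")
        if self.n_clades > self.n_accessions:
            raise ValueError("more clades than accessions")
        if self.snps_per_clade < 0 or self.private_snp_rate < 0:
            raise ValueError("SNP rates must be non-negative")
        if not (self.depth_numt < 20 < self.depth_mito < 900 < self.depth_plastid):
            raise ValueError(
                "depth means must satisfy depth_numt < 20 < depth_mito"
                " < 900 < depth_plastid"
            )
        if not (0.0 < self.heteroplasmy_minor_freq < 0.5):
            raise ValueError("heteroplasmy_minor_freq must lie in (0, 0.5)")
        if not (0.0 <= self.heteroplasmy_rate <= 1.0):
            raise ValueError("heteroplasmy_rate must lie in [0, 1]")
        intervals = sorted(self.plastid_regions + self.numt_regions)
        for lo, hi in intervals:
            if not (0 <= lo < hi <= self.genome_length):
                raise ValueError(f"region ({lo}, {hi}) outside the reference")
        for (_, prev_hi), (lo, _) in zip(intervals, intervals[1:]):
            if lo < prev_hi:
                raise ValueError("contamination regions must be disjoint")

    def contaminated_mask(self) -> np.ndarray:
        mask = np.zeros(self.genome_length, dtype=bool)
        for lo, hi in self.plastid_regions + self.numt_regions:
            mask[lo:hi] = True
        return mask


@dataclass
class TruthSet:
    """Ground truth of a simulated cohort, for recovery tests.

    ``true_snp_positions`` are 1-based reference coordinates of all
    polymorphic sites (clade-diagnostic plus private); ``true_tree`` is a
    Newick string with one polytomy per clade.
    """

    clade_of: dict[str, str]
    true_snp_positions: list[int]
    true_tree: str
    cms_carriers: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def clades(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for acc, clade in self.clade_of.items():
            out.setdefault(clade, []).append(acc)
        return out

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthSet":
        raw = json.loads(Path(path).read_text())
        raw["cms_carriers"] = {
            acc: {g: tuple(v) for g, v in genes.items()}
            for acc, genes in raw.get("cms_carriers", {}).items()
        }
        return cls(**raw)


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _codes_to_str(codes: np.ndarray) -> str:
    lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
    return lut[codes.astype(np.intp)].tobytes().decode()


def _mutate(rng: np.random.Generator, base: int) -> int:
    """Uniform random alternative base."""
    return int((base + rng.integers(1, 4)) % 4)


def simulate_clades(
    cfg: SimConfig,
) -> tuple[str, dict[str, str], TruthSet]:
    """Simulate a reference and clade-structured accession haplotypes.

    Clade-diagnostic SNP positions are drawn without replacement
    (infinite sites) from positions outside the configured contamination
    regions, so contamination never masks a true SNP; each accession
    additionally receives Poisson(``private_snp_rate``) private SNPs.
    Returns ``(reference, {accession: haplotype}, truth)``.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    ref = _random_sequence(rng, cfg.genome_length)

    candidates = np.nonzero(~cfg.contaminated_mask())[0]
    n_clade_snps = cfg.n_clades * cfg.snps_per_clade
    acc_ids = [f"ACC{i:03d}" for i in range(cfg.n_accessions)]
    clade_ids = [f"clade{i + 1}" for i in range(cfg.n_clades)]
    clade_of = {acc: clade_ids[i % cfg.n_clades] for i, acc in enumerate(acc_ids)}

    n_private = rng.poisson(cfg.private_snp_rate, size=cfg.n_accessions)
    total_needed = n_clade_snps + int(n_private.sum())
    if total_needed > len(candidates):
        raise ValueError(
            f"requested {total_needed} SNP positions but only "
            f"{len(candidates)} uncontaminated sites are available"
        )
    chosen = rng.choice(candidates, size=total_needed, replace=False)
    clade_pos = chosen[:n_clade_snps].reshape(cfg.n_clades, cfg.snps_per_clade)
    private_pos = np.split(chosen[n_clade_snps:], np.cumsum(n_private)[:-1])

    clade_haps = {}
    for c, clade in enumerate(clade_ids):
        hap = ref.copy()
        for p in clade_pos[c]:
            hap[p] = _mutate(rng, int(ref[p]))
        clade_haps[clade] = hap

    haplotypes: dict[str, str] = {}
    for i, acc in enumerate(acc_ids):
        hap = clade_haps[clade_of[acc]].copy()
        for p in private_pos[i]:
            hap[p] = _mutate(rng, int(ref[p]))
        haplotypes[acc] = _codes_to_str(hap)

    positions = sorted(int(p) + 1 for p in chosen)
    clades = {c: [] for c in clade_ids}
    for acc in acc_ids:
        clades[clade_of[acc]].append(acc)
    tree = (
        "("
        + ",".join(
            "(" + ",".join(members) + ")" + clade for clade, members in clades.items()
        )
        + ");"
    )
    truth = TruthSet(clade_of=clade_of, true_snp_positions=positions, true_tree=tree)
    return _codes_to_str(ref), haplotypes, truth


def make_outgroup_haplotype(
    reference: str,
    truth: TruthSet,
    cfg: SimConfig,
    n_snps: int = 100,
    seed: int = 987,
) -> str:
    """A divergent haplotype carrying private SNPs, for outgroup rooting.

    SNPs are placed on uncontaminated sites not already polymorphic in
    the cohort, so the outgroup adds columns rather than masking any.
    """
    rng = np.random.default_rng(seed)
    used = {p - 1 for p in truth.true_snp_positions}
    free = [
        p
        for p in np.nonzero(~cfg.contaminated_mask())[0]
        if int(p) not in used
    ]
    if n_snps > len(free):
        raise ValueError("not enough free sites for the outgroup")
    hap = np.frombuffer(reference.encode(), dtype=np.uint8).copy()
    codes = np.array([BASE_INDEX[chr(b)] for b in hap], dtype=np.int8)
    for p in rng.choice(np.array(free), size=n_snps, replace=False):
        codes[p] = _mutate(rng, int(codes[p]))
    return _codes_to_str(codes)


def _region_allele(
    rng: np.random.Generator, ref_codes: np.ndarray, lo: int, hi: int, divergence: float
) -> np.ndarray:
    """Fixed divergent allele sequence for one contamination region."""
    allele = ref_codes[lo:hi].copy()
    flip = rng.random(hi - lo) < divergence
    for i in np.nonzero(flip)[0]:
        allele[i] = _mutate(rng, int(allele[i]))
    return allele


def make_site_tables(
    haplotypes: dict[str, str],
    cfg: SimConfig,
    reference: str,
) -> list[SiteTable]:
    """Per-accession per-site nucleotide compositions with contamination.

    Depth is Poisson around the class mean: ``depth_mito`` genome-wide,
    overridden by ``depth_plastid`` / ``depth_numt`` inside the
    configured regions.  Inside contamination regions the read base is a
    fixed, slightly divergent allele shared by all accessions (the reads
    are not mitochondrial); outside, reads support the accession
    haplotype, except that heteroplasmic sites carry a minor allele at
    fraction ``heteroplasmy_minor_freq``.
    """
    if any(len(h) != cfg.genome_length for h in haplotypes.values()):
        raise ValueError("haplotype length must equal genome_length")
    rng = np.random.default_rng(np.random.SeedSequence((cfg.rng_seed, 1)))
    L = cfg.genome_length
    ref_codes = np.array(
        [BASE_INDEX[b] for b in reference.upper()], dtype=np.int8
    )

    mean = np.full(L, cfg.depth_mito)
    served = ref_codes.copy()  # base served by contaminating reads
    contam = np.zeros(L, dtype=bool)
    for lo, hi in cfg.plastid_regions:
        mean[lo:hi] = cfg.depth_plastid
        served[lo:hi] = _region_allele(
            rng, ref_codes, lo, hi, cfg.contamination_divergence
        )
        contam[lo:hi] = True
    for lo, hi in cfg.numt_regions:
        mean[lo:hi] = cfg.depth_numt
        served[lo:hi] = _region_allele(
            rng, ref_codes, lo, hi, cfg.contamination_divergence
        )
        contam[lo:hi] = True

    tables = []
    positions = np.arange(1, L + 1)
    for acc, hap in haplotypes.items():
        hap_codes = np.array([BASE_INDEX[b] for b in hap.upper()], dtype=np.int8)
        major = np.where(contam, served, hap_codes)
        depth = rng.poisson(mean).astype(np.int64)

        counts = np.zeros((L, 4), dtype=np.int64)
        rows = np.arange(L)
        counts[rows, major.astype(np.intp)] = depth

        if cfg.heteroplasmy_rate > 0:
            het = (rng.random(L) < cfg.heteroplasmy_rate) & ~contam & (depth > 0)
            idx = np.nonzero(het)[0]
            if idx.size:
                minor_counts = rng.binomial(
                    depth[idx], cfg.heteroplasmy_minor_freq
                )
                minor_base = (
                    major[idx] + rng.integers(1, 4, size=idx.size)
                ) % 4
                counts[idx, major[idx].astype(np.intp)] -= minor_counts
                np.add.at(counts, (idx, minor_base.astype(np.intp)), minor_counts)

        tables.append(
            SiteTable(
                accession_id=acc,
                positions=positions,
                depth=depth,
                base_counts=counts,
                ins=np.zeros(L, dtype=np.int64),
                dels=np.zeros(L, dtype=np.int64),
            )
        )
    return tables


class EmbeddedInsert(NamedTuple):
    """Record of a gene copy embedded into a contig."""

    offset: int  # 0-based start of the insert on the returned contig
    length: int  # inserted length (== truncate_to or full query length)
    mismatches: int
    strand: str


_COMP = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def embed_gene(
    contig: str,
    query: str,
    n_mismatches: int,
    truncate_to: int | None = None,
    seed: int = 0,
    position: int | None = None,
    strand: str = "+",
    margin: int = 25,
) -> tuple[str, EmbeddedInsert]:
    """Embed a (possibly truncated, mutated) copy of a query into a contig.

    Exactly ``n_mismatches`` substitutions are applied at reproducibly
    chosen positions.  Mismatch positions are kept at least ``margin``
    bases from the insert ends (when the insert is long enough) so that
    a local aligner cannot profitably trim them off, keeping the
    intended (length, mismatches) pair recoverable.  Returns the new
    contig and the intended hit record.
    """
    rng = np.random.default_rng(seed)
    insert = query if truncate_to is None else query[:truncate_to]
    if truncate_to is not None and truncate_to > len(query):
        raise ValueError("truncate_to exceeds query length")
    if n_mismatches > len(insert):
        raise ValueError("n_mismatches exceeds insert length")
    lo, hi = 0, len(insert)
    if len(insert) > 2 * margin + n_mismatches:
        lo, hi = margin, len(insert) - margin
    if n_mismatches > hi - lo:
        lo, hi = 0, len(insert)
    codes = np.array([BASE_INDEX[b] for b in insert], dtype=np.int8)
    if n_mismatches:
        sites = rng.choice(np.arange(lo, hi), size=n_mismatches, replace=False)
        for s in sites:
            codes[s] = _mutate(rng, int(codes[s]))
    mutated = _codes_to_str(codes)
    if strand == "-":
        mutated = reverse_complement(mutated)
    offset = (
        int(rng.integers(0, len(contig) + 1)) if position is None else position
    )
    new_contig = contig[:offset] + mutated + contig[offset:]
    return new_contig, EmbeddedInsert(
        offset=offset, length=len(insert), mismatches=n_mismatches, strand=strand
    )


def random_contig(length: int, seed: int = 0) -> str:
    """Uniform-random ACGT sequence, handy as neutral contig background."""
    rng = np.random.default_rng(seed)
    return _codes_to_str(_random_sequence(rng, length))


def write_fasta(records: dict[str, str], path: str | Path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write(
        [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()],
        str(path),
        "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
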