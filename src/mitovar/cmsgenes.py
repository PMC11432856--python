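"""Screening contigs for CMS-associated gene sequences.

Cytoplasmic male sterility (CMS) in beet is associated with specific
mitochondrial sequences (the *preSatp6* NH2-extension of atp6, full
length 1161 bp; *orf129*; the *Gcox1-ext* NH2-extension of cox1).  An
accession's assembled mitochondrial contigs are screened with a
seed-and-extend local aligner, and the best hit per gene is classified
by the alignment-length / mismatch rule: a full-length alignment with at
most 3 mismatches means the gene is *present*; a shorter alignment with
8 or more mismatches is a divergent homologue (*-like*); anything in
between is reported as *ambiguous* rather than forced to a side.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class GeneQuery:
    """A gene sequence used as search query (plain ACGT, no ambiguity)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if set(self.sequence) - set("ACGT"):
            raise ValueError(f"query {self.name}: only A/C/G/T allowed")
        if not self.sequence:
            raise ValueError("empty query")

    @property
    def full_length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneHit:
    """Best local alignment of a query against one accession's contigs."""

    accession_id: str
    query_name: str
    alignment_length: int  # aligned query span, bp
    mismatches: int  # substitution columns (gap columns excluded)
    contig_id: str
    start: int  # 1-based inclusive on the original contig
    end: int
    strand: str
    score: float = 0.0
    identity: float = 0.0


@dataclass(frozen=True)
class ClassifyConfig:
    max_mismatches_present: int = 3
    min_mismatches_like: int = 8
    min_identity_report: float = 0.5

    def __post_init__(self) -> None:
        if self.max_mismatches_present >= self.min_mismatches_like:
            raise ValueError("present/like mismatch bounds must not overlap")


@dataclass(frozen=True)
class AlignScoring:
    """BLAST-like scores; a length-L gap costs |gap_open| + L*|gap_extend|."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -5
    gap_extend: int = -2


def _banded_sw(
    q: str,
    t: str,
    diag: int,
    band: int,
    sc: AlignScoring = AlignScoring(),
) -> tuple[int, int, int, int, int, int, int, int] | None:
    """Banded affine-gap Smith-Waterman with traceback.

    Only cells with |(j - i) - diag| <= band are filled (i over query,
    j over target, both 1-based).  Returns (score, qstart, qend, tstart,
    tend, matches, mismatches, gap_columns), all 1-based inclusive, or
    None when no positive-scoring cell exists.
    """
    lq, lt = len(q), len(t)
    NEG = -(10**9)
    go = -(sc.gap_open + sc.gap_extend)  # cost of opening a length-1 gap
    ge = -sc.gap_extend
    H = [[NEG] * (lt + 1) for _ in range(lq + 1)]
    E = [[NEG] * (lt + 1) for _ in range(lq + 1)]
    F = [[NEG] * (lt + 1) for _ in range(lq + 1)]
    ptr = [bytearray(lt + 1) for _ in range(lq + 1)]  # 0 stop, 1 diag, 2 E, 3 F
    ptrE = [bytearray(lt + 1) for _ in range(lq + 1)]  # 1 = opened from H
    ptrF = [bytearray(lt + 1) for _ in range(lq + 1)]
    for j in range(max(0, diag - band), min(lt, diag + band) + 1):
        H[0][j] = 0
    best_score, bi, bj = 0, 0, 0
    for i in range(1, lq + 1):
        jlo = max(1, i + diag - band)
        jhi = min(lt, i + diag + band)
        if jlo > jhi:
            continue
        qc = q[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        Ei, Fi, Fi1 = E[i], F[i], F[i - 1]
        pi, pEi, pFi = ptr[i], ptrE[i], ptrF[i]
        for j in range(jlo, jhi + 1):
            e_open = Hi[j - 1] - go
            e_ext = Ei[j - 1] - ge
            if e_open >= e_ext:
                Ei[j] = e_open
                pEi[j] = 1
            else:
                Ei[j] = e_ext
            f_open = Hi1[j] - go
            f_ext = Fi1[j] - ge
            if f_open >= f_ext:
                Fi[j] = f_open
                pFi[j] = 1
            else:
                Fi[j] = f_ext
            hd = Hi1[j - 1]
            if hd < 0:
                hd = 0
            s = sc.match if qc == t[j - 1] else sc.mismatch
            best = hd + s
            p = 1
            if Ei[j] > best:
                best, p = Ei[j], 2
            if Fi[j] > best:
                best, p = Fi[j], 3
            if best <= 0:
                best, p = 0, 0
            Hi[j] = best
            pi[j] = p
            if best > best_score:
                best_score, bi, bj = best, i, j
    if best_score <= 0:
        return None
    i, j = bi, bj
    qend, tend = i, j
    matches = mismatches = gapcols = 0
    while H[i][j] > 0:
        p = ptr[i][j]
        if p == 0:
            break
        if p == 1:
            if q[i - 1] == t[j - 1]:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:
            while True:
                opened = ptrE[i][j]
                j -= 1
                gapcols += 1
                if opened:
                    break
        else:
            while True:
                opened = ptrF[i][j]
                i -= 1
                gapcols += 1
                if opened:
                    break
    return (best_score, i + 1, qend, j + 1, tend, matches, mismatches, gapcols)


def _seed_candidates(
    query: str, target: str, k: int, band: int, max_candidates: int
) -> list[tuple[int, int]]:
    """Candidate (diag_min, diag_max) clusters from exact k-mer seeds."""
    index: dict[str, list[int]] = {}
    for qp in range(len(query) - k + 1):
        index.setdefault(query[qp : qp + k], []).append(qp)
    diags: dict[int, int] = {}
    for tp in range(len(target) - k + 1):
        for qp in index.get(target[tp : tp + k], ()):
            dg = tp - qp
            diags[dg] = diags.get(dg, 0) + 1
    if not diags:
        return []
    ordered = sorted(diags)
    clusters: list[list[int]] = [[ordered[0]]]
    for dg in ordered[1:]:
        if dg - clusters[-1][-1] <= band:
            clusters[-1].append(dg)
        else:
            clusters.append([dg])
    scored = sorted(
        clusters, key=lambda c: -sum(diags[dg] for dg in c)
    )[:max_candidates]
    return [(c[0], c[-1]) for c in scored]


def search_gene(
    contigs: Mapping[str, str],
    query: GeneQuery,
    accession_id: str = "",
    k: int = 15,
    band: int = 16,
    max_candidates: int = 4,
    cfg: ClassifyConfig = ClassifyConfig(),
    scoring: AlignScoring = AlignScoring(),
) -> GeneHit | None:
    """Best local alignment of a query across an accession's contigs.

    Exact k-mer seeds on both strands nominate candidate diagonals;
    each is refined by banded affine-gap Smith-Waterman.  The best hit
    maximises aligned query span, then minimises mismatches.  Returns
    None when nothing reaches ``cfg.min_identity_report`` identity.
    """
    if not contigs:
        raise ValueError("no contigs given")
    q = query.sequence
    best: GeneHit | None = None
    for contig_id, raw in contigs.items():
        seq = raw.upper()
        for strand in "+-":
            target = seq if strand == "+" else _revcomp(seq)
            for dmin, dmax in _seed_candidates(q, target, k, band, max_candidates):
                pad = band
                wlo = max(0, dmin - pad)
                whi = min(len(target), dmax + len(q) + pad)
                window = target[wlo:whi]
                center = (dmin + dmax) // 2 - wlo
                width = band + (dmax - dmin + 1) // 2
                res = _banded_sw(q, window, center, width, scoring)
                if res is None:
                    continue
                score, qs, qe, ts, te, matches, mism, gapcols = res
                aln_len = qe - qs + 1
                ncols = matches + mism + gapcols
                identity = matches / ncols if ncols else 0.0
                if strand == "+":
                    start, end = wlo + ts, wlo + te
                else:
                    end = len(seq) - (wlo + ts) + 1
                    start = len(seq) - (wlo + te) + 1
                hit = GeneHit(
                    accession_id=accession_id,
                    query_name=query.name,
                    alignment_length=aln_len,
                    mismatches=mism,
                    contig_id=contig_id,
                    start=start,
                    end=end,
                    strand=strand,
                    score=float(score),
                    identity=identity,
                )
                if best is None or (hit.alignment_length, -hit.mismatches, hit.score) > (
                    best.alignment_length,
                    -best.mismatches,
                    best.score,
                ):
                    best = hit
    if best is not None and best.identity < cfg.min_identity_report:
        return None
    return best


def classify_hit(
    hit: GeneHit | None,
    query: GeneQuery,
    cfg: ClassifyConfig = ClassifyConfig(),
) -> str:
    """Label a hit as present / like / ambiguous / absent.

    ``present``: full-length alignment with <= 3 mismatches (the gene is
    there); ``like``: shorter alignment with >= 8 mismatches (a
    divergent homologue); ``absent``: no reportable hit; anything else
    falls between the two printed regimes and is ``ambiguous``.
    """
    if hit is None:
        return "absent"
    if hit.alignment_length > query.full_length:
        raise ValueError("hit longer than the query")
    if (
        hit.alignment_length == query.full_length
        and hit.mismatches <= cfg.max_mismatches_present
    ):
        return "present"
    if (
        hit.alignment_length < query.full_length
        and hit.mismatches >= cfg.min_mismatches_like
    ):
        return "like"
    return "ambiguous"


@dataclass
class ScreenResult:
    """Cohort-level classification of CMS-gene content."""

    hits: pd.DataFrame  # one row per (accession, gene)
    counts: pd.DataFrame  # genes x labels
    no_contigs: list[str]
    crosstabs: dict[str, pd.DataFrame] = field(default_factory=dict)
    co_occurrence: pd.DataFrame | None = None


def screen_cohort(
    contigs_by_accession: Mapping[str, Mapping[str, str] | None],
    queries: Iterable[GeneQuery],
    cfg: ClassifyConfig = ClassifyConfig(),
    metadata: pd.DataFrame | None = None,
    **search_kwargs,
) -> ScreenResult:
    """Classify every (accession, gene) pair and cross-tabulate.

    Accessions without contigs are recorded in ``no_contigs`` and
    excluded from per-gene denominators.  When ``metadata`` (indexed by
    accession, with e.g. ``clade`` / ``coast`` columns) is supplied,
    per-gene label counts are cross-tabulated against each column.
    """
    queries = list(queries)
    rows = []
    no_contigs = []
    for acc, contigs in contigs_by_accession.items():
        if not contigs:
            no_contigs.append(acc)
            continue
        for gq in queries:
            hit = search_gene(contigs, gq, accession_id=acc, cfg=cfg, **search_kwargs)
            label = classify_hit(hit, gq, cfg)
            rows.append(
                {
                    "accession": acc,
                    "gene": gq.name,
                    "label": label,
                    "contig": hit.contig_id if hit else None,
                    "start": hit.start if hit else None,
                    "end": hit.end if hit else None,
                    "strand": hit.strand if hit else None,
                    "aln_len": hit.alignment_length if hit else None,
                    "mismatches": hit.mismatches if hit else None,
                }
            )
    hits = pd.DataFrame(
        rows,
        columns=[
            "accession",
            "gene",
            "label",
            "contig",
            "start",
            "end",
            "strand",
            "aln_len",
            "mismatches",
        ],
    )
    labels = ["present", "like", "ambiguous", "absent"]
    if len(hits):
        counts = (
            hits.pivot_table(
                index="gene", columns="label", values="accession", aggfunc="count"
            )
            .reindex(columns=labels, fill_value=0)
            .fillna(0)
            .astype(int)
        )
    else:
        counts = pd.DataFrame(0, index=[q.name for q in queries], columns=labels)
    crosstabs = {}
    if metadata is not None and len(hits):
        joined = hits.join(metadata, on="accession")
        for col in metadata.columns:
            crosstabs[col] = pd.crosstab([joined["gene"], joined["label"]], joined[col])
    co = None
    if len(hits):
        co = hits.pivot(index="accession", columns="gene", values="label")
    return ScreenResult(
        hits=hits,
        counts=counts,
        no_contigs=no_contigs,
        crosstabs=crosstabs,
        co_occurrence=co,
    )
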