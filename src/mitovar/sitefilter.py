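"""Depth-class filtering, consensus calling and SNP-site extraction.

Plant mitochondrial read mappings carry two classes of contaminating
coverage: plastid-homologous regions attract ptDNA reads at very high
depth (plastids outnumber mitochondria per cell), while nuclear copies of
mtDNA (NUMTs) contribute a thin layer of mis-mapped reads at very low
depth.  This module implements the filtering strategy that separates the
genuine mitochondrial signal from both: a per-site read-depth window
(strictly between 20 and 900 by default), a consensus-frequency rule
(the majority base must exceed 80% of reads), indel-majority exclusion,
and cross-accession SNP-site extraction in which any site with missing
data, an indel call, or no polymorphism is dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: integer codes used in ConsensusMatrix.calls
MISSING_CODE = -1

#: flag codes used in ConsensusMatrix.flags
FLAG_OK = 0
FLAG_DEPTH_LOW = 1
FLAG_DEPTH_HIGH = 2
FLAG_LOW_CONSENSUS = 3
FLAG_INDEL_MAJORITY = 4

FLAG_NAMES = {
    FLAG_OK: "ok",
    FLAG_DEPTH_LOW: "depth_low",
    FLAG_DEPTH_HIGH: "depth_high",
    FLAG_LOW_CONSENSUS: "low_consensus",
    FLAG_INDEL_MAJORITY: "indel_majority",
}


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the variant-calling filter.

    Depths equal to or below ``min_depth_exclusive`` and equal to or
    above ``max_depth_exclusive`` are treated as missing data (NUMT and
    plastid contamination classes respectively).  Consensus frequencies
    equal to or below ``min_consensus_freq_exclusive`` are likewise
    treated as missing.
    """

    min_depth_exclusive: int = 20
    max_depth_exclusive: int = 900
    min_consensus_freq_exclusive: float = 0.80
    window_size: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.min_depth_exclusive < self.max_depth_exclusive):
            raise ValueError("need 0 <= min_depth_exclusive < max_depth_exclusive")
        if not (0.5 < self.min_consensus_freq_exclusive < 1.0):
            raise ValueError("min_consensus_freq_exclusive must lie in (0.5, 1)")
        if self.window_size < 1:
            raise ValueError("window_size must be positive")


@dataclass
class SiteTable:
    """Per-site nucleotide composition of one accession's read mapping.

    ``positions`` are 1-based reference coordinates; ``base_counts`` has
    one row per site with columns A, C, G, T; ``ins`` and ``dels`` count
    reads supporting an insertion/deletion at the site.  The stored
    ``depth`` must equal base_counts.sum(axis=1) + ins + dels.
    """

    accession_id: str
    positions: np.ndarray
    depth: np.ndarray
    base_counts: np.ndarray
    ins: np.ndarray
    dels: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        self.base_counts = np.asarray(self.base_counts, dtype=np.int64)
        self.ins = np.asarray(self.ins, dtype=np.int64)
        self.dels = np.asarray(self.dels, dtype=np.int64)
        n = len(self.positions)
        if self.base_counts.shape != (n, 4):
            raise ValueError("base_counts must be (n_sites, 4)")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        total = self.base_counts.sum(axis=1) + self.ins + self.dels
        if not np.array_equal(total, self.depth):
            raise ValueError("depth must equal sum of base counts plus indels")

    @property
    def indel_count(self) -> np.ndarray:
        return self.ins + self.dels

    def __len__(self) -> int:
        return len(self.positions)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "pos": self.positions,
                "depth": self.depth,
                "A": self.base_counts[:, 0],
                "C": self.base_counts[:, 1],
                "G": self.base_counts[:, 2],
                "T": self.base_counts[:, 3],
                "ins": self.ins,
                "del": self.dels,
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, accession_id: str | None = None) -> "SiteTable":
        df = pd.read_csv(path, sep="\t")
        acc = accession_id if accession_id is not None else Path(path).stem
        return cls(
            accession_id=acc,
            positions=df["pos"].to_numpy(),
            depth=df["depth"].to_numpy(),
            base_counts=df[["A", "C", "G", "T"]].to_numpy(),
            ins=df["ins"].to_numpy(),
            dels=df["del"].to_numpy(),
        )


@dataclass
class ConsensusMatrix:
    """Called bases per accession per reference position.

    ``calls`` holds base codes 0..3 (A,C,G,T) or -1 for missing; ``flags``
    holds the missing-data provenance (depth_low, depth_high,
    low_consensus, indel_majority) and 0 where a base was called.
    """

    accession_ids: list[str]
    calls: np.ndarray  # (n_accessions, reference_length) int8
    flags: np.ndarray  # same shape, int8

    def __post_init__(self) -> None:
        if self.calls.shape != self.flags.shape:
            raise ValueError("calls and flags must have the same shape")
        if self.calls.shape[0] != len(self.accession_ids):
            raise ValueError("row count must match accession_ids")
        missing = self.calls == MISSING_CODE
        if np.any(missing != (self.flags != FLAG_OK)):
            raise ValueError("flags must be set iff the call is missing")

    @property
    def reference_length(self) -> int:
        return self.calls.shape[1]

    def missing_fraction(self) -> float:
        return float(np.mean(self.calls == MISSING_CODE))


@dataclass
class SnpMatrix:
    """Retained polymorphic sites across accessions.

    ``positions`` are the 1-based reference coordinates of the retained
    columns (strictly increasing); ``bases`` holds base codes 0..3 with
    no missing entries.
    """

    accession_ids: list[str]
    positions: np.ndarray
    bases: np.ndarray  # (n_accessions, n_sites) int8

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.bases.shape != (len(self.accession_ids), len(self.positions)):
            raise ValueError("bases shape must be (n_accessions, n_positions)")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any((self.bases < 0) | (self.bases > 3)):
            raise ValueError("bases must be codes 0..3 with no missing entries")

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def sequences(self) -> dict[str, str]:
        """Concatenated SNP-column bases per accession."""
        lut = np.frombuffer(BASES.encode(), dtype=np.uint8)
        return {
            acc: lut[self.bases[i]].tobytes().decode()
            for i, acc in enumerate(self.accession_ids)
        }

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpMatrix):
            return NotImplemented
        return (
            self.accession_ids == other.accession_ids
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.bases, other.bases)
        )


def classify_site_depth(depth: int, cfg: FilterConfig = FilterConfig()) -> str:
    """Classify a site's read depth as retain / drop_low / drop_high.

    A depth equal to or below the low bound (NUMT class) or equal to or
    above the high bound (plastid class) is dropped.
    """
    if depth < 0:
        raise ValueError(f"negative depth: {depth}")
    if depth <= cfg.min_depth_exclusive:
        return "drop_low"
    if depth >= cfg.max_depth_exclusive:
        return "drop_high"
    return "retain"


def call_consensus(
    base_counts: Sequence[int],
    indel_count: int = 0,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[str | None, float, str]:
    """Call the consensus base at one site of one accession.

    Returns ``(base, frequency, flag)`` where ``base`` is None when the
    site is missing.  The consensus is the most frequent nucleotide; its
    frequency is taken over the full read depth including indel reads.
    The site is missing when indel reads are the plurality
    (``indel_majority``) or when the consensus frequency does not exceed
    the threshold (``low_consensus``).  The threshold comparison is done
    in exact integer arithmetic for the default 0.80.
    """
    counts = np.asarray(base_counts, dtype=np.int64)
    if counts.shape != (4,):
        raise ValueError("base_counts must have four entries (A, C, G, T)")
    if np.any(counts < 0) or indel_count < 0:
        raise ValueError("counts must be non-negative")
    depth = int(counts.sum()) + int(indel_count)
    if depth == 0:
        raise ValueError("all-zero counts: depth-filter the site first")
    top = int(counts.argmax())
    top_count = int(counts[top])
    freq = top_count / depth
    if indel_count > top_count:
        return None, freq, FLAG_NAMES[FLAG_INDEL_MAJORITY]
    if not _freq_exceeds(top_count, depth, cfg.min_consensus_freq_exclusive):
        return None, freq, FLAG_NAMES[FLAG_LOW_CONSENSUS]
    return BASES[top], freq, FLAG_NAMES[FLAG_OK]


def _freq_exceeds(count: int, depth: int, threshold: float) -> bool:
    """True iff count/depth > threshold, exact for rational thresholds.

    The default threshold 0.80 is evaluated as 5*count > 4*depth so that
    a site at exactly 80% is excluded regardless of float rounding.
    """
    if threshold == 0.80:
        return 5 * count > 4 * depth
    return count / depth > threshold


def _consensus_arrays(
    table: SiteTable, cfg: FilterConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised per-site calls/flags for one accession (codes)."""
    n = len(table)
    calls = np.full(n, MISSING_CODE, dtype=np.int8)
    flags = np.zeros(n, dtype=np.int8)

    depth = table.depth
    low = depth <= cfg.min_depth_exclusive
    high = depth >= cfg.max_depth_exclusive
    flags[low] = FLAG_DEPTH_LOW
    flags[high] = FLAG_DEPTH_HIGH

    live = ~(low | high)
    counts = table.base_counts
    top = counts.argmax(axis=1)
    top_count = np.take_along_axis(counts, top[:, None], axis=1)[:, 0]
    indel = table.indel_count

    indel_major = live & (indel > top_count)
    flags[indel_major] = FLAG_INDEL_MAJORITY
    if cfg.min_consensus_freq_exclusive == 0.80:
        ok_freq = 5 * top_count > 4 * depth
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ok_freq = np.where(
                depth > 0, top_count / np.maximum(depth, 1), 0.0
            ) > cfg.min_consensus_freq_exclusive
    low_cons = live & ~indel_major & ~ok_freq
    flags[low_cons] = FLAG_LOW_CONSENSUS

    retained = live & ~indel_major & ok_freq
    calls[retained] = top[retained].astype(np.int8)
    return calls, flags


def build_consensus_matrix(
    site_tables: Iterable[SiteTable], cfg: FilterConfig = FilterConfig()
) -> ConsensusMatrix:
    """Apply depth and consensus filters to a cohort of site tables.

    All tables must cover the same reference coordinate system (positions
    1..L exactly once).  Duplicate accession ids are rejected.
    """
    tables = list(site_tables)
    if not tables:
        raise ValueError("no site tables given")
    ids = [t.accession_id for t in tables]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate accession ids")
    length = len(tables[0])
    expected = np.arange(1, length + 1)
    calls = np.empty((len(tables), length), dtype=np.int8)
    flags = np.empty_like(calls)
    for i, t in enumerate(tables):
        if len(t) != length or not np.array_equal(t.positions, expected):
            raise ValueError(
                f"site table {t.accession_id} does not cover positions 1..{length}"
            )
        calls[i], flags[i] = _consensus_arrays(t, cfg)
    return ConsensusMatrix(ids, calls, flags)


def refine_reference(
    site_table: SiteTable,
    reference: str,
    cfg: FilterConfig = FilterConfig(),
) -> tuple[str, list[tuple[int, str, str]]]:
    """Correct a reference sequence from one accession's read pileup.

    At sites whose depth falls in the retained window and whose consensus
    exceeds the frequency threshold, the reference base is replaced by
    the consensus base; contaminated (plastid/NUMT depth class) and
    ambiguous sites keep the original base.  Returns the corrected
    sequence and the list of (1-based position, old, new) changes.
    """
    if len(site_table) != len(reference):
        raise ValueError(
            f"site table length {len(site_table)} != reference length {len(reference)}"
        )
    calls, _ = _consensus_arrays(site_table, cfg)
    seq = list(reference.upper())
    changes: list[tuple[int, str, str]] = []
    called = np.nonzero(calls != MISSING_CODE)[0]
    for i in called:
        new = BASES[calls[i]]
        if seq[i] != new:
            changes.append((i + 1, seq[i], new))
            seq[i] = new
    return "".join(seq), changes


def extract_snp_sites(cm: ConsensusMatrix) -> SnpMatrix:
    """Retain columns with no missing data and at least two distinct bases.

    Sites where any accession is missing (either depth class, a low
    consensus, or an indel majority) are dropped before polymorphism is
    assessed, so a site that looks invariant only because its variant
    accession went missing is counted as missing data, not as invariant.
    """
    if cm.calls.size == 0:
        raise ValueError("empty consensus matrix")
    complete = np.all(cm.calls != MISSING_CODE, axis=0)
    poly = (cm.calls != cm.calls[0]).any(axis=0)
    keep = complete & poly
    positions = np.nonzero(keep)[0] + 1
    return SnpMatrix(list(cm.accession_ids), positions, cm.calls[:, keep].copy())


def window_snp_density(
    positions: Sequence[int], reference_length: int, window_size: int = 1000
) -> np.ndarray:
    """Count SNP sites per non-overlapping window along the reference.

    Windows are anchored at position 1 and 1-based inclusive:
    [1..window], [window+1..2*window], ...; the last window may be short.
    """
    pos = np.asarray(positions, dtype=np.int64)
    if pos.size and (pos.min() < 1 or pos.max() > reference_length):
        raise ValueError("SNP position outside [1, reference_length]")
    n_windows = -(-reference_length // window_size)
    return np.bincount((pos - 1) // window_size, minlength=n_windows)


# ---------------------------------------------------------------------------
# SNP export / import
# ---------------------------------------------------------------------------

def write_snp_fasta(sm: SnpMatrix, path: str | Path) -> None:
    """Write concatenated SNP-column bases as a multi-FASTA file."""
    records = [
        SeqRecord(Seq(seq), id=acc, description="")
        for acc, seq in sm.sequences().items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_snp_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a SNP multi-FASTA back into (accession ids, sequences)."""
    ids, seqs = [], []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        seqs.append(str(rec.seq).upper())
    if len({len(s) for s in seqs}) > 1:
        raise ValueError(f"{path}: unequal sequence lengths in SNP FASTA")
    return ids, seqs


def write_snp_vcf(
    sm: SnpMatrix,
    reference: str,
    path: str | Path,
    chrom: str = "mito_ref",
) -> None:
    """Write the SNP matrix as a haploid VCF v4.2 with original coordinates.

    REF is the reference base at the site; ALT lists the non-reference
    bases observed, alphabetically; sample genotypes are haploid allele
    indices.
    """
    lines = [
        "##fileformat=VCFv4.2",
        "##source=mitovar",
        f"##contig=<ID={chrom},length={len(reference)}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Haploid genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(sm.accession_ids),
    ]
    for j, pos in enumerate(sm.positions):
        ref_base = reference[pos - 1].upper()
        col = sm.bases[:, j]
        observed = sorted({BASES[c] for c in col})
        alts = [b for b in observed if b != ref_base]
        allele_index = {ref_base: 0}
        for k, b in enumerate(alts, start=1):
            allele_index[b] = k
        gts = "\t".join(str(allele_index[BASES[c]]) for c in col)
        alt_field = ",".join(alts) if alts else "."
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref_base}\t{alt_field}\t.\tPASS\t.\tGT\t{gts}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_snp_vcf(path: str | Path) -> SnpMatrix:
    """Read a haploid SNP VCF written by :func:`write_snp_vcf`."""
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        ids = list(vf.header.samples)
        positions: list[int] = []
        rows: list[list[int]] = []
        for rec in vf:
            alleles = [rec.ref] + list(rec.alts or ())
            positions.append(rec.pos)
            rows.append(
                [
                    BASE_INDEX[alleles[rec.samples[s]["GT"][0]]]
                    for s in ids
                ]
            )
    bases = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((len(ids), 0), dtype=np.int8)
    )
    return SnpMatrix(ids, np.array(positions, dtype=np.int64), bases)
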