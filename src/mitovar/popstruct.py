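"""Population structure: Bray-Curtis / UPGMA clustering and PCA.

SNP haplotypes are encoded as binary non-reference-allele indicators
(one column per site x alternate allele), pairwise dissimilarities are
Bray-Curtis, the dendrogram is classical average-linkage (UPGMA) with
deterministic smallest-leaf-index tie-breaking, and PCA is performed on
the mean-centred indicator matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .sitefilter import BASES, SnpMatrix


@dataclass
class EncodedMatrix:
    """Binary indicators of non-reference alleles.

    One column per (site, alternate allele) pair actually observed in
    the cohort; an accession's row is 1 where it carries that allele.
    An all-zero row is an accession identical to the reference at every
    retained site.
    """

    accession_ids: list[str]
    columns: list[tuple[int, str]]  # (1-based position, alternate base)
    matrix: np.ndarray  # (n_accessions, n_columns) uint8

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.accession_ids), len(self.columns)):
            raise ValueError("matrix shape must match ids x columns")
        if self.matrix.size and not np.isin(self.matrix, (0, 1)).all():
            raise ValueError("entries must be 0/1")


def encode(sm: SnpMatrix, reference: str) -> EncodedMatrix:
    """Indicator-encode a SNP matrix against reference bases.

    Column order is deterministic: by position, then allele
    alphabetically.  Alleles equal to the reference base contribute no
    column; columns for alleles nobody carries cannot arise because only
    observed alleles are enumerated.
    """
    cols: list[tuple[int, str]] = []
    vecs: list[np.ndarray] = []
    for j, pos in enumerate(sm.positions):
        if pos > len(reference):
            raise ValueError(f"site {pos} beyond the reference (len {len(reference)})")
        ref_base = reference[pos - 1].upper()
        if ref_base not in BASES:
            raise ValueError(f"no reference base for site {pos!r}")
        col = sm.bases[:, j]
        for b in sorted({BASES[c] for c in col} - {ref_base}):
            cols.append((int(pos), b))
            vecs.append((col == BASES.index(b)).astype(np.uint8))
    matrix = (
        np.column_stack(vecs)
        if vecs
        else np.zeros((len(sm.accession_ids), 0), dtype=np.uint8)
    )
    return EncodedMatrix(list(sm.accession_ids), cols, matrix)


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity sum|u-v| / sum(u+v) of non-negative vectors.

    A pair of all-zero vectors (two accessions identical to the
    reference) is defined as distance 0 with a warning.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must have equal length")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("Bray-Curtis requires non-negative entries")
    denom = float((u + v).sum())
    if denom == 0.0:
        warnings.warn(
            "Bray-Curtis of two all-zero vectors defined as 0", stacklevel=2
        )
        return 0.0
    return float(np.abs(u - v).sum() / denom)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix must be square over ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(m), 0.0, atol=1e-12):
            raise ValueError("diagonal must be zero")
        self.matrix = m

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.matrix, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t"
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index), df.to_numpy())


def pairwise_bray_curtis(em: EncodedMatrix) -> DistanceMatrix:
    """All-pairs Bray-Curtis over encoded accession rows."""
    n = len(em.accession_ids)
    x = em.matrix.astype(float)
    d = np.zeros((n, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = bray_curtis(x[i], x[j])
    return DistanceMatrix(list(em.accession_ids), d)


@dataclass
class Dendrogram:
    """Average-linkage merge tree.

    ``merges`` lists (left_id, right_id, merge_distance, size); cluster
    ids 0..n-1 are leaves in input order, id n+k is the cluster created
    by merge k.  Dendrogram node heights follow the standard convention
    of half the merge distance, so cophenetic distances equal merge
    distances.
    """

    leaf_ids: list[str]
    merges: list[tuple[int, int, float, int]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def heights(self) -> list[float]:
        return [d / 2.0 for _, _, d, _ in self.merges]

    def linkage(self) -> np.ndarray:
        """scipy-style (n-1, 4) linkage array (merge distances, sizes)."""
        return np.array(self.merges, dtype=float)

    def _members(self) -> dict[int, list[int]]:
        members = {i: [i] for i in range(self.n_leaves)}
        for k, (a, b, _, _) in enumerate(self.merges):
            members[self.n_leaves + k] = members[a] + members[b]
        return members

    def to_newick(self) -> str:
        """Ultrametric Newick with branch lengths from node heights."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        node = {i: f"{_escape(self.leaf_ids[i])}" for i in range(self.n_leaves)}
        for k, (a, b, dist, _) in enumerate(self.merges):
            h = dist / 2.0
            nid = self.n_leaves + k
            la, lb = h - height[a], h - height[b]
            node[nid] = f"({node[a]}:{la:.10g},{node[b]}:{lb:.10g})"
            height[nid] = h
        return node[2 * self.n_leaves - 2] + ";"


def _escape(label: str) -> str:
    return label.replace(" ", "_")


def _pair_key(members_a: list[int], members_b: list[int]) -> tuple[int, int]:
    """Deterministic tie-break key: smallest leaf index of each side."""
    return tuple(sorted((min(members_a), min(members_b))))


def upgma(D: DistanceMatrix) -> Dendrogram:
    """Average-linkage agglomeration with smallest-leaf-index tie-breaks.

    Inter-cluster distance is the size-weighted arithmetic mean of member
    pair distances (the classical UPGMA update), so the result is
    ultrametric with non-decreasing merge distances.
    """
    n = len(D.ids)
    if n < 2:
        raise ValueError("UPGMA needs at least two taxa")
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(D.matrix[i, j])
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for key, d in dist.items():
            tie = _pair_key(active[key[0]], active[key[1]])
            cand = (d, tie)
            if best is None or cand < best[0]:
                best = (cand, key)
        (d_min, _), (a, b) = best
        new_size = sizes[a] + sizes[b]
        # UPGMA update: weighted average to every other active cluster
        for other in list(active):
            if other in (a, b):
                continue
            da = dist.pop(tuple(sorted((a, other))))
            db = dist.pop(tuple(sorted((b, other))))
            dist[tuple(sorted((next_id, other)))] = (
                sizes[a] * da + sizes[b] * db
            ) / new_size
        dist.pop((a, b))
        active[next_id] = active.pop(a) + active.pop(b)
        sizes[next_id] = new_size
        merges.append((a, b, d_min, new_size))
        next_id += 1
    return Dendrogram(list(D.ids), merges)


def cut_clusters(dg: Dendrogram, k: int) -> np.ndarray:
    """Flat cluster labels from cutting the k-1 highest merges.

    Labels are 1..k, numbered by the smallest member leaf index of each
    cluster for stability.
    """
    n = dg.n_leaves
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for idx, (a, b, _, _) in enumerate(dg.merges[: n - k]):
        nid = n + idx
        parent[find(a)] = nid
        parent[find(b)] = nid
    roots: dict[int, list[int]] = {}
    for leaf in range(n):
        roots.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(roots.values(), key=min)
    labels = np.empty(n, dtype=np.int64)
    for lab, members in enumerate(ordered, start=1):
        labels[np.array(members)] = lab
    return labels


@dataclass
class PCAResult:
    accession_ids: list[str]
    scores: np.ndarray  # (n, k)
    loadings: np.ndarray  # (p, k)
    explained_ratio: np.ndarray  # (k,)


def pca(em: EncodedMatrix, n_components: int | None = None) -> PCAResult:
    """PCA of the mean-centred (unscaled) indicator matrix.

    Components come from an SVD of the centred matrix; explained
    proportions are relative to total variance, so the cumulative
    proportion is non-decreasing and bounded by 1.  The sign of each
    component is fixed by making its largest-magnitude loading positive.
    """
    x = em.matrix.astype(float)
    n, p = x.shape
    if n < 2 or p < 1:
        raise ValueError("PCA needs at least two accessions and one column")
    xc = x - x.mean(axis=0)
    total_var = float((xc**2).sum()) / (n - 1)
    if total_var == 0.0:
        raise ValueError("zero-variance input: explained proportions undefined")
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    k = min(n_components or len(s), len(s))
    scores = u[:, :k] * s[:k]
    loadings = vt[:k].T
    for j in range(k):
        i_max = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_max, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    explained = (s[:k] ** 2 / (n - 1)) / total_var
    return PCAResult(list(em.accession_ids), scores, loadings, explained)
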