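"""Distance-based phylogeny with bootstrap support.

A concatenated-SNP alignment is turned into a tree by neighbor-joining
on p-distances or Jukes-Cantor-corrected distances, with classic
Felsenstein bootstrap (columns resampled with replacement; support is
the percentage of replicate trees containing each internal bipartition
of the point-estimate tree).  dendropy provides the tree container,
Newick serialisation and bipartition machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np

from .popstruct import DistanceMatrix
from .sitefilter import BASES

JC_MAX_DISTANCE = 5.0  # clamp for saturated Jukes-Cantor pairs


@dataclass
class SnpAlignment:
    """Equal-length concatenated SNP haplotypes."""

    ids: list[str]
    seqs: list[str]
    outgroup: str | None = None

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs must align")
        if len({len(s) for s in self.seqs}) > 1:
            raise ValueError("sequences must have equal length")
        if self.outgroup is not None and self.outgroup not in self.ids:
            raise ValueError(f"outgroup {self.outgroup!r} not among accessions")

    @property
    def n_sites(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def codes(self) -> np.ndarray:
        """(n_taxa, n_sites) uint8 matrix of base ordinals."""
        return np.array(
            [np.frombuffer(s.encode(), dtype=np.uint8) for s in self.seqs]
        )

    @classmethod
    def from_fasta(cls, path: str | Path, outgroup: str | None = None):
        from .sitefilter import read_snp_fasta

        ids, seqs = read_snp_fasta(path)
        return cls(ids, seqs, outgroup)


@dataclass
class PhyloTree:
    """A dendropy tree plus per-bipartition bootstrap supports (0-100)."""

    tree: dendropy.Tree
    supports: dict[frozenset, float] = field(default_factory=dict)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(data=text, schema="newick")
        pt = cls(tree)
        all_leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
        first = min(all_leaves)
        for node in tree.preorder_internal_node_iter(exclude_seed_node=True):
            if node.label is not None:
                side = leafset(node)
                key = side if first not in side else all_leaves - side
                pt.supports[key] = float(node.label)
        return pt

    def leaf_ids(self) -> list[str]:
        return [lf.taxon.label for lf in self.tree.leaf_node_iter()]


def leafset(node: dendropy.Node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def pairwise_distance(aln: SnpAlignment, model: str = "p") -> DistanceMatrix:
    """p-distance or JC69-corrected distance between all sequence pairs.

    p-distance is the mismatch fraction over all columns; JC69 applies
    -(3/4)ln(1 - 4p/3), with saturated pairs (p >= 0.75) clamped to
    ``JC_MAX_DISTANCE`` with a warning.
    """
    if aln.n_sites == 0:
        raise ValueError("zero-length alignment")
    codes = aln.codes()
    n = len(aln.ids)
    p = np.zeros((n, n))
    for i in range(n):
        diff = (codes[i + 1 :] != codes[i]).mean(axis=1)
        p[i, i + 1 :] = diff
        p[i + 1 :, i] = diff
    if model == "p":
        return DistanceMatrix(list(aln.ids), p)
    if model.upper() == "JC69":
        saturated = p >= 0.75
        if saturated.any():
            warnings.warn(
                "saturated JC69 pairs clamped to "
                f"{JC_MAX_DISTANCE} substitutions/site",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            d = -0.75 * np.log1p(-(4.0 / 3.0) * p)
        d = np.where(saturated, JC_MAX_DISTANCE, d)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list(aln.ids), d)
    raise ValueError(f"unknown model {model!r}")


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor-joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the smallest (i, j) index
    pair.  Negative branch lengths are clamped to zero, the deficit
    moving to the sibling edge (which is clamped in turn if needed).
    The result is unrooted with a central trifurcation.
    """
    n = len(D.ids)
    if n < 3:
        raise ValueError("neighbor-joining needs at least three taxa")
    taxa = dendropy.TaxonNamespace(list(D.ids))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in D.ids:
        nd = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(nd)
    d = D.matrix.astype(float).copy()
    idx = list(range(n))  # positions into d / nodes

    while len(idx) > 3:
        m = len(idx)
        sub = d[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        best = np.unravel_index(np.argmin(q), q.shape)
        ties = np.argwhere(np.isclose(q, q[best], rtol=0, atol=1e-12))
        ai, bj = min((min(i, j), max(i, j)) for i, j in ties)
        i_glob, j_glob = idx[ai], idx[bj]
        dij = sub[ai, bj]
        li = 0.5 * dij + (r[ai] - r[bj]) / (2 * (m - 2))
        lj = dij - li
        li, lj = _clamp_pair(li, lj)
        parent = dendropy.Node()
        parent.add_child(nodes[i_glob])
        parent.add_child(nodes[j_glob])
        nodes[i_glob].edge.length = li
        nodes[j_glob].edge.length = lj
        # distances from the new node to the remaining taxa
        new_row = np.zeros(len(d) + 1)
        for k in idx:
            if k in (i_glob, j_glob):
                continue
            new_row[k] = 0.5 * (d[i_glob, k] + d[j_glob, k] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(new_row)] = new_row
        d[: len(new_row), -1] = new_row
        nodes.append(parent)
        idx = [k for k in idx if k not in (i_glob, j_glob)] + [len(d) - 1]

    a, b, c = idx
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        center.add_child(nodes[k])
        nodes[k].edge.length = max(0.0, lk)
    tree.seed_node = center
    tree.is_rooted = False
    return PhyloTree(tree)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def nj_tree(aln: SnpAlignment, model: str = "JC69") -> PhyloTree:
    return neighbor_joining(pairwise_distance(aln, model=model))


def _internal_bipartitions(pt: PhyloTree) -> set[frozenset]:
    """Non-trivial splits of an unrooted tree, as the leaf set of one side."""
    all_leaves = frozenset(pt.leaf_ids())
    splits = set()
    for node in pt.tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = leafset(node)
        if 1 < len(side) < len(all_leaves) - 1:
            # normalise: use the side not containing the first taxon
            first = min(all_leaves)
            splits.add(side if first not in side else all_leaves - side)
    return splits


def bootstrap(
    aln: SnpAlignment,
    n_reps: int = 1000,
    seed: int = 0,
    model: str = "JC69",
) -> PhyloTree:
    """Bootstrap supports on the point-estimate NJ tree.

    Columns are resampled with replacement ``n_reps`` times; the support
    of each internal bipartition of the point tree is the percentage of
    replicate trees containing it.  Supports are written into the
    internal-node labels of the returned tree.
    """
    if aln.n_sites < 1:
        raise ValueError("alignment has no columns")
    point = nj_tree(aln, model=model)
    target = _internal_bipartitions(point)
    counts = {s: 0 for s in target}
    codes = aln.codes()
    rng = np.random.default_rng(seed)
    lut = codes  # (n, m)
    m = aln.n_sites
    for _ in range(n_reps):
        cols = rng.integers(0, m, size=m)
        rep_seqs = ["".join(map(chr, row)) for row in lut[:, cols]]
        rep = nj_tree(SnpAlignment(list(aln.ids), rep_seqs), model=model)
        rep_splits = _internal_bipartitions(rep)
        for s in target:
            if s in rep_splits:
                counts[s] += 1
    all_leaves = frozenset(aln.ids)
    first = min(all_leaves)
    for node in point.tree.preorder_internal_node_iter(exclude_seed_node=True):
        side = leafset(node)
        if 1 < len(side) < len(all_leaves) - 1:
            key = side if first not in side else all_leaves - side
            pct = 100.0 * counts[key] / n_reps
            point.supports[key] = pct
            node.label = f"{pct:g}"
    return point


def root_with_outgroup(pt: PhyloTree, outgroup_id: str) -> PhyloTree:
    """Root the tree on the midpoint of the outgroup's terminal edge."""
    tree = pt.tree.clone(depth=1)
    node = None
    for lf in tree.leaf_node_iter():
        if lf.taxon.label == outgroup_id:
            node = lf
            break
    if node is None:
        raise ValueError(f"outgroup {outgroup_id!r} not in tree")
    length = node.edge.length or 0.0
    tree.reroot_at_edge(node.edge, length1=length / 2, length2=length / 2)
    tree.is_rooted = True
    rooted = PhyloTree(tree, dict(pt.supports))
    return rooted


def clade_membership(
    pt: PhyloTree, clade_defs: dict[str, set[str]]
) -> tuple[dict[str, str | None], dict[str, bool]]:
    """Assign accessions to named clades via exemplar MRCAs.

    For each named clade the smallest monophyletic group (subtree of the
    exemplars' MRCA) is taken; every accession falling in that subtree
    and in no smaller named subtree gets the label.  A clade whose MRCA
    subtree contains exemplars of another clade is flagged as
    non-monophyletic (its containing subtree is still reported).
    Requires a rooted tree.
    """
    subtree: dict[str, frozenset] = {}
    for name, exemplars in clade_defs.items():
        missing = exemplars - set(pt.leaf_ids())
        if missing:
            raise ValueError(f"exemplars not in tree: {sorted(missing)}")
        mrca = pt.tree.mrca(taxon_labels=sorted(exemplars))
        subtree[name] = leafset(mrca)
    other_exemplars = {
        name: set().union(*(e for n, e in clade_defs.items() if n != name))
        if len(clade_defs) > 1
        else set()
        for name in clade_defs
    }
    monophyletic = {
        name: not (subtree[name] & other_exemplars[name]) for name in clade_defs
    }
    assignment: dict[str, str | None] = {}
    for acc in pt.leaf_ids():
        containing = [n for n, s in subtree.items() if acc in s]
        if not containing:
            assignment[acc] = None
        else:
            assignment[acc] = min(containing, key=lambda n: len(subtree[n]))
    return assignment, monophyletic


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unrooted symmetric (Robinson-Foulds) distance via split sets."""
    return len(_internal_bipartitions(a) ^ _internal_bipartitions(b))
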