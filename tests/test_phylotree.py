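"""Distances, neighbor-joining, bootstrap, rooting and Newick round-trip."""

import math

import dendropy
import numpy as np
import pytest

from mitovar import phylotree as pt
from mitovar import syndata
from mitovar.popstruct import DistanceMatrix
from mitovar.phylotree import (
    PhyloTree,
    SnpAlignment,
    bootstrap,
    clade_membership,
    neighbor_joining,
    pairwise_distance,
    robinson_foulds,
    root_with_outgroup,
)


def random_tree_distances(rng, n):
    """A random binary tree with random branch lengths and its additive
    leaf-to-leaf distance matrix (graph shortest paths)."""
    import networkx as nx

    g = nx.Graph()
    nodes = [f"t{i}" for i in range(n)]
    g.add_nodes_from(nodes)
    pool = list(nodes)
    nxt = 0
    while len(pool) > 1:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[j], pool[i]
        parent = f"i{nxt}"
        nxt += 1
        g.add_edge(parent, a, weight=float(rng.uniform(0.05, 1.0)))
        g.add_edge(parent, b, weight=float(rng.uniform(0.05, 1.0)))
        pool = [x for x in pool if x not in (a, b)] + [parent]
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    m = np.array([[lengths[a][b] for b in nodes] for a in nodes])
    np.fill_diagonal(m, 0.0)
    tree = dendropy.Tree.get(
        data=newick_from_graph(g, pool[0], nodes) + ";", schema="newick"
    )
    tree.is_rooted = False
    return DistanceMatrix(nodes, m), PhyloTree(tree)


def newick_from_graph(g, root, leaves, parent=None):
    children = [x for x in g.neighbors(root) if x != parent]
    if not children:
        return root
    inner = ",".join(newick_from_graph(g, c, leaves, root) for c in children)
    return f"({inner})" if parent is None else f"({inner})"


def naive_nj(D):
    """Loop-based Saitou-Nei oracle returning the merge sequence."""
    ids = list(D.ids)
    d = {(a, b): D.matrix[i, j] for i, a in enumerate(ids) for j, b in enumerate(ids)}
    active = list(ids)
    joins = []
    clade = {a: frozenset([a]) for a in ids}
    nxt = 0
    while len(active) > 3:
        m = len(active)
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1:]:
                ra = sum(d[(a, c)] for c in active)
                rb = sum(d[(b, c)] for c in active)
                q = (m - 2) * d[(a, b)] - ra - rb
                if best is None or q < best[0] - 1e-12:
                    best = (q, a, b)
        _, a, b = best
        new = f"n{nxt}"
        nxt += 1
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = 0.5 * (d[(a, c)] + d[(b, c)] - d[(a, b)])
        d[(new, new)] = 0.0
        clade[new] = clade[a] | clade[b]
        joins.append(clade[new])
        active = [c for c in active if c not in (a, b)] + [new]
    return joins


class TestPairwiseDistance:
    def test_identical_sequences_zero(self):
        aln = SnpAlignment(["a", "b"], ["ACGT", "ACGT"])
        for model in ("p", "JC69"):
            assert pairwise_distance(aln, model).matrix[0, 1] == 0.0

    def test_closed_form_quarter_difference(self):
        aln = SnpAlignment(["a", "b"], ["AAAA", "AAAG"])
        assert pairwise_distance(aln, "p").matrix[0, 1] == pytest.approx(0.25)
        jc = pairwise_distance(aln, "JC69").matrix[0, 1]
        assert jc == pytest.approx(-0.75 * math.log(1 - 1 / 3), abs=1e-4)

    def test_jc_dominates_p_distance(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            s1 = syndata.random_contig(60, seed=int(rng.integers(1e6)))
            s2 = syndata.random_contig(60, seed=int(rng.integers(1e6)))
            aln = SnpAlignment(["a", "b"], [s1, s2])
            p = pairwise_distance(aln, "p").matrix[0, 1]
            with np.errstate(all="ignore"):
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    jc = pairwise_distance(aln, "JC69").matrix[0, 1]
            assert jc >= p - 1e-12

    def test_saturated_pairs_clamped_with_warning(self):
        aln = SnpAlignment(["a", "b"], ["AAAA", "CCCC"])
        with pytest.warns(UserWarning, match="saturated"):
            d = pairwise_distance(aln, "JC69").matrix[0, 1]
        assert d == pt.JC_MAX_DISTANCE

    def test_zero_length_alignment_raises(self):
        with pytest.raises(ValueError):
            pairwise_distance(SnpAlignment(["a", "b"], ["", ""]))


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive distances
        m = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        m[3, 2] = 7
        m[2, 3] = 7
        D = DistanceMatrix(list("ABCD"), m)
        tree = neighbor_joining(D)
        splits = pt._internal_bipartitions(tree)
        allt = frozenset("ABCD")
        expect = frozenset("AB")
        expect = expect if min(allt) not in expect else allt - expect
        assert splits == {expect}
        # branch lengths: leaf edges 1,2,3,4 and internal edge 1
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"A": 1, "B": 2, "C": 3, "D": 4})

    def test_star_distances_zero_internal_branches(self):
        n = 6
        m = np.ones((n, n)) * 2 - 2 * np.eye(n)
        tree = neighbor_joining(DistanceMatrix([f"t{i}" for i in range(n)], m))
        for node in tree.tree.preorder_internal_node_iter(exclude_seed_node=True):
            assert node.edge.length == pytest.approx(0.0, abs=1e-12)

    def test_random_additive_trees_recovered(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            D, true_tree = random_tree_distances(rng, 8)
            est = neighbor_joining(D)
            assert robinson_foulds(est, true_tree) == 0

    def test_matches_naive_oracle_on_random_matrices(self):
        rng = np.random.default_rng(22)
        for _ in range(25):
            m = rng.random((8, 8))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            D = DistanceMatrix([f"t{i}" for i in range(8)], m)
            est = neighbor_joining(D)
            oracle_joins = {s for s in naive_nj(D) if 1 < len(s) < 7}
            allt = frozenset(D.ids)
            first = min(allt)
            oracle_splits = {
                s if first not in s else allt - s for s in oracle_joins
            }
            assert pt._internal_bipartitions(est) == oracle_splits

    def test_matches_dendropy_nj_on_additive_matrices(self):
        """Independent-library cross-check of the NJ topology at n=5."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            D, true_tree = random_tree_distances(rng, 5)
            est = neighbor_joining(D)
            pdm_csv = "," + ",".join(D.ids) + "\n" + "\n".join(
                D.ids[i] + "," + ",".join(str(x) for x in D.matrix[i])
                for i in range(5)
            )
            import io

            pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(
                io.StringIO(pdm_csv)
            )
            ref = pdm.nj_tree()
            ref_pt = PhyloTree(ref)
            assert robinson_foulds(est, ref_pt) == 0

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            neighbor_joining(
                DistanceMatrix(["a", "b"], np.array([[0.0, 1], [1, 0]]))
            )


class TestBootstrap:
    def test_uniform_signal_full_support(self):
        # every column splits {a,b} vs {c,d}
        aln = SnpAlignment(["a", "b", "c", "d"], ["AAAA", "AAAA", "GGGG", "GGGG"])
        tree = bootstrap(aln, n_reps=50, seed=1, model="p")
        assert list(tree.supports.values()) == [100.0]

    def test_same_seed_reproducible(self, small_snp_matrix):
        aln = SnpAlignment(
            small_snp_matrix.accession_ids,
            list(small_snp_matrix.sequences().values()),
        )
        t1 = bootstrap(aln, n_reps=10, seed=7)
        t2 = bootstrap(aln, n_reps=10, seed=7)
        assert t1.supports == t2.supports

    def test_strong_clades_highly_supported(self, small_cohort, small_snp_matrix):
        _, _, truth, _ = small_cohort
        aln = SnpAlignment(
            small_snp_matrix.accession_ids,
            list(small_snp_matrix.sequences().values()),
        )
        # p-distances: the compact cohort's SNP-only columns sit close to
        # the JC69 saturation clamp, which is not the property under test
        tree = bootstrap(aln, n_reps=100, seed=3, model="p")
        allt = frozenset(aln.ids)
        first = min(allt)
        for members in truth.clades().values():
            s = frozenset(members)
            key = s if first not in s else allt - s
            assert tree.supports[key] >= 95.0


class TestRootingAndClades:
    def test_outgroup_rooting_separates_outgroup(self, small_cfg, small_cohort):
        reference, haplotypes, truth, _ = small_cohort
        og = syndata.make_outgroup_haplotype(reference, truth, small_cfg, n_snps=60)
        haps = dict(haplotypes)
        haps["OUTGROUP"] = og
        # build alignment directly from haplotype columns that vary
        L = len(reference)
        cols = [i for i in range(L) if len({h[i] for h in haps.values()}) > 1]
        aln = SnpAlignment(
            list(haps), ["".join(h[i] for i in cols) for h in haps.values()]
        )
        tree = pt.nj_tree(aln)
        rooted = root_with_outgroup(tree, "OUTGROUP")
        children = rooted.tree.seed_node.child_nodes()
        sides = [pt.leafset(c) for c in children]
        assert frozenset(["OUTGROUP"]) in sides

    def test_missing_outgroup_raises(self):
        aln = SnpAlignment(["a", "b", "c"], ["AA", "AG", "GG"])
        tree = pt.nj_tree(aln, model="p")
        with pytest.raises(ValueError):
            root_with_outgroup(tree, "nope")

    def test_clade_membership_monophyletic(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        tree.tree.is_rooted = True
        assign, mono = clade_membership(
            tree, {"left": {"a", "b"}, "right": {"c", "d"}}
        )
        assert assign == {"a": "left", "b": "left", "c": "right", "d": "right"}
        assert mono == {"left": True, "right": True}

    def test_spanning_exemplars_flagged(self):
        tree = PhyloTree.from_newick("((a:1,b:1):1,(c:1,d:1):1);")
        tree.tree.is_rooted = True
        _, mono = clade_membership(tree, {"bad": {"a", "c"}, "ok": {"b"}})
        assert mono["bad"] is False


class TestNewickRoundTrip:
    def test_topology_lengths_supports_preserved(self, small_snp_matrix):
        aln = SnpAlignment(
            small_snp_matrix.accession_ids,
            list(small_snp_matrix.sequences().values()),
        )
        tree = bootstrap(aln, n_reps=10, seed=9)
        text = tree.to_newick()
        back = PhyloTree.from_newick(text)
        assert robinson_foulds(tree, back) == 0
        orig = {
            lf.taxon.label: lf.edge.length for lf in tree.tree.leaf_node_iter()
        }
        rt = {lf.taxon.label: lf.edge.length for lf in back.tree.leaf_node_iter()}
        for k in orig:
            assert rt[k] == pytest.approx(orig[k], abs=1e-10)
        assert back.supports == tree.supports
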