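"""Unit tests for distance matrices, NJ/UPGMA, bootstrap, and clustering."""

import numpy as np
import pytest

from mapkevo import trees_cluster as tc
from mapkevo.io_formats import ExpressionMatrix, SequenceRecord, write_newick


def records(pairs):
    return [SequenceRecord(i, s, "protein") for i, s in pairs]


class TestDistanceMatrix:
    def test_valid(self):
        tc.DistanceMatrix(["a", "b"], [[0, 1], [1, 0]])

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            tc.DistanceMatrix(["a"], [[0, 1], [1, 0]])

    def test_asymmetric(self):
        with pytest.raises(ValueError, match="symmetric"):
            tc.DistanceMatrix(["a", "b"], [[0, 1], [2, 0]])

    def test_nonzero_diagonal(self):
        with pytest.raises(ValueError, match="diagonal"):
            tc.DistanceMatrix(["a", "b"], [[1, 1], [1, 0]])

    def test_negative(self):
        with pytest.raises(ValueError, match="negative"):
            tc.DistanceMatrix(["a", "b"], [[0, -1], [-1, 0]])


class TestProteinDistance:
    def test_p_distance(self):
        dm = tc.protein_distance(records([("a", "MKVL"), ("b", "MKIL")]))
        assert dm.d[0, 1] == pytest.approx(0.25)

    def test_gap_columns_skipped_per_pair(self):
        dm = tc.protein_distance(records([("a", "MKVL"), ("b", "MK-L")]))
        assert dm.d[0, 1] == 0.0

    def test_poisson_correction(self):
        dm = tc.protein_distance(
            records([("a", "MKVL"), ("b", "MKIL")]), model="poisson"
        )
        assert dm.d[0, 1] == pytest.approx(-np.log(0.75))

    def test_all_gap_pair_rejected(self):
        with pytest.raises(ValueError, match="ungapped"):
            tc.protein_distance(records([("a", "MK--"), ("b", "--VL")]))

    def test_unknown_model(self):
        with pytest.raises(ValueError, match="model"):
            tc.protein_distance(records([("a", "MK"), ("b", "MK")]), model="jc")


def random_additive_matrix(rng, n):
    """Independent construction of an additive matrix from a random binary
    tree with branch lengths in [0.1, 1.0]."""
    # each cluster: (leaf set, {leaf: distance to cluster root})
    clusters = [({i}, {i: 0.0}) for i in range(n)]
    dist = np.zeros((n, n))
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        (set_i, up_i), (set_j, up_j) = clusters[i], clusters[j]
        bi, bj = rng.uniform(0.1, 1.0, size=2)
        for a in set_i:
            for b in set_j:
                dist[a, b] = dist[b, a] = up_i[a] + bi + up_j[b] + bj
        merged = {a: d + bi for a, d in up_i.items()}
        merged.update({b: d + bj for b, d in up_j.items()})
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append((set_i | set_j, merged))
    return dist


class TestNjTree:
    def test_exact_on_additive_matrix(self):
        rng = np.random.default_rng(42)
        for _ in range(10):
            n = int(rng.integers(4, 8))
            d = random_additive_matrix(rng, n)
            labels = [f"t{i}" for i in range(n)]
            tree = tc.nj_tree(tc.DistanceMatrix(labels, d))
            coph = tc.cophenetic_matrix(tree, labels)
            assert np.allclose(coph, d, atol=1e-9)

    def test_three_taxa(self):
        d = np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
        tree = tc.nj_tree(tc.DistanceMatrix(["a", "b", "c"], d))
        coph = tc.cophenetic_matrix(tree, ["a", "b", "c"])
        assert np.allclose(coph, d)

    def test_unrooted(self):
        d = random_additive_matrix(np.random.default_rng(0), 5)
        tree = tc.nj_tree(tc.DistanceMatrix([f"t{i}" for i in range(5)], d))
        assert not tree.is_rooted

    def test_negative_branches_clamped(self):
        # non-additive matrix that produces a negative NJ branch estimate
        d = np.array(
            [
                [0, 0.1, 0.6, 0.6],
                [0.1, 0, 0.6, 0.6],
                [0.6, 0.6, 0, 0.05],
                [0.6, 0.6, 0.05, 0],
            ]
        )
        tree = tc.nj_tree(tc.DistanceMatrix(["a", "b", "c", "d"], d))
        for edge in tree.preorder_edge_iter():
            if edge.length is not None:
                assert edge.length >= 0

    def test_too_few_labels(self):
        with pytest.raises(ValueError, match=">= 3"):
            tc.nj_tree(tc.DistanceMatrix(["a", "b"], [[0, 1], [1, 0]]))


class TestUpgmaTree:
    def test_three_taxon_worked_example(self):
        # d(a,b)=2, d(a,c)=d(b,c)=4 -> ((a:1,b:1):1,c:2)
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = tc.upgma_tree(tc.DistanceMatrix(["a", "b", "c"], d))
        assert tree.is_rooted
        depths = {}
        for leaf in tree.leaf_node_iter():
            depth = 0.0
            node = leaf
            while node.parent_node is not None:
                depth += node.edge.length
                node = node.parent_node
            depths[leaf.taxon.label] = depth
        assert depths == pytest.approx({"a": 2.0, "b": 2.0, "c": 2.0})
        coph = tc.cophenetic_matrix(tree, ["a", "b", "c"])
        assert np.allclose(coph, d)

    def test_ultrametric_on_random_input(self):
        rng = np.random.default_rng(3)
        n = 6
        x = rng.uniform(0.2, 1.0, size=(n, n))
        d = (x + x.T) / 2
        np.fill_diagonal(d, 0.0)
        tree = tc.upgma_tree(tc.DistanceMatrix([f"t{i}" for i in range(n)], d))
        depths = []
        for leaf in tree.leaf_node_iter():
            depth, node = 0.0, leaf
            while node.parent_node is not None:
                depth += node.edge.length
                node = node.parent_node
            depths.append(depth)
        assert np.allclose(depths, depths[0])


class TestBipartitionsAndOverlap:
    def trees(self):
        from mapkevo.io_formats import read_newick

        t1 = read_newick("((a,b),(c,d),(e,f));")
        t2 = read_newick("((a,b),((c,d),(e,f)));")
        t3 = read_newick("((a,c),(b,d),(e,f));")
        return t1, t2, t3

    def test_bipartitions_canonical(self):
        t1, _, _ = self.trees()
        splits = tc.tree_bipartitions(t1)
        assert frozenset({"c", "d"}) in splits
        assert frozenset({"e", "f"}) in splits
        # the {a,b} side contains the anchor "a": represented by complement
        assert frozenset({"c", "d", "e", "f"}) in splits

    def test_identical_topologies_full_overlap(self):
        t1, t2, _ = self.trees()
        shared, norm = tc.topology_overlap(t1, t2)
        assert shared == 3
        assert norm == pytest.approx(1.0)

    def test_partial_overlap(self):
        t1, _, t3 = self.trees()
        shared, norm = tc.topology_overlap(t1, t3)
        assert shared == 1  # only {e,f}
        assert norm == pytest.approx(1 / 3)

    def test_small_trees_overlap_one(self):
        from mapkevo.io_formats import read_newick

        a = read_newick("(a,b,c);")
        b = read_newick("((a,b),c);")
        assert tc.topology_overlap(a, b) == (0, 1.0)

    def test_leaf_set_mismatch(self):
        from mapkevo.io_formats import read_newick

        with pytest.raises(ValueError, match="leaf"):
            tc.topology_overlap(read_newick("(a,b,c);"), read_newick("(a,b,d);"))


def two_clade_alignment():
    """Six taxa, two clades separated by 30 fixed columns, plus per-taxon
    private columns (zero homoplasy)."""
    n_clade_cols = 30
    taxa = ["a1", "a2", "a3", "b1", "b2", "b3"]
    length = n_clade_cols + 2 * len(taxa)
    rows = {}
    for k, t in enumerate(taxa):
        clade_char = "A" if t.startswith("a") else "C"
        row = [clade_char] * n_clade_cols + ["G"] * (2 * len(taxa))
        row[n_clade_cols + 2 * k] = "W"
        row[n_clade_cols + 2 * k + 1] = "W"
        rows[t] = "".join(row)
    assert all(len(r) == length for r in rows.values())
    return records(sorted(rows.items()))


class TestBootstrap:
    def test_deterministic_given_seed(self):
        aln = two_clade_alignment()
        t1 = tc.bootstrap_support(aln, n_reps=25, seed=5)
        t2 = tc.bootstrap_support(aln, n_reps=25, seed=5)
        assert write_newick(t1) == write_newick(t2)

    def test_clade_split_supported(self):
        aln = two_clade_alignment()
        tree = tc.bootstrap_support(aln, n_reps=50, seed=1)
        all_leaves = frozenset(l.taxon.label for l in tree.leaf_node_iter())
        target = frozenset({"b1", "b2", "b3"})
        found = False
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node is tree.seed_node:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            if side in (target, all_leaves - target):
                found = True
                assert node.label == "100"
        assert found

    def test_bad_builder(self):
        with pytest.raises(ValueError, match="builder"):
            tc.bootstrap_support(two_clade_alignment(), tree_builder="ml")


class TestExpressionCluster:
    def test_recovers_planted_clusters(self):
        from mapkevo import synthetic_data as sd

        cluster_map = {f"g{i}": ("c1" if i < 4 else "c2") for i in range(8)}
        matrix = sd.simulate_expression(8, 20, cluster_map, seed=9)
        tree = tc.expression_cluster(matrix)
        splits = tc.tree_bipartitions(tree)
        c2 = frozenset(g for g, c in cluster_map.items() if c == "c2")
        assert c2 in splits  # anchor g0 is in c1, so c2 is the canonical side

    def test_constant_gene_rejected(self):
        m = ExpressionMatrix(
            ["g1", "g2"], ["s1", "s2", "s3"], [[1.0, 1.0, 1.0], [1, 2, 3]]
        )
        with pytest.raises(ValueError, match="g1"):
            tc.expression_cluster(m)
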