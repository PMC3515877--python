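"""Distance-based trees: neighbor joining with bootstrap, UPGMA, expression
dendrograms under the 1 - Pearson correlation distance, and tree-vs-tree
topology comparison by shared bipartitions.

Trees are dendropy Tree objects throughout; bootstrap supports are stored
as internal node labels (percentage of replicates containing the same leaf
bipartition), the convention io_formats uses for Newick round-trips.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "DistanceMatrix",
    "protein_distance",
    "nj_tree",
    "upgma_tree",
    "bootstrap_support",
    "expression_cluster",
    "topology_overlap",
    "tree_bipartitions",
    "cophenetic_matrix",
]


@dataclass
class DistanceMatrix:
    labels: list
    d: np.ndarray

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal not zero")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")


def protein_distance(alignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise distances over shared non-gap columns of a protein alignment.

    ``p_distance`` is the mismatch proportion; ``poisson`` applies
    d = -ln(1 - p).  A pair with zero shared (non-gap) columns raises.
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown model {model!r}")
    labels = [rec.id for rec in alignment]
    rows = [rec.seq.upper() for rec in alignment]
    if len({len(r) for r in rows}) != 1:
        raise ValueError("ragged alignment")
    n = len(rows)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = mism = 0
            for a, b in zip(rows[i], rows[j]):
                if a == "-" or b == "-":
                    continue
                shared += 1
                mism += a != b
            if shared == 0:
                raise ValueError(
                    f"pair ({labels[i]}, {labels[j]}) shares no ungapped columns"
                )
            p = mism / shared
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("saturated pair under poisson model")
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=labels, d=d)


def _new_tree(labels) -> tuple:
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    return tree, taxa


class _Cluster:
    """Active cluster during agglomeration; ``key`` is the smallest original
    leaf label it contains, used for deterministic tie-breaking."""

    __slots__ = ("node", "key", "size", "height")

    def __init__(self, node, key, size=1, height=0.0):
        self.node = node
        self.key = key
        self.size = size
        self.height = height


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Ties in the Q criterion are broken by the smallest (label, label) pair.
    Negative branch lengths are clamped to zero with the deficit moved to
    the sister branch, preserving their sum.
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("NJ needs >= 3 labels")
    tree, taxa = _new_tree(dm.labels)
    clusters = []
    for label in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        clusters.append(_Cluster(node, label))
    d = {
        (i, j): float(dm.d[i, j])
        for i in range(n)
        for j in range(n)
    }
    active = list(range(n))
    next_id = n

    def dist(i, j):
        return d[(i, j)] if (i, j) in d else d[(j, i)]

    cl = {i: clusters[i] for i in range(n)}
    while len(active) > 2:
        m = len(active)
        r = {i: sum(dist(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * dist(i, j) - r[i] - r[j]
                pair_key = tuple(sorted((cl[i].key, cl[j].key)))
                cand = (q, pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        _, _, i, j = best
        dij = dist(i, j)
        bi = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2)) if m > 2 else 0.5 * dij
        bj = dij - bi
        if bi < 0:
            bj += bi
            bi = 0.0
        if bj < 0:
            bi += bj
            bj = 0.0
        bi, bj = max(bi, 0.0), max(bj, 0.0)
        parent = dendropy.Node()
        parent.add_child(cl[i].node)
        parent.add_child(cl[j].node)
        cl[i].node.edge.length = bi
        cl[j].node.edge.length = bj
        new = _Cluster(parent, min(cl[i].key, cl[j].key))
        u = next_id
        next_id += 1
        cl[u] = new
        for k in active:
            if k in (i, j):
                continue
            d[(u, k)] = 0.5 * (dist(i, k) + dist(j, k) - dij)
        active = [k for k in active if k not in (i, j)] + [u]
    # join the last two clusters at the (unrooted) seed
    i, j = active
    dij = dist(i, j)
    root = tree.seed_node
    if cl[i].node.is_leaf() and cl[j].node.is_leaf():
        root.add_child(cl[i].node)
        root.add_child(cl[j].node)
        cl[i].node.edge.length = dij / 2
        cl[j].node.edge.length = dij / 2
    else:
        # attach the smaller cluster onto the larger's root
        inner, outer = (i, j) if not cl[i].node.is_leaf() else (j, i)
        root = cl[inner].node
        root.add_child(cl[outer].node)
        cl[outer].node.edge.length = dij
        tree.seed_node = root
    tree.is_rooted = False
    return tree


def upgma_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Average-linkage (size-weighted) agglomeration; merge height d/2.

    Output is rooted and ultrametric; ties are broken by the smallest label
    pair.
    """
    n = len(dm.labels)
    if n < 2:
        raise ValueError("UPGMA needs >= 2 labels")
    tree, taxa = _new_tree(dm.labels)
    cl = {}
    for i, label in enumerate(dm.labels):
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        cl[i] = _Cluster(node, label, size=1, height=0.0)
    d = {(i, j): float(dm.d[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n

    def dist(i, j):
        return d[(i, j)] if (i, j) in d else d[(j, i)]

    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                pair_key = tuple(sorted((cl[i].key, cl[j].key)))
                cand = (dist(i, j), pair_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dij, _, i, j = best
        height = dij / 2.0
        parent = dendropy.Node()
        parent.add_child(cl[i].node)
        parent.add_child(cl[j].node)
        cl[i].node.edge.length = max(height - cl[i].height, 0.0)
        cl[j].node.edge.length = max(height - cl[j].height, 0.0)
        size = cl[i].size + cl[j].size
        u = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            d[(u, k)] = (
                cl[i].size * dist(i, k) + cl[j].size * dist(j, k)
            ) / size
        cl[u] = _Cluster(parent, min(cl[i].key, cl[j].key), size=size, height=height)
        active = [k for k in active if k not in (i, j)] + [u]
    tree.seed_node = cl[active[0]].node
    tree.is_rooted = True
    return tree


def _leaf_labels(node) -> frozenset:
    return frozenset(lf.taxon.label for lf in node.leaf_iter())


def tree_bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial unrooted bipartitions as canonical frozensets of labels.

    Each split is represented by the side NOT containing the
    lexicographically smallest leaf label.
    """
    all_leaves = _leaf_labels(tree.seed_node)
    anchor = min(all_leaves)
    splits = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = _leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            splits.add(side)
    return splits


def topology_overlap(tree_a: dendropy.Tree, tree_b: dendropy.Tree) -> tuple:
    """Shared non-trivial bipartition count and normalized overlap in [0, 1].

    Normalization is by n - 3, the number of non-trivial splits of a fully
    resolved unrooted tree on n leaves; trees on 3 or fewer leaves have a
    single topology and overlap 1 by convention.
    """
    leaves_a = _leaf_labels(tree_a.seed_node)
    leaves_b = _leaf_labels(tree_b.seed_node)
    if leaves_a != leaves_b:
        raise ValueError("trees have different leaf sets")
    n = len(leaves_a)
    if n <= 3:
        return 0, 1.0
    shared = tree_bipartitions(tree_a) & tree_bipartitions(tree_b)
    return len(shared), len(shared) / (n - 3)


def cophenetic_matrix(tree: dendropy.Tree, labels) -> np.ndarray:
    """Leaf-to-leaf path-length matrix, in the order of ``labels``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return out


def bootstrap_support(alignment, tree_builder: str = "nj", n_reps: int = 100,
                      seed: int = 0, model: str = "p_distance") -> dendropy.Tree:
    """Bootstrap a distance tree by resampling alignment columns.

    The main tree is built from the full alignment; each internal edge's
    support is the percentage of replicate trees containing the same leaf
    bipartition, written as the node label.  Deterministic given ``seed``.
    """
    from .io_formats import SequenceRecord

    if tree_builder not in ("nj", "upgma"):
        raise ValueError(f"unknown tree builder {tree_builder!r}")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    build = nj_tree if tree_builder == "nj" else upgma_tree
    main = build(protein_distance(alignment, model))
    rng = np.random.default_rng(seed)
    length = len(alignment[0].seq)
    rows = [rec.seq.upper() for rec in sorted(alignment, key=lambda r: r.id)]
    ids = [rec.id for rec in sorted(alignment, key=lambda r: r.id)]
    counts: dict = {}
    for _ in range(n_reps):
        cols = rng.integers(0, length, size=length)
        reps = [
            SequenceRecord(i, "".join(row[c] for c in cols), "protein")
            for i, row in zip(ids, rows)
        ]
        try:
            rep_tree = build(protein_distance(reps, model))
        except ValueError:
            continue  # e.g. fully gapped resample
        for split in tree_bipartitions(rep_tree):
            counts[split] = counts.get(split, 0) + 1
    all_leaves = _leaf_labels(main.seed_node)
    anchor = min(all_leaves)
    for node in main.preorder_node_iter():
        if node is main.seed_node or node.is_leaf():
            continue
        side = _leaf_labels(node)
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            support = 100.0 * counts.get(side, 0) / n_reps
            node.label = f"{support:g}"
    return main


def expression_cluster(matrix) -> dendropy.Tree:
    """UPGMA dendrogram of genes under distance = 1 - Pearson correlation.

    A constant expression profile has no defined correlation and raises,
    naming the gene.
    """
    values = np.asarray(matrix.values, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need >= 2 genes")
    if values.shape[1] < 2:
        raise ValueError("need >= 2 samples (correlation undefined)")
    sds = values.std(axis=1)
    for gene, sd in zip(matrix.gene_ids, sds):
        if sd == 0:
            raise ValueError(f"gene {gene!r} has a constant expression profile")
    corr = np.corrcoef(values)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return upgma_tree(DistanceMatrix(labels=list(matrix.gene_ids), d=d))
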