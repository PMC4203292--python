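"""Neighbor joining, bootstrap supports, monophyly scoring."""

import numpy as np
import pytest

from oracles import (
    additive_matrix_from_topology,
    all_topologies,
    ls_residual,
    topology_bipartitions,
)

from barcodegap.distances import DistanceMatrix, SaturationError, pairwise_matrix
from barcodegap.io import BarcodeAlignment, TaxonomyMap, TaxonRecord
from barcodegap.nj import bootstrap_supports, monophyly_report, nj_tree


def dm(ids, values):
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(list(ids), v, np.zeros_like(v))


def test_two_taxa_single_edge():
    t = nj_tree(dm(["X", "Y"], [[0, 0.4], [0.4, 0]]))
    assert sorted(t.leaves()) == ["X", "Y"]
    assert t.total_length() == pytest.approx(0.4)


def test_additive_four_taxon_matrix_recovers_generating_tree():
    # generating tree: A-1, B-2 off one hub; C-3, D-4 off the other;
    # internal edge 1 => the classic 4x4 additive matrix below
    ids = ["A", "B", "C", "D"]
    V = [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]]
    t = nj_tree(dm(ids, V))
    assert t.bipartitions() == {frozenset({"C", "D"})}  # == AB|CD
    assert t.total_length() == pytest.approx(11.0)
    # leaf branch lengths recovered exactly
    leaf_len = {}

    def walk(node):
        for child, length in node.children:
            if child.is_leaf:
                leaf_len[child.name] = length
            walk(child)

    walk(t.root)
    assert leaf_len == pytest.approx({"A": 1.0, "B": 2.0, "C": 3.0, "D": 4.0})


def test_ultrametric_two_cluster_matrix_yields_sister_clades():
    # clusters {A,B} at 0.1 and {C,D,E} at 0.1, separated by 1.0
    ids = list("ABCDE")
    V = np.full((5, 5), 1.0)
    for i in range(5):
        V[i, i] = 0.0
    for i, j in [(0, 1), (2, 3), (2, 4), (3, 4)]:
        V[i, j] = V[j, i] = 0.1
    t = nj_tree(dm(ids, V))
    assert frozenset("CDE") in t.bipartitions()


@pytest.mark.parametrize("n_leaves", [4, 5, 6])
def test_nj_vs_exhaustive_topology_search_on_additive_matrices(n_leaves):
    """NJ must select the unique topology with zero least-squares residual."""
    rng = np.random.default_rng(100 + n_leaves)
    labels = [f"L{i}" for i in range(n_leaves)]
    topologies = all_topologies(labels)
    for rep in range(5):
        true = topologies[int(rng.integers(len(topologies)))]
        D = additive_matrix_from_topology(true, labels, rng)
        residuals = [ls_residual(t, labels, D) for t in topologies]
        best = topologies[int(np.argmin(residuals))]
        assert min(residuals) < 1e-9
        nj_bps = nj_tree(dm(labels, D)).bipartitions()
        assert nj_bps == topology_bipartitions(best)


@pytest.mark.parametrize("n_leaves", [7, 8])
def test_nj_recovers_generating_topology(n_leaves):
    rng = np.random.default_rng(55 + n_leaves)
    labels = [f"L{i}" for i in range(n_leaves)]
    full = all_topologies(labels)
    true = full[int(rng.integers(len(full)))]
    D = additive_matrix_from_topology(true, labels, rng)
    assert nj_tree(dm(labels, D)).bipartitions() == topology_bipartitions(true)


def test_nj_matches_scikit_bio_on_random_matrices():
    """Independent cross-check against an established NJ implementation."""
    skbio = pytest.importorskip("skbio")
    from skbio.tree import nj as skbio_nj

    rng = np.random.default_rng(7)
    for rep in range(5):
        labels = [f"t{i}" for i in range(7)]
        full = all_topologies(labels)
        true = full[int(rng.integers(len(full)))]
        D = additive_matrix_from_topology(true, labels, rng)
        D = D + rng.uniform(0, 0.01, D.shape)  # generic: no exact ties
        D = (D + D.T) / 2.0
        np.fill_diagonal(D, 0.0)
        ours = nj_tree(dm(labels, D)).bipartitions()
        sk_tree = skbio_nj(skbio.DistanceMatrix(D, labels))
        ref = min(labels)
        theirs = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            canon = frozenset(labels) - side if ref in side else side
            if 2 <= len(canon) <= len(labels) - 2:
                theirs.add(canon)
        assert ours == theirs


def test_order_invariance_up_to_isomorphism():
    rng = np.random.default_rng(3)
    labels = [f"s{i}" for i in range(6)]
    full = all_topologies(labels)
    true = full[int(rng.integers(len(full)))]
    D = additive_matrix_from_topology(true, labels, rng)
    bps = nj_tree(dm(labels, D)).bipartitions()
    perm = [4, 2, 0, 5, 1, 3]
    D2 = D[np.ix_(perm, perm)]
    bps2 = nj_tree(dm([labels[i] for i in perm], D2)).bipartitions()
    assert bps == bps2


def test_saturated_matrix_is_refused():
    V = np.array([[0, np.nan], [np.nan, 0]])
    with pytest.raises(SaturationError, match="exclude"):
        nj_tree(DistanceMatrix(["a", "b"], V, np.zeros_like(V)))


def test_bootstrap_clean_signal_gets_full_support():
    # every informative column separates the same two clusters, so no
    # (non-degenerate) resample can break the cluster edge
    a = "ACGT" * 10
    b_chars = list(a)
    for pos in range(0, 40, 4):  # 10 A->G transitions
        b_chars[pos] = "G"
    b = "".join(b_chars)
    aln = BarcodeAlignment(
        ["a1", "a2", "a3", "b1", "b2", "b3"], [a, a, a, b, b, b]
    )
    t = bootstrap_supports(aln, n_replicates=30, seed=1)
    supports = {}

    def walk(node):
        for child, _ in node.children:
            if not child.is_leaf and child.support is not None:
                leaves = frozenset(
                    n.name for n, _ in _leaf_iter(child)
                )
                supports[leaves] = child.support
            walk(child)

    def _leaf_iter(node):
        if node.is_leaf:
            yield node, 0
        for c, _ in node.children:
            yield from _leaf_iter(c)

    walk(t.root)
    cluster_edges = [
        s for leaves, s in supports.items()
        if leaves in (frozenset({"a1", "a2", "a3"}), frozenset({"b1", "b2", "b3"}))
    ]
    assert cluster_edges and all(s == 100 for s in cluster_edges)


def test_bootstrap_is_deterministic_given_seed(fixtures):
    aln, _ = fixtures["two_clusters"]
    t1 = bootstrap_supports(aln, n_replicates=25, seed=9)
    t2 = bootstrap_supports(aln, n_replicates=25, seed=9)
    assert t1.to_newick() == t2.to_newick()
    t3 = bootstrap_supports(aln, n_replicates=25, seed=10)
    assert sorted(t3.leaves()) == sorted(t1.leaves())


def test_monophyly_on_hand_built_tree():
    # 5 leaves: species X = {x1, x2} split apart by y1 -> not monophyletic
    ids = ["x1", "y1", "x2", "z1", "z2"]
    V = np.array(
        [
            [0.0, 0.1, 0.4, 0.8, 0.8],
            [0.1, 0.0, 0.4, 0.8, 0.8],
            [0.4, 0.4, 0.0, 0.8, 0.8],
            [0.8, 0.8, 0.8, 0.0, 0.1],
            [0.8, 0.8, 0.8, 0.1, 0.0],
        ]
    )
    tree = nj_tree(dm(ids, V))
    tax = TaxonomyMap(
        {
            "x1": TaxonRecord("X", "gX", "F"),
            "x2": TaxonRecord("X", "gX", "F"),
            "y1": TaxonRecord("Y", "gY", "F"),
            "z1": TaxonRecord("Z", "gZ", "F"),
            "z2": TaxonRecord("Z", "gZ", "F"),
        }
    )
    rep = monophyly_report(tree, tax, "species")
    assert rep.status == {"X": False, "Y": True, "Z": True}
    assert rep.n_total == 3 and rep.n_monophyletic == 2
    assert rep.ratio == pytest.approx(100 * 2 / 3)
    # exhaustive check: X's specimen set appears on no edge side
    sides = set()
    for _, s in tree._edge_sides():
        sides.add(s)
        sides.add(frozenset(ids) - s)
    assert frozenset({"x1", "x2"}) not in sides


def test_singletons_count_as_monophyletic():
    base = "ACGT" * 8
    seqs = [base]
    for pos in (0, 1, 2):  # three distinct single-transition variants
        chars = list(base)
        chars[pos] = {"A": "G", "C": "T", "G": "A"}[chars[pos]]
        seqs.append("".join(chars))
    aln = BarcodeAlignment([f"s{i}" for i in range(4)], seqs)
    tax = TaxonomyMap(
        {f"s{i}": TaxonRecord(f"sp{i}", f"g{i}", "F") for i in range(4)}
    )
    rep = monophyly_report(nj_tree(pairwise_matrix(aln)), tax, "species")
    assert rep.ratio == 100.0


def test_unknown_rank_is_rejected(fixtures):
    aln, tax = fixtures["two_clusters"]
    tree = nj_tree(pairwise_matrix(aln))
    with pytest.raises(ValueError, match="rank"):
        monophyly_report(tree, tax, "family")
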