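"""Automatic-gap partitioning: gap detection, partitions, concordance."""

import numpy as np
import pytest

from barcodegap.abgd import (
    AbgdConfig,
    Partition,
    find_gap,
    initial_partition,
    partition_concordance,
    partition_grid,
    recursive_partition,
)
from barcodegap.distances import DistanceMatrix, pairwise_matrix
from barcodegap.io import TaxonomyMap, TaxonRecord


def dm(ids, values):
    v = np.asarray(values, dtype=float)
    return DistanceMatrix(list(ids), v, np.zeros_like(v))


def test_find_gap_locates_the_wide_jump():
    vals = [0.0, 0.002, 0.003, 0.10, 0.11, 0.12]
    t = find_gap(vals, prior_p=0.02, relative_gap_width=1.5)
    assert t is not None and 0.003 < t < 0.10
    # brute check: of all candidate jumps (upper value above the prior),
    # only the cross-cluster one is wide relative to the spacing below it
    v = sorted(vals)
    qualifying = []
    for i in range(len(v) - 1):
        if v[i + 1] <= 0.02 or v[i + 1] == v[i]:
            continue
        slope = (v[i] - v[0]) / i if i else 0.0
        if v[i + 1] - v[i] > 1.5 * slope:
            qualifying.append((v[i], v[i + 1]))
    assert qualifying[0] == (0.003, 0.10)


def test_find_gap_absence_is_none():
    assert find_gap([0.05] * 6, prior_p=0.01) is None          # all identical
    assert find_gap([0.01, 0.02, 0.03], prior_p=0.5) is None   # prior above max
    with pytest.raises(ValueError):
        find_gap([], prior_p=0.01)


def test_initial_partition_two_clusters_by_hand():
    # 2+2 specimens, intra 0.005, inter 0.2: components computed by hand
    V = [
        [0.0, 0.005, 0.2, 0.2],
        [0.005, 0.0, 0.2, 0.2],
        [0.2, 0.2, 0.0, 0.005],
        [0.2, 0.2, 0.005, 0.0],
    ]
    p = initial_partition(dm(["a1", "a2", "b1", "b2"], V), prior_p=0.02)
    assert p.n_groups == 2
    assert set(p.groups) == {frozenset({"a1", "a2"}), frozenset({"b1", "b2"})}


def test_identical_sequences_give_one_group():
    V = np.zeros((3, 3))
    p = initial_partition(dm(list("abc"), V), prior_p=0.01)
    assert p.n_groups == 1


def test_recursive_splits_heterogeneous_group():
    """Constructed case: A and B merge at the global gap (the ranked curve
    below their separation is too even for the width rule) but separate
    on the local re-search; C stays whole.  Hand-derived: globally the
    ranked values 0.004, 0.008, 0.012 rise too evenly for the 1.5x rule
    until the far jump to 0.2, so the threshold (~0.108) merges A and B;
    inside A+B the jump 0.008 -> 0.016 is wide relative to 0.004 -> 0.008
    and splits them.  Initial = 2 groups {A+B},{C}; recursive = 3."""
    ids = ["a1", "a2", "b1", "b2", "c1", "c2"]
    n = len(ids)
    V = np.full((n, n), 0.2)
    def setd(x, y, d):
        i, j = ids.index(x), ids.index(y)
        V[i, j] = V[j, i] = d
    np.fill_diagonal(V, 0.0)
    setd("a1", "a2", 0.004)
    setd("b1", "b2", 0.008)
    for a in ("a1", "a2"):
        for b in ("b1", "b2"):
            setd(a, b, 0.016)
    setd("c1", "c2", 0.012)
    matrix = dm(ids, V)
    init = initial_partition(matrix, prior_p=0.01)
    rec = recursive_partition(matrix, prior_p=0.01)
    assert set(init.groups) == {
        frozenset({"a1", "a2", "b1", "b2"}),
        frozenset({"c1", "c2"}),
    }
    assert set(rec.groups) == {
        frozenset({"a1", "a2"}),
        frozenset({"b1", "b2"}),
        frozenset({"c1", "c2"}),
    }


def test_no_substructure_means_recursive_equals_initial(fixtures):
    aln, _ = fixtures["two_clusters"]
    matrix = pairwise_matrix(aln)
    for prior in (0.01, 0.02, 0.04):
        init = initial_partition(matrix, prior)
        rec = recursive_partition(matrix, prior)
        assert set(init.groups) == set(rec.groups)


def test_recursive_refines_initial_on_random_matrices():
    """Refinement property over 100 random matrices: every recursive
    group is a subset of an initial group, hence counts never shrink."""
    rng = np.random.default_rng(99)
    for rep in range(100):
        n = int(rng.integers(4, 12))
        tri = rng.uniform(0, 0.3, size=(n, n))
        V = np.triu(tri, 1)
        V = V + V.T
        ids = [f"s{i}" for i in range(n)]
        matrix = dm(ids, V)
        prior = float(rng.uniform(0.001, 0.1))
        init = initial_partition(matrix, prior)
        rec = recursive_partition(matrix, prior)
        assert rec.n_groups >= init.n_groups
        for g in rec.groups:
            assert any(g <= G for G in init.groups)
        # true set-partitions in both modes
        for p in (init, rec):
            members = [s for grp in p.groups for s in grp]
            assert sorted(members) == sorted(ids)


def test_grid_priors_match_geometric_sequence():
    cfg = AbgdConfig(p_min=0.001, p_max=0.1, steps=10)
    got = cfg.prior_grid()
    expected = [0.0010, 0.0017, 0.0028, 0.0046, 0.0077,
                0.0129, 0.0215, 0.0359, 0.0599, 0.1000]
    assert np.allclose(np.round(got, 4), expected)


def test_group_counts_non_increasing_in_prior(fixtures):
    aln, _ = fixtures["two_clusters"]
    parts = partition_grid(pairwise_matrix(aln))
    counts = [p.n_groups for p in parts if p.mode == "initial"]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    # the coarsest prior can never beat the finest one
    assert counts[-1] <= counts[0]


def test_concordance_counts():
    tax = TaxonomyMap(
        {
            "a1": TaxonRecord("A", "g", "f"),
            "a2": TaxonRecord("A", "g", "f"),
            "b1": TaxonRecord("B", "g", "f"),
            "b2": TaxonRecord("B", "g", "f"),
        }
    )
    perfect = Partition(0.01, "initial", [frozenset({"a1", "a2"}), frozenset({"b1", "b2"})])
    c = partition_concordance(perfect, tax)
    assert c == {
        "n_groups": 2, "n_species": 2, "n_matching_groups": 2,
        "match_ratio": 100.0,
    }
    # one species split in two: both halves unmatched, B still matched
    split = Partition(
        0.01, "initial",
        [frozenset({"a1"}), frozenset({"a2"}), frozenset({"b1", "b2"})],
    )
    c2 = partition_concordance(split, tax)
    assert (c2["n_matching_groups"], c2["n_groups"]) == (1, 3)
    # two species merged: that group matches nothing
    merged = Partition(0.01, "initial", [frozenset({"a1", "a2", "b1", "b2"})])
    assert partition_concordance(merged, tax)["n_matching_groups"] == 0


def test_overlapping_groups_are_rejected():
    with pytest.raises(ValueError, match="overlap"):
        Partition(0.01, "initial", [frozenset({"a"}), frozenset({"a", "b"})])
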