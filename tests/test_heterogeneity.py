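"""Discretization, NMI oracle equivalence, and the subsampled group test."""

import itertools
from collections import Counter
from math import log

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nvu_hetero.errors import InputError
from nvu_hetero.heterogeneity import (NMIParams, discretize_equal_width,
                                      heterogeneity_test, median_pairwise_nmi,
                                      nmi_pair, pairwise_nmi,
                                      resampling_p_value)


def oracle_nmi(x, y, normalization="arithmetic"):
    """Independent pure-Python plug-in NMI from joint histogram counts."""
    n = len(x)
    joint = Counter(zip(x, y))
    px = Counter(x)
    py = Counter(y)
    mi = sum(c / n * log((c / n) / ((px[a] / n) * (py[b] / n)))
             for (a, b), c in joint.items())
    hx = -sum(c / n * log(c / n) for c in px.values())
    hy = -sum(c / n * log(c / n) for c in py.values())
    if hx == 0.0 or hy == 0.0:
        return 0.0
    denom = {"arithmetic": (hx + hy) / 2, "geometric": (hx * hy) ** 0.5,
             "min": min(hx, hy), "max": max(hx, hy)}[normalization]
    return min(max(mi / denom, 0.0), 1.0)


# ------------------------------------------------------------ discretize

def test_discretize_worked_examples():
    assert list(discretize_equal_width(np.array([[0.], [1.], [2.], [3.]]), 2)
                .bins.ravel()) == [0, 0, 1, 1]
    assert list(discretize_equal_width(np.array([[0.], [0.9], [1.0]]), 10)
                .bins.ravel()) == [0, 8, 9]


def test_discretize_constant_gene_all_bin_zero():
    prof = discretize_equal_width(np.full((5, 3), 2.5), 4)
    assert (prof.bins == 0).all()


def test_discretize_max_in_top_bin_min_in_bottom():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=(50, 8))
    prof = discretize_equal_width(vals, 7)
    for g in range(8):
        assert prof.bins[np.argmax(vals[:, g]), g] == 6
        assert prof.bins[np.argmin(vals[:, g]), g] == 0


def test_discretize_empty_selection_raises():
    with pytest.raises(InputError):
        discretize_equal_width(np.empty((5, 0)), 3)


# ------------------------------------------------------------ nmi_pair

def test_nmi_worked_value():
    assert nmi_pair([0, 0, 1, 1], [0, 1, 1, 1]) == pytest.approx(0.3437, abs=5e-4)


def test_nmi_identical_nonconstant_is_one():
    assert nmi_pair([0, 1, 0, 2], [0, 1, 0, 2]) == pytest.approx(1.0)


def test_nmi_independent_balanced_is_zero():
    assert nmi_pair([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0, abs=1e-15)


def test_nmi_constant_vector_convention_zero():
    assert nmi_pair([1, 1, 1, 1], [0, 1, 2, 3]) == 0.0


def test_nmi_length_mismatch_raises():
    with pytest.raises(InputError):
        nmi_pair([0, 1], [0, 1, 2])


def _all_joint_histograms(length, n_bins=3):
    """Every joint histogram over n_bins^2 cells with `length` total counts.

    Each pair of bin vectors of this length maps to one of these
    histograms, and NMI depends on the pair only through its histogram, so
    checking every histogram checks every pair (gene order is covered by a
    separate permutation-invariance test).
    """
    cells = list(itertools.product(range(n_bins), repeat=2))
    for counts in itertools.combinations_with_replacement(range(len(cells)), length):
        x, y = [], []
        for idx in counts:
            x.append(cells[idx][0])
            y.append(cells[idx][1])
        yield x, y


@pytest.mark.parametrize("length", [2, 3, 4, 5, 6])
def test_nmi_exhaustive_oracle_equivalence(length):
    """nmi_pair equals the independent oracle on every pair shape <= 6 over 3 bins."""
    for x, y in _all_joint_histograms(length):
        for norm in ("arithmetic", "geometric", "min", "max"):
            assert nmi_pair(x, y, norm) == pytest.approx(
                oracle_nmi(x, y, norm), abs=1e-12)


def test_nmi_direct_all_pairs_length3():
    vecs = list(itertools.product(range(3), repeat=3))
    for x in vecs:
        for y in vecs:
            assert nmi_pair(x, y) == pytest.approx(oracle_nmi(x, y), abs=1e-12)


@given(st.lists(st.integers(0, 4), min_size=2, max_size=30),
       st.randoms(use_true_random=False))
@settings(max_examples=150, derandomize=True, deadline=None)
def test_nmi_symmetry_range_and_relabeling(x, rnd):
    y = list(x)
    rnd.shuffle(y)
    v = nmi_pair(x, y)
    assert 0.0 <= v <= 1.0
    assert v == pytest.approx(nmi_pair(y, x), abs=1e-12)
    # bin-id relabeling invariance
    perm = list(range(5))
    rnd.shuffle(perm)
    assert nmi_pair([perm[i] for i in x], y) == pytest.approx(v, abs=1e-12)
    # gene-position permutation invariance
    order = list(range(len(x)))
    rnd.shuffle(order)
    assert nmi_pair([x[i] for i in order], [y[i] for i in order]) == \
        pytest.approx(v, abs=1e-12)


def test_pairwise_matrix_matches_scalar():
    rng = np.random.default_rng(1)
    bins = rng.integers(0, 6, size=(12, 40))
    mat = pairwise_nmi(bins, 6)
    for i in range(12):
        for j in range(12):
            assert mat[i, j] == pytest.approx(nmi_pair(bins[i], bins[j]), abs=1e-10)


def test_sklearn_cross_check():
    from sklearn.metrics import normalized_mutual_info_score
    rng = np.random.default_rng(2)
    for _ in range(20):
        x = rng.integers(0, 4, 25)
        y = rng.integers(0, 4, 25)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        assert nmi_pair(x, y) == pytest.approx(
            normalized_mutual_info_score(x, y, average_method="arithmetic"),
            abs=1e-10)


# ------------------------------------------------------------ p-value

def test_p_value_all_ties_is_one():
    assert resampling_p_value(np.ones(10), np.ones(10)) == 1.0


def test_p_value_floor_one_sided():
    a = np.arange(20) + 100.0
    b = np.arange(20) * 0.0
    assert resampling_p_value(a, b) == pytest.approx(1 / 20)


def test_p_value_balanced_is_one():
    a = np.array([1.0, 0.0] * 10)
    b = np.array([0.0, 1.0] * 10)
    assert resampling_p_value(a, b) == 1.0


# ------------------------------------------------------------ group test

def _profile_from(bins, ids):
    from nvu_hetero.heterogeneity import DiscretizedProfile
    return DiscretizedProfile(bins, int(bins.max()) + 1,
                              np.zeros((bins.shape[1], 2)),
                              np.asarray(ids, dtype=object),
                              np.arange(bins.shape[1]))


def test_identical_groups_shared_stream_gives_null_result():
    """Two copies of the same cells with common random numbers: D=0, p=1."""
    rng = np.random.default_rng(3)
    base = rng.integers(0, 5, size=(30, 25))
    bins = np.vstack([base, base])
    ids = [f"a{i}" for i in range(30)] + [f"b{i}" for i in range(30)]
    groups = pd.Series(["A"] * 30 + ["B"] * 30, index=ids)
    params = NMIParams(n_cells_per_class=10, n_replicates=12, n_bins=5, seed=5,
                       share_replicate_rng=True)
    res = heterogeneity_test(_profile_from(bins, ids), groups, params,
                             group_a="A", group_b="B")
    assert res.observed_diff == 0.0
    assert res.p_value == 1.0
    np.testing.assert_array_equal(res.medians_a, res.medians_b)


def test_replicate_medians_match_brute_force_recomputation():
    """Medians per replicate equal an independent recomputation of the draws."""
    rng = np.random.default_rng(6)
    bins = rng.integers(0, 4, size=(8, 15))
    ids = [f"c{i}" for i in range(8)]
    groups = pd.Series(["A"] * 4 + ["B"] * 4, index=ids)
    params = NMIParams(n_cells_per_class=3, n_replicates=4, n_bins=4, seed=9)
    res = heterogeneity_test(_profile_from(bins, ids), groups, params,
                             group_a="A", group_b="B", keep_draws=True)
    for r, rec in enumerate(res.draws):
        for g, med in (("A", res.medians_a[r]), ("B", res.medians_b[r])):
            cells = rec[g]
            vals = [oracle_nmi(list(bins[i]), list(bins[j]))
                    for i, j in itertools.combinations(cells, 2)]
            assert med == pytest.approx(np.median(vals), abs=1e-12)


def test_seeded_reproducibility():
    rng = np.random.default_rng(7)
    bins = rng.integers(0, 5, size=(40, 30))
    ids = [f"c{i}" for i in range(40)]
    groups = pd.Series(["A"] * 20 + ["B"] * 20, index=ids)
    params = NMIParams(n_cells_per_class=8, n_replicates=6, n_bins=5, seed=11)
    r1 = heterogeneity_test(_profile_from(bins, ids), groups, params, "A", "B")
    r2 = heterogeneity_test(_profile_from(bins, ids), groups, params, "A", "B")
    np.testing.assert_array_equal(r1.medians_a, r2.medians_a)
    assert r1.p_value == r2.p_value


def test_missing_group_raises():
    bins = np.zeros((4, 5), dtype=int)
    ids = list("abcd")
    groups = pd.Series(["A"] * 4, index=ids)
    with pytest.raises(InputError):
        heterogeneity_test(_profile_from(bins, ids), groups,
                           NMIParams(n_cells_per_class=2, n_replicates=2),
                           group_a="A", group_b="B")


def test_median_nmi_monotone_in_dispersion_knob():
    """Mean (over seeds) within-group median NMI is non-increasing along a
    3-point heterogeneity-factor grid."""
    from nvu_hetero.markers import lognormalize
    from nvu_hetero.synthetic_data import SimConfig, simulate_counts

    grid = [1.0, 1.5, 2.5]
    means = []
    for h in grid:
        vals = []
        for seed in range(10):
            cfg = SimConfig(n_genes=300, n_cell_types=1,
                            cells_per_type_per_group=60, program_size=40,
                            n_de_genes=60, seed=seed,
                            heterogeneity_factor={"AC": {"old": h}})
            m, meta, truth = simulate_counts(cfg)
            norm = lognormalize(m)
            profile_genes = list(truth.de_genes["AC"]["gene"])
            sub = np.asarray(norm.restrict_genes(profile_genes).values.todense()).T
            old = (meta["group"] == "old").to_numpy()
            prof = discretize_equal_width(sub[old], 10)
            vals.append(median_pairwise_nmi(prof.bins, 10))
        means.append(np.mean(vals))
    assert means[0] >= means[1] >= means[2]
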