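import itertools

import numpy as np
import pandas as pd
import pytest

from gutrace import (FeatureMatrix, SampleMetadata, UsageError,
                     compare_ordination_methods, factor_effect_sizes,
                     pairwise_distance, permanova_test)


def _fm(X, ids=None):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(X, [f"f{j}" for j in range(X.shape[1])],
                         ids or [f"s{i}" for i in range(X.shape[0])])


# ---------------------------------------------------------------- distances

def test_euclidean_345_triangle():
    D = pairwise_distance(np.array([[0.0, 0.0], [3.0, 4.0]]))
    assert D.values[0, 1] == pytest.approx(5.0)


def test_bray_curtis_disjoint_and_identical():
    D = pairwise_distance(np.array([[1.0, 0.0], [0.0, 1.0]]),
                          metric="bray-curtis")
    assert D.values[0, 1] == pytest.approx(1.0)
    D2 = pairwise_distance(np.array([[2.0, 3.0], [2.0, 3.0]]),
                           metric="bray-curtis")
    assert D2.values[0, 1] == pytest.approx(0.0)


def test_bray_curtis_rejects_negative():
    with pytest.raises(UsageError):
        pairwise_distance(np.array([[1.0, -1.0], [0.0, 1.0]]),
                          metric="bray-curtis")


def test_distance_matrix_invariants():
    rng = np.random.default_rng(20)
    X = rng.random((8, 3))
    for metric in ("euclidean", "bray-curtis"):
        D = pairwise_distance(X, metric=metric)
        np.testing.assert_allclose(D.values, D.values.T, atol=1e-12)
        assert np.all(np.diag(D.values) == 0)
        assert np.all(D.values >= 0)


# ----------------------------------------------------------------- permanova

def test_worked_example_hand_computation():
    """A={0,1}, B={2,3} on the line: SS_b=4, SS_w=1, F=8, R2=0.8; the
    exhaustive permutation p-value is 1/3."""
    D = pairwise_distance(np.array([[0.0], [1.0], [2.0], [3.0]]))
    res = permanova_test(D, ["A", "A", "B", "B"], exhaustive=True)
    assert res.pseudo_f == pytest.approx(8.0)
    assert res.r2 == pytest.approx(0.8)
    assert res.p_value == pytest.approx(1 / 3)


def test_random_permutation_p_converges_to_exhaustive():
    D = pairwise_distance(np.array([[0.0], [1.0], [2.0], [3.0]]))
    res = permanova_test(D, ["A", "A", "B", "B"], n_perm=4999, seed=1)
    assert res.p_value == pytest.approx(1 / 3, abs=0.02)


def test_exhaustive_matches_manual_enumeration():
    """Independent oracle: enumerate distinct labelings by brute force."""
    rng = np.random.default_rng(21)
    x = rng.normal(size=(6, 1))
    D = pairwise_distance(x)
    y = np.array(["A", "A", "A", "B", "B", "B"])
    res = permanova_test(D, y, exhaustive=True)

    def f_of(labels):
        labels = np.asarray(labels)
        d2 = D.values ** 2
        n = len(labels)
        sst = d2.sum() / (2 * n)
        ssw = 0.0
        for gval in ("A", "B"):
            idx = np.flatnonzero(labels == gval)
            ssw += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        return ((sst - ssw) / 1) / (ssw / (n - 2))

    f_obs = f_of(y)
    labelings = [np.array(perm) for perm in
                 set(itertools.permutations(y))]
    p_manual = np.mean([f_of(lab) >= f_obs - 1e-12 for lab in labelings])
    assert res.p_value == pytest.approx(p_manual, abs=1e-12)


def test_univariate_equals_anova_f():
    """With Euclidean distance on one variable, pseudo-F is the classical
    one-way ANOVA F (50 random instances)."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(22)
    for _ in range(50):
        g = int(rng.integers(2, 4))
        sizes = rng.integers(3, 7, size=g)
        groups = [rng.normal(k, 1.0, size=s) for k, s in enumerate(sizes)]
        x = np.concatenate(groups)[:, None]
        y = np.repeat([f"g{k}" for k in range(g)], sizes)
        res = permanova_test(pairwise_distance(x), y, n_perm=9, seed=0)
        assert res.pseudo_f == pytest.approx(f_oneway(*groups).statistic,
                                             rel=1e-9)


def test_ss_decomposition_and_r2_range():
    rng = np.random.default_rng(23)
    X = rng.normal(size=(20, 4))
    y = np.repeat(["a", "b", "c", "d"], 5)
    D = pairwise_distance(X)
    res = permanova_test(D, y, n_perm=99, seed=0)
    assert 0.0 <= res.r2 <= 1.0
    assert 0.0 < res.p_value <= 1.0


def test_degenerate_identical_samples():
    D = pairwise_distance(np.zeros((6, 2)))
    res = permanova_test(D, ["a"] * 3 + ["b"] * 3)
    assert np.isnan(res.pseudo_f)
    assert res.r2 == 0.0


def test_single_group_rejected():
    D = pairwise_distance(np.random.default_rng(0).normal(size=(4, 2)))
    with pytest.raises(UsageError):
        permanova_test(D, ["a"] * 4)


def test_skbio_cross_check():
    """Independent implementation agrees on pseudo-F and the permutation
    p-value (same statistic, same +1 convention)."""
    from skbio.stats.distance import DistanceMatrix as SkDM
    from skbio.stats.distance import permanova as sk_permanova

    rng = np.random.default_rng(24)
    X = np.vstack([rng.normal(k, 1.0, size=(8, 3)) for k in range(3)])
    y = np.repeat(["a", "b", "c"], 8)
    D = pairwise_distance(X)
    res = permanova_test(D, y, n_perm=999, seed=3)
    ref = sk_permanova(SkDM(D.values, ids=D.sample_ids), list(y),
                       permutations=999)
    assert res.pseudo_f == pytest.approx(float(ref["test statistic"]),
                                         rel=1e-9)
    assert res.p_value == pytest.approx(float(ref["p-value"]), abs=0.03)


def test_determinism_per_seed():
    rng = np.random.default_rng(25)
    X = rng.normal(size=(15, 3))
    y = np.repeat(["a", "b", "c"], 5)
    D = pairwise_distance(X)
    r1 = permanova_test(D, y, n_perm=199, seed=9)
    r2 = permanova_test(D, y, n_perm=199, seed=9)
    assert r1.p_value == r2.p_value


# ---------------------------------------------------------- factor effects

def test_factor_effect_sizes_ordering_and_skip(small_dataset):
    meta = small_dataset.metadata
    results = factor_effect_sizes(
        small_dataset.table, meta,
        ["insect_species", "developmental_stage", "geographic_area", "sex"],
        n_perm=19, seed=1)
    r2s = [r.r2 for r in results]
    assert r2s == sorted(r2s, reverse=True)
    # constant factor is skipped with a warning
    meta2 = SampleMetadata(meta.sample_ids, meta.factors.assign(
        constant=["x"] * len(meta.sample_ids)))
    results2 = factor_effect_sizes(small_dataset.table, meta2,
                                   ["constant", "sex"], n_perm=19, seed=1)
    assert [r.factor for r in results2] == ["sex"]


# ------------------------------------------------- LDA-vs-PCA comparison

def _minority_direction_data(rng, n_per=20):
    """Class signal lives on a low-variance axis, orthogonal to the
    dominant variance direction."""
    big = rng.normal(0, 10, size=(2 * n_per, 1))   # dominant, classless
    small = np.concatenate([rng.normal(0, 0.5, n_per),
                            rng.normal(3, 0.5, n_per)])[:, None]
    X = np.hstack([big, small])
    y = np.array(["a"] * n_per + ["b"] * n_per)
    return _fm(X), y


def test_lda_beats_pca_when_signal_is_minority_variance():
    rng = np.random.default_rng(26)
    fm, y = _minority_direction_data(rng)
    cmp = compare_ordination_methods(fm, y, n_subsamples=10, frac=0.85,
                                     n_perm=49, seed=2)
    assert cmp.mean_r2_lda > cmp.mean_r2_pca
    assert cmp.p_value < 0.05


def test_compare_with_itself_is_null():
    rng = np.random.default_rng(27)
    fm, y = _minority_direction_data(rng)
    cmp1 = compare_ordination_methods(fm, y, n_subsamples=6, n_perm=19,
                                      seed=4)
    cmp2 = compare_ordination_methods(fm, y, n_subsamples=6, n_perm=19,
                                      seed=4)
    # determinism per seed, and the self-difference of a method is null
    assert np.array_equal(cmp1.r2_lda, cmp2.r2_lda)
    diff = cmp1.r2_lda - cmp2.r2_lda
    assert np.allclose(diff, 0.0)
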