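import numpy as np
import pytest

from gutrace import (DataError, FeatureMatrix, UsageError, lda_classify,
                     lda_fit, lda_transform, pca, resubstitution_accuracy)
from conftest import separated_clusters


def _fm(X, ids=None):
    X = np.asarray(X, dtype=float)
    return FeatureMatrix(
        X, [f"f{j}" for j in range(X.shape[1])],
        ids or [f"s{i}" for i in range(X.shape[0])])


# --------------------------------------------------------------------- PCA

def test_pca_collinear_points_single_axis():
    res = pca(_fm([[0, 0], [1, 1], [2, 2]]))
    assert res.axis_summaries[0] == pytest.approx(1.0)
    assert res.axis_summaries[1:] == pytest.approx(0.0, abs=1e-12)


def test_pca_scores_centered_and_orthogonal():
    rng = np.random.default_rng(2)
    res = pca(_fm(rng.normal(size=(15, 4))))
    np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-12)
    G = res.coordinates.T @ res.coordinates
    np.testing.assert_allclose(G - np.diag(np.diag(G)), 0, atol=1e-9)


def test_pca_reconstruction_oracle():
    """Scores times loadings reproduce the centered matrix."""
    rng = np.random.default_rng(3)
    X = rng.normal(size=(6, 4))
    res = pca(_fm(X))
    centered = X - X.mean(axis=0)
    recon = res.coordinates @ res.loadings.T
    assert np.abs(recon - centered).max() < 1e-9


def test_pca_total_variance_preserved():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(12, 5))
    res = pca(_fm(X), scale=True)
    scaled = (X - X.mean(0)) / X.std(0, ddof=1)
    assert res.coordinates.var(axis=0, ddof=1).sum() == pytest.approx(
        scaled.var(axis=0, ddof=1).sum())


def test_pca_constant_features_rejected():
    with pytest.raises(DataError):
        pca(_fm(np.ones((4, 3))))


# --------------------------------------------------------------------- LDA

def test_lda_axis_recovers_separating_direction():
    rng = np.random.default_rng(7)
    n = 40
    x1 = np.concatenate([rng.normal(0, 1, n), rng.normal(8, 1, n)])
    x2 = rng.normal(0, 1, 2 * n)  # exchangeable across classes
    X = np.column_stack([x1, x2])
    y = np.array(["a"] * n + ["b"] * n)
    model = lda_fit(_fm(X), y, reg=0.0)
    d = model.scaling[:, 0]
    d = d / np.linalg.norm(d)
    assert abs(d[0]) > 0.99  # LD1 collinear with axis 1 up to sign


def test_lda_axis_count_bound():
    rng = np.random.default_rng(8)
    for g in (2, 3, 4):
        X = rng.normal(size=(g * 6, 5))
        y = np.repeat([f"c{k}" for k in range(g)], 6)
        model = lda_fit(_fm(X), y)
        assert model.scaling.shape[1] <= g - 1


def test_lda_rejects_singleton_class():
    X = np.arange(10, dtype=float).reshape(5, 2)
    y = np.array(["a", "a", "a", "a", "b"])
    with pytest.raises(DataError):
        lda_fit(_fm(X), y)


def test_lda_scalings_match_dense_eigensolver():
    """Brute-force generalized eigenproblem reproduces the scalings."""
    import scipy.linalg as la

    rng = np.random.default_rng(9)
    X = rng.normal(size=(12, 3))
    y = np.repeat(["a", "b", "c"], 4)
    model = lda_fit(_fm(X), y, reg=0.0)
    # independent scatter computation
    classes = ["a", "b", "c"]
    means = np.vstack([X[y == c].mean(0) for c in classes])
    W = sum((X[y == c] - means[i]).T @ (X[y == c] - means[i])
            for i, c in enumerate(classes))
    grand = X.mean(0)
    B = sum(4 * np.outer(means[i] - grand, means[i] - grand)
            for i in range(3))
    evals, evecs = la.eig(np.linalg.solve(W, B))
    order = np.argsort(evals.real)[::-1]
    for j in range(model.scaling.shape[1]):
        v_ref = evecs[:, order[j]].real
        v = model.scaling[:, j]
        cos = abs(v @ v_ref) / (np.linalg.norm(v) * np.linalg.norm(v_ref))
        assert cos == pytest.approx(1.0, abs=1e-8)


def test_lda_score_within_covariance_identity():
    rng = np.random.default_rng(10)
    X = rng.normal(size=(30, 4))
    y = np.repeat(["a", "b", "c"], 10)
    model = lda_fit(_fm(X), y, reg=0.0)
    scores = lda_transform(model, _fm(X)).coordinates
    classes = ["a", "b", "c"]
    Wn = sum((scores[y == c] - scores[y == c].mean(0)).T
             @ (scores[y == c] - scores[y == c].mean(0)) for c in classes)
    np.testing.assert_allclose(Wn / (30 - 3), np.eye(scores.shape[1]),
                               atol=1e-8)


def test_lda_transform_identities():
    rng = np.random.default_rng(11)
    X = rng.normal(size=(20, 3))
    y = np.repeat(["a", "b"], 10)
    fm = _fm(X)
    model = lda_fit(fm, y)
    scores = lda_transform(model, fm).coordinates
    # class mean maps to its centroid
    mean_a = _fm(model.class_means[:1], ids=["m"])
    np.testing.assert_allclose(
        lda_transform(model, mean_a).coordinates[0], model.centroids[0],
        atol=1e-10)
    # grand mean maps to the origin
    gm = _fm(model.grand_mean[None, :], ids=["g"])
    np.testing.assert_allclose(lda_transform(model, gm).coordinates[0], 0,
                               atol=1e-10)
    # refit-transform reproducibility
    np.testing.assert_allclose(
        lda_transform(model, fm).coordinates, scores, atol=0)


def test_lda_transform_feature_mismatch():
    rng = np.random.default_rng(12)
    X = rng.normal(size=(8, 2))
    y = np.repeat(["a", "b"], 4)
    model = lda_fit(_fm(X), y)
    other = FeatureMatrix(X, ["g0", "g1"], [f"s{i}" for i in range(8)])
    with pytest.raises(UsageError):
        lda_transform(model, other)


def test_classify_nearest_centroid_and_tie_break():
    X = np.array([[0.0], [1.0], [10.0], [11.0]])
    y = np.array(["lo", "hi"])[[0, 0, 1, 1]]
    model = lda_fit(_fm(X), y)
    labels, post = lda_classify(model, _fm(np.array([[0.4]]), ids=["q"]))
    assert labels[0] == "lo"
    # equidistant sample: tie broken to the earlier class, posteriors half
    mid = float(np.mean(X))
    labels, post = lda_classify(model, _fm(np.array([[mid]]), ids=["q"]))
    assert labels[0] == model.classes[0]
    np.testing.assert_allclose(post[0], [0.5, 0.5], atol=1e-12)


def test_posterior_rows_sum_to_one():
    rng = np.random.default_rng(13)
    X = rng.normal(size=(24, 3))
    y = np.repeat(["a", "b", "c"], 8)
    model = lda_fit(_fm(X), y)
    _, post = lda_classify(model, _fm(rng.normal(size=(50, 3))))
    np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)


def test_brute_force_gaussian_oracle_agreement():
    """Discriminant-space rule equals the pooled-covariance Gaussian rule
    computed directly in original feature space, on many small instances."""
    rng = np.random.default_rng(14)
    for _ in range(50):
        g = int(rng.integers(2, 4))
        p = int(rng.integers(1, 4))
        n_per = int(rng.integers(max(3, p + 1), 8))
        X = np.vstack([rng.normal(3 * k, 1.0, size=(n_per, p))
                       for k in range(g)])
        y = np.repeat([f"c{k}" for k in range(g)], n_per)
        fm = _fm(X)
        model = lda_fit(fm, y, reg=0.0)
        pred, _ = lda_classify(model, fm)

        # independent oracle: argmax_g log prior + logN(x; m_g, S_pooled)
        classes = sorted(set(y))
        means = np.vstack([X[y == c].mean(0) for c in classes])
        n = len(y)
        S = sum((X[y == c] - means[i]).T @ (X[y == c] - means[i])
                for i, c in enumerate(classes)) / (n - g)
        Sinv = np.linalg.inv(S)
        priors = np.array([(y == c).mean() for c in classes])
        scores = np.array([
            [np.log(priors[i]) - 0.5 * (x - means[i]) @ Sinv @ (x - means[i])
             for i in range(g)] for x in X])
        oracle = np.array(classes, dtype=object)[scores.argmax(axis=1)]
        assert np.array_equal(pred, oracle)


def test_affine_invariance_of_classifications():
    rng = np.random.default_rng(15)
    X = rng.normal(size=(30, 3))
    y = np.repeat(["a", "b", "c"], 10)
    A = rng.normal(size=(3, 3)) + 3 * np.eye(3)  # invertible rescaling
    b = rng.normal(size=3)
    pred1, _ = lda_classify(lda_fit(_fm(X), y, reg=0.0), _fm(X))
    X2 = X @ A + b
    pred2, _ = lda_classify(lda_fit(_fm(X2), y, reg=0.0), _fm(X2))
    assert np.array_equal(pred1, pred2)


def test_separated_clusters_resubstitution_perfect():
    rng = np.random.default_rng(16)
    fm, y = separated_clusters(rng, sep=50.0)
    assert resubstitution_accuracy(fm, y) == 1.0


def test_sklearn_cross_check():
    """Independent library implementation agrees on classifications."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(17)
    X = np.vstack([rng.normal(k, 1.2, size=(15, 4)) for k in range(3)])
    y = np.repeat(["a", "b", "c"], 15)
    model = lda_fit(_fm(X), y, reg=0.0)
    pred, _ = lda_classify(model, _fm(X))
    ref = LinearDiscriminantAnalysis(solver="eigen").fit(X, y).predict(X)
    assert (pred == ref).mean() == 1.0
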