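"""From-scratch PCA and multiclass Fisher discriminant analysis.

PCA is the singular decomposition of the centered (optionally unit-scaled)
feature matrix.  LDA solves the generalized eigenproblem

    B v = lambda (W + reg * tr(W)/p * I) v

where W is the pooled within-class scatter and B the between-class scatter
of the class means.  The ridge term keeps the problem well posed in the
p >> n regime typical of taxon tables (hundreds of features, ~179 samples);
reg is expressed relative to the mean within-class variance tr(W)/p so its
scale is data-independent.  Discriminant scalings are normalized so that
the within-class covariance of the scores is the identity, which makes the
classification rule a nearest-centroid Gaussian rule in score space:

    posterior(g | x)  proportional to  prior_g * exp(-1/2 ||score(x) - centroid_g||^2)

Ties are broken deterministically toward the earlier-registered class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as la

from .errors import DataError, UsageError

#: Relative eigenvalue threshold below which a discriminant axis is
#: considered null (rank detection in B).
_EIG_RTOL = 1e-9


@dataclass
class FeatureMatrix:
    """Samples x features matrix with names and provenance."""

    X: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise UsageError("feature matrix must be 2-D (samples x features)")
        if self.X.shape != (len(self.sample_ids), len(self.feature_names)):
            raise UsageError("feature matrix shape does not match names")
        if np.any(~np.isfinite(self.X)):
            raise DataError("feature matrix contains missing or infinite entries")
        if self.X.shape[0] < 1:
            raise DataError("at least 1 sample required")


@dataclass
class OrdinationResult:
    """Low-dimensional sample coordinates from PCA or LDA.

    ``axis_summaries`` holds variance-explained fractions for PCA and
    between/within generalized eigenvalues for LDA.
    """

    method: str  # "PCA" | "LDA"
    coordinates: np.ndarray  # samples x axes
    axis_labels: list[str]
    axis_summaries: np.ndarray
    sample_ids: list[str]
    loadings: np.ndarray | None = None  # features x axes (PCA: V; LDA: scaling)

    def first_two(self) -> np.ndarray:
        """The visualized subspace: first two axes (or all if fewer)."""
        return self.coordinates[:, : min(2, self.coordinates.shape[1])]


@dataclass
class LdaModel:
    """Fitted Fisher discriminant model."""

    classes: list[str]
    priors: np.ndarray
    grand_mean: np.ndarray
    class_means: np.ndarray  # g x p, in original feature space
    scaling: np.ndarray  # p x k discriminant directions
    eigenvalues: np.ndarray  # between/within ratio per axis
    feature_names: list[str]
    reg: float
    within_trace: float  # tr(W), recorded for reproducibility

    @property
    def centroids(self) -> np.ndarray:
        """Class centroids in discriminant space (g x k)."""
        return (self.class_means - self.grand_mean) @ self.scaling


def pca(X: FeatureMatrix, scale: bool = False, n_axes: int | None = None) -> OrdinationResult:
    """Principal component analysis by SVD of the centered matrix.

    Parameters
    ----------
    scale : bool
        Divide each centered column by its standard deviation (columns with
        zero variance are left unscaled).
    n_axes : int, optional
        Number of axes to retain; default all ``min(n-1, p)``.
    """
    if X.X.shape[0] < 2:
        raise DataError("PCA needs at least 2 samples")
    M = X.X - X.X.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    if np.all(sd == 0):
        raise DataError("all features constant; PCA undefined")
    if scale:
        safe = np.where(sd > 0, sd, 1.0)
        M = M / safe
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    n = M.shape[0]
    k = min(n - 1, M.shape[1])
    if n_axes is not None:
        k = min(k, n_axes)
    scores = U[:, :k] * s[:k]
    var = s[:k] ** 2 / (n - 1)
    total_var = (s ** 2).sum() / (n - 1)
    return OrdinationResult(
        method="PCA",
        coordinates=scores,
        axis_labels=[f"PC{i + 1}" for i in range(k)],
        axis_summaries=var / total_var,
        sample_ids=list(X.sample_ids),
        loadings=Vt[:k].T,
    )


def _class_stats(Xv: np.ndarray, labels: np.ndarray):
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < 2]
    if small.size:
        raise DataError(f"class(es) with fewer than 2 samples: {list(small)}")
    if classes.size < 2:
        raise DataError("at least 2 classes required")
    means = np.vstack([Xv[labels == c].mean(axis=0) for c in classes])
    return classes, counts, means


def lda_fit(X: FeatureMatrix, labels, reg: float = 1e-6) -> LdaModel:
    """Fit multiclass Fisher LDA with spectral-ridge regularization.

    Zero-variance features are removed before fitting (their scaling rows
    are zero in the returned model, so transform/classify still accept the
    full feature set).  Priors are the empirical class frequencies.
    """
    if reg < 0:
        raise UsageError("reg must be non-negative")
    y = np.asarray([str(v) for v in labels])
    if y.shape[0] != X.X.shape[0]:
        raise UsageError("labels length does not match sample count")
    classes, counts, _ = _class_stats(X.X, y)

    keep = X.X.std(axis=0) > 0
    Xv = X.X[:, keep]
    p = Xv.shape[1]
    if p == 0:
        raise DataError("all features have zero variance")
    n = Xv.shape[0]
    g = classes.size

    means = np.vstack([Xv[y == c].mean(axis=0) for c in classes])
    grand = Xv.mean(axis=0)
    W = np.zeros((p, p))
    for c, m in zip(classes, means):
        D = Xv[y == c] - m
        W += D.T @ D
    dev = means - grand
    B = (dev.T * counts) @ dev

    trW = float(np.trace(W))
    if trW <= 0:
        raise DataError("degenerate within-class scatter: every class is a "
                        "single repeated point; rank deficiency is total")
    W_reg = W + reg * (trW / p) * np.eye(p)
    try:
        evals, evecs = la.eigh(B, W_reg)
    except la.LinAlgError as exc:
        raise DataError(
            f"generalized eigenproblem failed: within-class scatter is rank "
            f"deficient even after regularization (p={p}, n={n}): {exc}"
        ) from exc
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    k_max = min(g - 1, p)
    nz = evals > max(evals[0], 0) * _EIG_RTOL
    k = int(min(k_max, nz.sum())) or 1
    V = evecs[:, :k]
    # eigh(B, W_reg) yields V' W_reg V = I; rescale so the within-class
    # covariance of the scores, W/(n-g) in score space, is the identity.
    V = V * np.sqrt(n - g)

    scaling = np.zeros((X.X.shape[1], k))
    scaling[keep] = V
    class_means_full = np.vstack([X.X[y == c].mean(axis=0) for c in classes])
    return LdaModel(
        classes=[str(c) for c in classes],
        priors=counts / n,
        grand_mean=X.X.mean(axis=0),
        class_means=class_means_full,
        scaling=scaling,
        eigenvalues=np.maximum(evals[:k], 0.0),
        feature_names=list(X.feature_names),
        reg=reg,
        within_trace=trW,
    )


def _check_features(model: LdaModel, X: FeatureMatrix) -> None:
    if list(X.feature_names) != list(model.feature_names):
        raise UsageError("feature names do not match the fitted model")


def lda_transform(model: LdaModel, X: FeatureMatrix) -> OrdinationResult:
    """Project samples onto the discriminant axes (LD1, LD2, ...)."""
    _check_features(model, X)
    scores = (X.X - model.grand_mean) @ model.scaling
    return OrdinationResult(
        method="LDA",
        coordinates=scores,
        axis_labels=[f"LD{i + 1}" for i in range(scores.shape[1])],
        axis_summaries=model.eigenvalues.copy(),
        sample_ids=list(X.sample_ids),
        loadings=model.scaling.copy(),
    )


def lda_classify(model: LdaModel, X: FeatureMatrix):
    """Classify samples with the equal-covariance Gaussian rule.

    Returns ``(labels, posteriors)``; posterior rows sum to 1 and the argmax
    resolves ties toward the earlier class in ``model.classes``.
    """
    _check_features(model, X)
    scores = (X.X - model.grand_mean) @ model.scaling
    d2 = ((scores[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    logpost = np.log(model.priors)[None, :] - 0.5 * d2
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    idx = np.argmax(post, axis=1)  # first occurrence wins ties
    labels = np.asarray(model.classes, dtype=object)[idx]
    return labels, post
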