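"""Distance matrices, PERMANOVA effect sizes, and the LDA-vs-PCA contrast.

PERMANOVA partitions the squared inter-sample distances into between- and
within-group sums of squares:

    SS_total = sum_{i<j} d_ij^2 / n
    SS_within = sum_g sum_{i<j in g} d_ij^2 / n_g
    SS_between = SS_total - SS_within
    pseudo-F = (SS_between / (g-1)) / (SS_within / (n-g))
    R^2 = SS_between / SS_total

and assesses significance by permuting group labels uniformly:
p = (1 + #{F_perm >= F_obs}) / (1 + n_perm).  With a Euclidean distance on
one variable the pseudo-F reduces to the classical one-way ANOVA F.

Per-factor effect sizes (one marginal PERMANOVA per factor on the same
distance matrix) reproduce the "which factor dominates the community"
analysis; :func:`compare_ordination_methods` contrasts the group separation
achieved by LDA and PCA via a paired t-test on R^2 across repeated
stratified subsamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import DataError, UsageError
from .ordination import FeatureMatrix, lda_fit, lda_transform, pca
from .table_io import MISSING, SampleMetadata, TaxonTable
from .taxonomy_agg import feature_matrix

logger = logging.getLogger(__name__)

METRICS = ("euclidean", "bray-curtis")


@dataclass
class DistanceMatrix:
    """Symmetric non-negative pairwise distances with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise UsageError("distance matrix shape does not match sample ids")
        if np.any(np.abs(self.values - self.values.T) > 1e-12):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise DataError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise DataError("negative distances")


@dataclass
class PermanovaResult:
    factor: str
    r2: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    seed: int
    n_samples: int
    n_groups: int
    metric: str
    extras: dict = field(default_factory=dict)


def pairwise_distance(data, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise distances between samples.

    ``data`` is a :class:`FeatureMatrix` (samples x features), an
    :class:`OrdinationResult`-like array, or an abundance
    :class:`TaxonTable` (taxa x samples; transposed internally).
    Bray-Curtis requires non-negative inputs.
    """
    if metric not in METRICS:
        raise UsageError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if isinstance(data, TaxonTable):
        X = data.values.T.astype(float)
        ids = list(data.sample_ids)
    elif isinstance(data, FeatureMatrix):
        X, ids = data.X, list(data.sample_ids)
    else:
        X = np.asarray(data, dtype=float)
        ids = [str(i) for i in range(X.shape[0])]
    if metric == "bray-curtis":
        if np.any(X < 0):
            raise UsageError("bray-curtis requires non-negative abundances")
        D = squareform(pdist(X, metric="braycurtis"))
        D = np.nan_to_num(D, nan=0.0)  # two all-zero samples: distance 0
    else:
        D = squareform(pdist(X, metric="euclidean"))
    return DistanceMatrix(ids, D, metric)


def _ss_within(D2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ssw = 0.0
    for gval in groups:
        idx = np.flatnonzero(labels == gval)
        ssw += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ssw


def permanova_test(
    D: DistanceMatrix,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    factor_name: str = "factor",
    exhaustive: bool = False,
) -> PermanovaResult:
    """One-factor PERMANOVA with a uniform label-permutation null.

    With ``exhaustive`` the p-value enumerates all n! label permutations
    (feasible only for small n) instead of sampling; the identity
    permutation is part of the enumeration, matching the +1 convention of
    the sampled p.  When all samples coincide (``SS_total == 0``) the
    pseudo-F is undefined (NaN), R^2 is 0 and p is 1.
    """
    y = np.asarray([str(v) for v in labels])
    n = len(y)
    if n != len(D.sample_ids):
        raise UsageError("labels length does not match the distance matrix")
    groups = np.unique(y)
    g = len(groups)
    if g < 2:
        raise UsageError("PERMANOVA needs at least 2 groups")
    if n < g + 1:
        raise UsageError("PERMANOVA needs n >= number of groups + 1")
    D2 = D.values ** 2
    ss_total = D2.sum() / (2 * n)
    if ss_total <= 0:
        return PermanovaResult(factor_name, 0.0, float("nan"), 1.0, n_perm,
                               seed, n, g, D.metric,
                               extras={"degenerate": "all samples identical"})

    def f_and_r2(lab):
        ssw = _ss_within(D2, lab, groups)
        ssb = ss_total - ssw
        f = (ssb / (g - 1)) / (ssw / (n - g)) if ssw > 0 else float("inf")
        return f, ssb / ss_total

    f_obs, r2 = f_and_r2(y)
    if exhaustive:
        from itertools import permutations as _perms

        if n > 9:
            raise UsageError("exhaustive enumeration limited to n <= 9")
        hits = total = 0
        for order in _perms(range(n)):
            f_perm, _ = f_and_r2(y[list(order)])
            total += 1
            if f_perm >= f_obs:
                hits += 1
        p = hits / total
        n_perm = total - 1
    else:
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        hits = 0
        for _ in range(n_perm):
            f_perm, _ = f_and_r2(rng.permutation(y))
            if f_perm >= f_obs:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return PermanovaResult(factor_name, float(r2), float(f_obs), float(p),
                           n_perm, seed, n, g, D.metric)


def factor_effect_sizes(
    data,
    meta: SampleMetadata,
    factors: list[str],
    metric: str = "bray-curtis",
    n_perm: int = 999,
    seed: int = 0,
    epsilon: float = 1e-6,
) -> list[PermanovaResult]:
    """Marginal PERMANOVA per factor on one shared distance matrix.

    ``data`` may be a counts :class:`TaxonTable` (log-normalized relative
    abundance is used as the sample space) or a ready
    :class:`FeatureMatrix`/:class:`DistanceMatrix`.  Factors with a single
    observed level are skipped with a warning.  Results are ordered by R^2
    descending; samples with a missing level for a factor are excluded from
    that factor's test.
    """
    if isinstance(data, DistanceMatrix):
        D = data
    elif isinstance(data, TaxonTable):
        Xm, names = feature_matrix(data, epsilon=epsilon)
        fm = FeatureMatrix(Xm, names, list(data.sample_ids))
        if metric == "bray-curtis":
            # Bray-Curtis is defined on abundances, not log space
            Xr, names_r = feature_matrix(data, epsilon=epsilon, log=False)
            fm = FeatureMatrix(Xr, names_r, list(data.sample_ids))
        D = pairwise_distance(fm, metric=metric)
    else:
        D = pairwise_distance(data, metric=metric)

    streams = np.random.SeedSequence(seed).spawn(len(factors))
    results = []
    for i, factor in enumerate(factors):
        if factor not in meta.factor_names:
            raise UsageError(f"factor {factor!r} not in metadata")
        y_all = meta.factors.loc[D.sample_ids, factor].to_numpy()
        ok = y_all != MISSING
        levels = np.unique(y_all[ok])
        if len(levels) < 2:
            logger.warning("factor %r has a single level; skipped", factor)
            continue
        idx = np.flatnonzero(ok)
        Dsub = DistanceMatrix([D.sample_ids[i] for i in idx],
                              D.values[np.ix_(idx, idx)], D.metric)
        res = permanova_test(
            Dsub, y_all[ok], n_perm=n_perm,
            seed=int(streams[i].generate_state(1)[0] % (2 ** 31)),
            factor_name=factor)
        results.append(res)
    results.sort(key=lambda r: -r.r2)
    return results


@dataclass
class OrdinationComparison:
    """Paired LDA-vs-PCA separation contrast across stratified subsamples."""

    r2_lda: np.ndarray
    r2_pca: np.ndarray
    t_statistic: float
    p_value: float
    parameters: dict = field(default_factory=dict)

    @property
    def mean_r2_lda(self) -> float:
        return float(np.mean(self.r2_lda))

    @property
    def mean_r2_pca(self) -> float:
        return float(np.mean(self.r2_pca))


def compare_ordination_methods(
    X: FeatureMatrix,
    labels,
    n_subsamples: int = 20,
    frac: float = 0.85,
    metric: str = "euclidean",
    n_perm: int = 99,
    seed: int = 0,
    reg: float = 1e-6,
) -> OrdinationComparison:
    """Compare group separation in LDA vs PCA score space.

    For each stratified subsample (fraction ``frac`` of every class), PCA
    and LDA are fitted and the PERMANOVA R^2 of ``labels`` on the first two
    axes of each is computed; a paired two-sided t-test across subsamples
    summarizes the difference.
    """
    y = np.asarray([str(v) for v in labels])
    classes = np.unique(y)
    streams = np.random.SeedSequence(seed).spawn(n_subsamples + 1)
    perm_seed = int(streams[-1].generate_state(1)[0] % (2 ** 31))
    r2_l, r2_p = np.empty(n_subsamples), np.empty(n_subsamples)
    for r in range(n_subsamples):
        rng = np.random.default_rng(streams[r])
        keep = []
        for c in classes:
            members = np.flatnonzero(y == c)
            k = max(2, round(frac * len(members)))
            keep.append(rng.choice(members, size=min(k, len(members)),
                                   replace=False))
        idx = np.sort(np.concatenate(keep))
        Xs = FeatureMatrix(X.X[idx], list(X.feature_names),
                           [X.sample_ids[i] for i in idx])
        ys = y[idx]
        model = lda_fit(Xs, ys, reg=reg)
        lda_scores = lda_transform(model, Xs).first_two()
        pca_scores = pca(Xs).first_two()
        for scores, out in ((lda_scores, r2_l), (pca_scores, r2_p)):
            D = pairwise_distance(scores, metric=metric)
            D.sample_ids = list(Xs.sample_ids)
            out[r] = permanova_test(D, ys, n_perm=n_perm, seed=perm_seed).r2
    if np.allclose(r2_l, r2_p):
        t, p = 0.0, 1.0
    else:
        t, p = stats.ttest_rel(r2_l, r2_p)
    return OrdinationComparison(
        r2_lda=r2_l, r2_pca=r2_p, t_statistic=float(t), p_value=float(p),
        parameters={"n_subsamples": n_subsamples, "frac": frac,
                    "metric": metric, "n_perm": n_perm, "seed": seed,
                    "reg": reg, "space": "first two axes"},
    )
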