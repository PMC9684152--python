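"""Resampled classification accuracy and taxonomic-level selection.

The accuracy statistic is the fraction of samples the fitted discriminant
assigns to their own labels (resubstitution).  Its stability is probed two
ways: a stratified jackknife that repeatedly drops ~15% of each class and
refits, and an unstratified bootstrap drawing n samples with replacement.
Running both across taxonomic ranks, the ranks whose jackknife AND
bootstrap mean accuracies clear a threshold are reported as suitable levels
for geographic traceability.

By default each replicate is scored by resubstitution on its own (retained
or resampled) samples; ``score_heldout=True`` scores the dropped samples
instead (jackknife only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .ordination import FeatureMatrix, lda_classify, lda_fit
from .table_io import MISSING, SampleMetadata
from .taxonomy_agg import FEATURE_RANKS, RankTableSet, feature_matrix


@dataclass
class AccuracyDistribution:
    """Replicate accuracies from one resampling scheme."""

    replicates: np.ndarray
    kind: str  # "jackknife" | "bootstrap"
    seed: int
    parameters: dict = field(default_factory=dict)

    @property
    def mean(self) -> float:
        return float(np.mean(self.replicates))

    @property
    def sd(self) -> float:
        return float(np.std(self.replicates, ddof=1)) if len(self.replicates) > 1 else 0.0

    @property
    def n_replicates(self) -> int:
        return int(len(self.replicates))


def _subset(X: FeatureMatrix, idx: np.ndarray) -> FeatureMatrix:
    return FeatureMatrix(
        X.X[idx],
        list(X.feature_names),
        [X.sample_ids[i] for i in idx],
        dict(X.provenance),
    )


def resubstitution_accuracy(X: FeatureMatrix, labels, reg: float = 1e-6) -> float:
    """Fit on (X, labels), classify X, return the fraction of matches."""
    y = np.asarray([str(v) for v in labels])
    model = lda_fit(X, y, reg=reg)
    pred, _ = lda_classify(model, X)
    return float(np.mean(pred == y))


def _accuracy_on(Xfit: FeatureMatrix, yfit, Xscore: FeatureMatrix, yscore,
                 reg: float) -> float:
    model = lda_fit(Xfit, yfit, reg=reg)
    pred, _ = lda_classify(model, Xscore)
    return float(np.mean(pred == np.asarray(yscore)))


def jackknife_accuracy(
    X: FeatureMatrix,
    labels,
    drop_frac: float = 0.15,
    reps: int = 1000,
    seed: int = 0,
    reg: float = 1e-6,
    score_heldout: bool = False,
) -> AccuracyDistribution:
    """Stratified deletion jackknife of the accuracy statistic.

    Each replicate drops ``max(1, round(drop_frac * n_g))`` samples uniformly
    at random from every class g, refits the discriminant on the retained
    samples, and records accuracy — by resubstitution on the retained
    samples, or on the dropped samples when ``score_heldout``.

    A single ``seed`` deterministically spawns one substream per replicate,
    so replicate r is reproducible independent of execution order.
    """
    y = np.asarray([str(v) for v in labels])
    classes = np.unique(y)
    drop_counts = {}
    for c in classes:
        n_g = int((y == c).sum())
        d = max(1, round(drop_frac * n_g))
        if n_g - d < 2:
            raise DataError(
                f"class {c!r} has {n_g} samples; dropping {d} leaves fewer than 2"
            )
        drop_counts[c] = d
    streams = np.random.SeedSequence(seed).spawn(reps)
    accs = np.empty(reps)
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        dropped = []
        for c in classes:
            members = np.flatnonzero(y == c)
            dropped.append(rng.choice(members, size=drop_counts[c], replace=False))
        dropped = np.concatenate(dropped)
        mask = np.ones(len(y), dtype=bool)
        mask[dropped] = False
        keep_idx = np.flatnonzero(mask)
        Xk, yk = _subset(X, keep_idx), y[keep_idx]
        if score_heldout:
            accs[r] = _accuracy_on(Xk, yk, _subset(X, dropped), y[dropped], reg)
        else:
            accs[r] = _accuracy_on(Xk, yk, Xk, yk, reg)
    return AccuracyDistribution(
        replicates=accs, kind="jackknife", seed=seed,
        parameters={"drop_frac": drop_frac, "reps": reps, "reg": reg,
                    "score": "heldout" if score_heldout else "resubstitution",
                    "drop_counts": {str(c): int(d) for c, d in drop_counts.items()}},
    )


def bootstrap_accuracy(
    X: FeatureMatrix,
    labels,
    reps: int = 1000,
    seed: int = 0,
    reg: float = 1e-6,
) -> AccuracyDistribution:
    """Unstratified bootstrap of the accuracy statistic.

    Each replicate draws n samples with replacement, refits, and records
    resubstitution accuracy on the bootstrap sample.  Draws that leave
    fewer than two classes with >= 2 samples are redrawn (count recorded in
    ``parameters['redraws']``).
    """
    y = np.asarray([str(v) for v in labels])
    n = len(y)
    streams = np.random.SeedSequence(seed).spawn(reps)
    accs = np.empty(reps)
    redraws = 0
    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        while True:
            idx = rng.integers(0, n, size=n)
            _, cnts = np.unique(y[idx], return_counts=True)
            if (cnts >= 2).sum() >= 2 and len(cnts) >= 2 and cnts.min() >= 2:
                break
            redraws += 1
        Xb, yb = _subset(X, idx), y[idx]
        accs[r] = _accuracy_on(Xb, yb, Xb, yb, reg)
    return AccuracyDistribution(
        replicates=accs, kind="bootstrap", seed=seed,
        parameters={"reps": reps, "reg": reg, "redraws": redraws,
                    "score": "resubstitution"},
    )


@dataclass
class LevelSelectionReport:
    """Per-rank accuracy summaries and the selected traceability levels."""

    resubstitution: dict[str, float]
    jackknife: dict[str, AccuracyDistribution]
    bootstrap: dict[str, AccuracyDistribution]
    selected: list[str]
    parameters: dict = field(default_factory=dict)

    def summary_rows(self) -> list[dict]:
        rows = []
        for rank in self.resubstitution:
            jk, bs = self.jackknife[rank], self.bootstrap[rank]
            rows.append({
                "rank": rank,
                "resubstitution": self.resubstitution[rank],
                "jackknife_mean": jk.mean, "jackknife_sd": jk.sd,
                "bootstrap_mean": bs.mean, "bootstrap_sd": bs.sd,
                "selected": rank in self.selected,
            })
        return rows


def evaluate_levels(
    ranks: RankTableSet,
    meta: SampleMetadata,
    label_factor: str,
    reg: float = 1e-6,
    reps: int = 1000,
    seed: int = 0,
    drop_frac: float = 0.15,
    threshold: float = 0.95,
    epsilon: float = 1e-6,
    rank_names: list[str] | None = None,
) -> LevelSelectionReport:
    """Score every taxonomic rank and select the suitable traceability levels.

    For each rank, a log-normalized feature matrix is built, and the
    resubstitution accuracy plus jackknife and bootstrap distributions are
    computed for ``label_factor``.  Ranks whose jackknife AND bootstrap mean
    accuracies are >= ``threshold`` are selected, ordered by descending mean
    (jackknife + bootstrap) and ascending pooled SD.
    """
    rank_names = list(rank_names) if rank_names is not None else list(FEATURE_RANKS)
    for rk in rank_names:
        if rk not in ranks.tables:
            raise DataError(f"rank {rk!r} not present in the rank set")
    if label_factor not in meta.factor_names:
        raise DataError(f"factor {label_factor!r} not in metadata")
    labels_all = meta.factors[label_factor]
    if len({v for v in labels_all if v != MISSING}) < 2:
        raise DataError(f"factor {label_factor!r} has fewer than 2 levels")

    ss = np.random.SeedSequence(seed)
    # fixed-size spawn keyed by position so per-rank streams are stable
    substreams = ss.spawn(2 * len(rank_names))
    resub: dict[str, float] = {}
    jack: dict[str, AccuracyDistribution] = {}
    boot: dict[str, AccuracyDistribution] = {}
    for i, rank in enumerate(rank_names):
        table = ranks[rank]
        keep = [s for s in table.sample_ids
                if meta.factors.loc[s, label_factor] != MISSING]
        sub = table.select_samples(keep)
        Xm, names = feature_matrix(sub, epsilon=epsilon)
        X = FeatureMatrix(Xm, names, keep,
                          {"rank": rank, "normalization": f"log(rel+{epsilon})"})
        y = meta.factors.loc[keep, label_factor].to_numpy()
        resub[rank] = resubstitution_accuracy(X, y, reg=reg)
        jack[rank] = jackknife_accuracy(
            X, y, drop_frac=drop_frac, reps=reps,
            seed=int(substreams[2 * i].generate_state(1)[0] % (2 ** 31)), reg=reg)
        boot[rank] = bootstrap_accuracy(
            X, y, reps=reps,
            seed=int(substreams[2 * i + 1].generate_state(1)[0] % (2 ** 31)), reg=reg)

    passing = [rk for rk in rank_names
               if jack[rk].mean >= threshold and boot[rk].mean >= threshold]
    passing.sort(key=lambda rk: (-(jack[rk].mean + boot[rk].mean) / 2,
                                 jack[rk].sd + boot[rk].sd))
    return LevelSelectionReport(
        resubstitution=resub, jackknife=jack, bootstrap=boot, selected=passing,
        parameters={"label_factor": label_factor, "reg": reg, "reps": reps,
                    "seed": seed, "drop_frac": drop_frac,
                    "threshold": threshold, "epsilon": epsilon,
                    "ranks": rank_names},
    )
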