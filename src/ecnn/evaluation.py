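"""Experimental harness: cross-validated training, confusion metrics,
baselines and simple statistics.

The protocol is a k-fold plan with cyclic train/validation/test roles
(default 5 folds, repeated twice, so 10 test evaluations).  Normalization
statistics are always fitted on the training role only and applied frozen
to the other roles, so no test-role information leaks into training.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance

from .cohort import EventMatrix, FoldPlan, make_cv_folds, normalize
from .config import TrainConfig
from .training import ensemble_predict, train_snapshots

__all__ = [
    "MetricSet",
    "CVResults",
    "DegenerateStatisticError",
    "confusion_metrics",
    "run_cv",
    "backward_stepwise",
    "rf_baseline_ranking",
    "random_subset",
    "pearson_feature_correlation",
    "paired_ttest",
]

METRIC_NAMES = ("accuracy", "tpr", "tnr", "ppv", "npv", "f1")


class DegenerateStatisticError(ValueError):
    """A statistic is undefined on this input (e.g. zero-variance t-test)."""


@dataclass
class MetricSet:
    """Confusion counts and the standard derived binary metrics.

    Ratios with a zero denominator are reported as NaN, never silently 0.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @staticmethod
    def _ratio(num: float, den: float) -> float:
        return num / den if den else math.nan

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.tp + self.fp + self.tn + self.fn)

    @property
    def tpr(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn)

    @property
    def tnr(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self._ratio(self.tn, self.tn + self.fn)

    @property
    def f1(self) -> float:
        return self._ratio(2 * self.tp, 2 * self.tp + self.fp + self.fn)

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class CVResults:
    """Per-evaluation metrics plus nan-aware mean/SD aggregates."""

    per_evaluation: list[tuple[int, int, MetricSet]]  # (repeat, fold, metrics)
    aggregate: dict[str, tuple[float, float]]
    n_degenerate: int

    def metric_values(self, name: str) -> np.ndarray:
        """Per-evaluation values of one metric, in plan order."""
        return np.array([getattr(m, name) for _, _, m in self.per_evaluation])


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricSet:
    """Confusion counts and derived metrics for binary label vectors."""
    y_true = np.asarray(y_true).reshape(-1)
    y_pred = np.asarray(y_pred).reshape(-1)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    if not (np.isin(y_true, [0, 1]).all() and np.isin(y_pred, [0, 1]).all()):
        raise ValueError("labels must be in {0, 1}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    return MetricSet(tp=tp, fp=fp, tn=tn, fn=fn)


def _aggregate(metric_sets: list[MetricSet]) -> tuple[dict, int]:
    agg: dict[str, tuple[float, float]] = {}
    degenerate = 0
    stacked = {name: np.array([getattr(m, name) for m in metric_sets])
               for name in METRIC_NAMES}
    degenerate = int(np.isnan(np.column_stack(list(stacked.values()))).any(axis=1).sum())
    for name, vals in stacked.items():
        ok = vals[~np.isnan(vals)]
        if ok.size:
            agg[name] = (float(ok.mean()), float(ok.std(ddof=1)) if ok.size > 1 else 0.0)
        else:
            agg[name] = (math.nan, math.nan)
    return agg, degenerate


def _eval_seed(base_seed: int, index: int) -> int:
    # distinct, reproducible, < 2**31
    return int((base_seed * 1_000_003 + 7919 * (index + 1)) % (2**31))


def run_cv(
    dataset: EventMatrix,
    config: TrainConfig,
    feature_subset: list[str] | None = None,
    plan: FoldPlan | None = None,
) -> CVResults:
    """Cross-validated snapshot-ensemble training and test-role evaluation.

    For every (repeat, fold) evaluation: restrict columns to
    ``feature_subset`` if given, fit min-max normalization on the training
    role, train the snapshot ensemble, and score the averaged ensemble
    prediction on the test role.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    if plan is None:
        plan = make_cv_folds(dataset.n_patients, config.cv_k, config.cv_repeats,
                             seed=config.seed)
    X_all = dataset.dense()
    if feature_subset is not None:
        X_all = X_all[:, dataset.column_index(feature_subset)]
    y = np.asarray(dataset.labels)

    per_evaluation = []
    for i, a in enumerate(plan.assignments):
        cfg = TrainConfig(**{**config.to_dict(), "seed": _eval_seed(config.seed, i)})
        Xtr, stats = normalize(X_all[a.train])
        Xval, _ = normalize(X_all[a.validation], stats)
        Xte, _ = normalize(X_all[a.test], stats)
        ensemble = train_snapshots(Xtr, y[a.train], cfg, Xval, y[a.validation])
        _, pred = ensemble_predict(ensemble, Xte)
        per_evaluation.append((a.repeat, a.fold, confusion_metrics(y[a.test], pred)))

    agg, degenerate = _aggregate([m for _, _, m in per_evaluation])
    return CVResults(per_evaluation=per_evaluation, aggregate=agg,
                     n_degenerate=degenerate)


def _subset_val_accuracy(
    X_train: np.ndarray, y_train: np.ndarray,
    X_val: np.ndarray, y_val: np.ndarray,
    cols: np.ndarray, config: TrainConfig, seed: int, n_restarts: int = 3,
) -> float:
    """Validation accuracy of a column subset, averaged over a few seeded
    training restarts to damp training noise in subset comparisons."""
    Xtr, stats = normalize(X_train[:, cols])
    Xva, _ = normalize(X_val[:, cols], stats)
    accs = []
    for r in range(n_restarts):
        cfg = TrainConfig(**{**config.to_dict(), "seed": (seed + 7 * r) % 2**31})
        ensemble = train_snapshots(Xtr, y_train, cfg)
        _, pred = ensemble_predict(ensemble, Xva)
        accs.append(confusion_metrics(y_val, pred).accuracy)
    return float(np.mean(accs))


def backward_stepwise(
    dataset: EventMatrix,
    initial_subset: list[str],
    config: TrainConfig,
    tol: float | None = None,
    val_fraction: float = 0.25,
) -> tuple[list[str], list[tuple[str | None, float]]]:
    """Greedy backward elimination validated on a held-out role.

    Starting from ``initial_subset`` (at least two features), repeatedly
    retrain without each remaining feature and drop the one whose removal
    least degrades (or most improves) validation accuracy; stop when every
    candidate removal costs more than ``tol`` accuracy, or one feature is
    left.  Returns the surviving subset and the per-step trace of
    ``(removed_feature, accuracy)`` beginning with ``(None, baseline)``.
    """
    if len(initial_subset) < 2:
        raise ValueError("need at least two features to run elimination")
    if tol is None:
        tol = config.stepwise_tol
    if dataset.labels is None:
        raise ValueError("dataset has no labels")

    rng = np.random.default_rng(config.seed)
    n = dataset.n_patients
    order = rng.permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    val_idx, train_idx = order[:n_val], order[n_val:]
    X = dataset.dense()
    y = np.asarray(dataset.labels)
    Xtr_full, ytr = X[train_idx], y[train_idx]
    Xva_full, yva = X[val_idx], y[val_idx]

    current = list(initial_subset)
    cols = dataset.column_index(current)
    base = _subset_val_accuracy(
        Xtr_full, ytr, Xva_full, yva, cols, config, _eval_seed(config.seed, 0)
    )
    trace: list[tuple[str | None, float]] = [(None, base)]

    step = 0
    while len(current) > 1:
        step += 1
        # one shared training seed per step: candidate removals are then a
        # paired comparison, not confounded by training noise
        step_seed = _eval_seed(config.seed, step)
        candidates = []
        for name in current:
            keep = [f for f in current if f != name]
            acc = _subset_val_accuracy(
                Xtr_full, ytr, Xva_full, yva,
                dataset.column_index(keep), config, step_seed,
            )
            candidates.append((acc, name))
        best_acc, best_name = max(candidates, key=lambda c: (c[0], c[1]))
        if best_acc < base - tol:
            break
        current.remove(best_name)
        base = best_acc
        trace.append((best_name, best_acc))
    return current, trace


def rf_baseline_ranking(
    dataset: EventMatrix, n_trees: int = 200, seed: int = 0, n_repeats: int = 5
) -> np.ndarray:
    """Permutation-importance vector from a random-forest baseline.

    Delegates to scikit-learn: fit a forest on the normalized counts, then
    score each feature by the accuracy drop under column permutation.
    """
    if dataset.labels is None:
        raise ValueError("dataset has no labels")
    y = np.asarray(dataset.labels)
    if len(np.unique(y)) < 2:
        raise ValueError("labels are single-class; ranking is undefined")
    X, _ = normalize(dataset)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    forest.fit(X, y)
    result = permutation_importance(
        forest, X, y, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    return np.asarray(result.importances_mean)


def random_subset(p: int, k: int, seed: int) -> np.ndarray:
    """Uniform sample of k feature indices without replacement."""
    if k > p:
        raise ValueError(f"cannot draw {k} features from {p}")
    if k < 0:
        raise ValueError("k must be >= 0")
    return np.random.default_rng(seed).choice(p, size=k, replace=False)


def pearson_feature_correlation(
    feature_column: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """Product-moment correlation between one feature and the outcome,
    with a two-sided p-value.  For binary/binary input this is the phi
    coefficient."""
    x = np.asarray(feature_column, dtype=float).reshape(-1)
    y = np.asarray(labels, dtype=float).reshape(-1)
    if x.shape[0] != y.shape[0]:
        raise ValueError("length mismatch")
    if x.shape[0] < 3:
        raise ValueError("need at least three observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateStatisticError("correlation undefined for constant input")
    r, p = sp_stats.pearsonr(x, y)
    return float(r), float(p)


def paired_ttest(
    metrics_a: np.ndarray, metrics_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided paired t-test on per-evaluation metric values.

    The pairing is by (repeat, fold); zero variance of the differences
    (including identical vectors) makes the statistic undefined and raises
    :class:`DegenerateStatisticError`.
    """
    a = np.asarray(metrics_a, dtype=float).reshape(-1)
    b = np.asarray(metrics_b, dtype=float).reshape(-1)
    if a.shape != b.shape:
        raise ValueError("paired samples differ in length")
    if a.shape[0] < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if np.allclose(d, d[0], rtol=1e-9, atol=1e-12):
        raise DegenerateStatisticError(
            "paired differences have zero variance; t statistic undefined"
        )
    t, p = sp_stats.ttest_rel(a, b)
    return float(t), float(p)
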