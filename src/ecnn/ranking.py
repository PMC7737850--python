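"""Feature Sparsity Importance: ranking features from first-layer weights.

After entropy-regularized training the first weight matrix is a near-binary
gate.  For feature k with gate column W1_k (its weights into the J units of
the first hidden layer), the importance is

    R_k = (mean|W1_k| - var(|W1_k|)) / max_k mean|W1_k|

where the variance uses the sample (J-1) denominator.  A fully connected
feature (all weights near 1) scores near 1; a partially connected feature
is penalized through the variance term; a disconnected feature scores near
0.  The denominator self-normalizes each snapshot, and the per-snapshot
vectors are averaged into the final ranking.  Note R_k can go negative when
the variance exceeds the mean; negative values are kept for ranking and
floored at zero only by the cumulative-mass selection policy.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .training import SnapshotEnsemble

__all__ = [
    "ImportanceReport",
    "SelectionResult",
    "weight_variance",
    "feature_importance",
    "aggregate_importance",
    "categorize_features",
    "select_topk",
    "select_outliers",
    "select_cumulative",
    "importance_report",
    "apply_policy",
]

CATEGORIES = ("disconnected", "partial", "full")


@dataclass
class SelectionResult:
    """Outcome of one thresholding policy: the chosen features in
    descending-importance order with their aggregated values."""

    policy: str
    parameters: dict
    selected: list[tuple[str, float]]

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.selected]


@dataclass
class ImportanceReport:
    """Per-snapshot and aggregated importance values for every feature."""

    per_snapshot: np.ndarray  # (M, p)
    aggregated: np.ndarray  # (p,)
    feature_names: list[str]
    distribution_fit: tuple[float, float]  # (mu, sigma) of aggregated values
    categories: list[str]

    def __post_init__(self) -> None:
        M, p = self.per_snapshot.shape
        if not (len(self.aggregated) == len(self.feature_names)
                == len(self.categories) == p):
            raise ValueError("inconsistent lengths in importance report")


def weight_variance(column: np.ndarray) -> float:
    """Sample variance (denominator J-1) of one feature's absolute weights.

    High variance flags element-wise sparsity: some connections survive
    while others were driven to zero.
    """
    column = np.asarray(column, dtype=float)
    if column.ndim != 1 or column.shape[0] < 2:
        raise ValueError("need a 1-D column with at least two weights")
    return float(np.var(column, ddof=1))


def feature_importance(W1: np.ndarray) -> np.ndarray:
    """Feature Sparsity Importance for every feature of one weight matrix.

    ``W1`` has one row per input feature and one column per first-hidden
    unit (J >= 2).  Returns R_k = (mean|W1_k| - var(|W1_k|)) / max mean; if
    every mean is zero the whole vector is zero.
    """
    W1 = np.asarray(W1, dtype=float)
    if W1.ndim != 2 or W1.size == 0:
        raise ValueError("W1 must be a non-empty 2-D matrix")
    if W1.shape[1] < 2:
        raise ValueError("need at least two hidden units per feature")
    A = np.abs(W1)
    means = A.mean(axis=1)
    variances = np.var(A, axis=1, ddof=1)
    top = means.max()
    if top == 0:
        return np.zeros(W1.shape[0])
    return (means - variances) / top


def aggregate_importance(per_snapshot: Sequence[np.ndarray]) -> np.ndarray:
    """Elementwise mean of per-snapshot importance vectors."""
    arrays = [np.asarray(v, dtype=float) for v in per_snapshot]
    if not arrays:
        raise ValueError("no importance vectors to aggregate")
    if len({a.shape for a in arrays}) != 1:
        raise ValueError("importance vectors have mismatched lengths")
    return np.mean(arrays, axis=0)


def categorize_features(
    W1: np.ndarray, low: float = 0.1, high: float = 0.9
) -> list[str]:
    """Label each feature disconnected / partial / full from its gate column.

    A feature is disconnected when every weight sits at or below ``low``
    (all connections driven to zero), fully connected when every weight is
    at or above ``high``, and partially connected otherwise.
    """
    if not 0 <= low < high <= 1:
        raise ValueError("need 0 <= low < high <= 1")
    W1 = np.asarray(W1, dtype=float)
    out = []
    for row in W1:
        if (row <= low).all():
            out.append("disconnected")
        elif (row >= high).all():
            out.append("full")
        else:
            out.append("partial")
    return out


def _ordered(
    names: Sequence[str], values: np.ndarray, idx: np.ndarray
) -> list[tuple[str, float]]:
    """Sort selected indices by descending value, ties by ascending name."""
    chosen = sorted(idx, key=lambda i: (-values[i], names[i]))
    return [(names[i], float(values[i])) for i in chosen]


def select_topk(
    aggregated: np.ndarray, feature_names: Sequence[str], k: int
) -> SelectionResult:
    """The k largest importance values; ties broken by ascending name."""
    values = np.asarray(aggregated, dtype=float)
    p = values.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k={k} out of range for {p} features")
    order = sorted(range(p), key=lambda i: (-values[i], feature_names[i]))
    idx = np.array(order[:k])
    return SelectionResult(
        policy="top_k",
        parameters={"k": k},
        selected=_ordered(feature_names, values, idx),
    )


def select_outliers(
    aggregated: np.ndarray, feature_names: Sequence[str], n_sigma: float = 3.0
) -> SelectionResult:
    """Features lying strictly above mean + n_sigma * sd of the aggregated
    importance distribution.

    The normal fit is plain moment matching over all values; with zero
    spread nothing is selected.
    """
    values = np.asarray(aggregated, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two features to fit a distribution")
    mu = float(values.mean())
    sigma = float(values.std(ddof=0))
    idx = np.flatnonzero(values > mu + n_sigma * sigma)
    return SelectionResult(
        policy="sigma_outlier",
        parameters={"n_sigma": n_sigma, "mu": mu, "sigma": sigma},
        selected=_ordered(feature_names, values, idx),
    )


def select_cumulative(
    aggregated: np.ndarray, feature_names: Sequence[str], quantile: float = 0.95
) -> SelectionResult:
    """Smallest descending-importance prefix holding ``quantile`` of the
    total importance mass (negative values floored at zero)."""
    if not 0 < quantile < 1:
        raise ValueError("quantile must be in (0, 1)")
    values = np.asarray(aggregated, dtype=float)
    floored = np.maximum(values, 0.0)
    total = floored.sum()
    if total == 0:
        return SelectionResult(
            policy="cumulative", parameters={"quantile": quantile}, selected=[]
        )
    order = sorted(range(len(values)), key=lambda i: (-floored[i], feature_names[i]))
    acc = 0.0
    chosen: list[int] = []
    for i in order:
        if acc >= quantile * total:
            break
        chosen.append(i)
        acc += floored[i]
    return SelectionResult(
        policy="cumulative",
        parameters={"quantile": quantile},
        selected=[(feature_names[i], float(floored[i])) for i in chosen],
    )


def importance_report(
    ensemble: SnapshotEnsemble,
    feature_names: Sequence[str],
    low: float = 0.1,
    high: float = 0.9,
) -> ImportanceReport:
    """Importance of every feature across an ensemble's snapshots.

    Each snapshot's first layer is scored (self-normalized) and the vectors
    are averaged; categories come from a majority vote of the per-snapshot
    labels, ties resolved to "partial".
    """
    per = np.vstack([feature_importance(W1) for W1 in ensemble.first_layers])
    agg = aggregate_importance(list(per))
    cats_per_snapshot = [categorize_features(W1, low, high)
                         for W1 in ensemble.first_layers]
    categories = []
    for labels in zip(*cats_per_snapshot):
        count = Counter(labels)
        top = count.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            categories.append("partial")
        else:
            categories.append(top[0][0])
    return ImportanceReport(
        per_snapshot=per,
        aggregated=agg,
        feature_names=list(feature_names),
        distribution_fit=(float(agg.mean()), float(agg.std(ddof=0))),
        categories=categories,
    )


def apply_policy(
    report: ImportanceReport,
    policy: str,
    *,
    k: int = 10,
    n_sigma: float = 3.0,
    quantile: float = 0.95,
) -> SelectionResult:
    """Dispatch one of the three thresholding policies on a report."""
    if policy == "top_k":
        return select_topk(report.aggregated, report.feature_names, k)
    if policy == "sigma_outlier":
        return select_outliers(report.aggregated, report.feature_names, n_sigma)
    if policy == "cumulative":
        return select_cumulative(report.aggregated, report.feature_names, quantile)
    raise ValueError(f"unknown policy {policy!r}")
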