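"""Synthetic coded-event cohorts and the preprocessing they share with real data.

The cohorts emulated here are patient-by-event count matrices as extracted
from primary-care records: one column per unique event code (diagnosis,
prescription, procedure), one row per patient, cell = number of occurrences
over a fixed observation window.  Such matrices are extremely sparse — a
patient uses a tiny subset of the code vocabulary — and carry a binary
outcome label (e.g. hospitalized / not hospitalized).

A small subset of "planted" features carries the signal for the label via a
logistic model with optional pairwise interaction terms, so that recovery of
the planted set by a feature-selection method is a meaningful benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "EventLog",
    "EventMatrix",
    "SimConfig",
    "FoldPlan",
    "FoldAssignment",
    "NormalizationStats",
    "generate_cohort",
    "encode_events",
    "normalize",
    "make_cv_folds",
]


@dataclass
class EventLog:
    """Long-format event records: (patient_id, event_code, count) triples.

    Counts are non-negative integers; duplicate (patient, code) pairs are
    legal in the raw log and are summed during encoding.
    """

    records: list[tuple[str, str, int]]

    def __post_init__(self) -> None:
        for pid, code, count in self.records:
            if count < 0 or int(count) != count:
                raise ValueError(
                    f"event count must be a non-negative integer, got {count!r} "
                    f"for ({pid!r}, {code!r})"
                )


@dataclass
class EventMatrix:
    """Sparse patient x event-code count matrix with labels.

    Attributes
    ----------
    values : scipy.sparse.csr_matrix
        Non-negative counts, shape (n_patients, n_features).
    feature_names : list of str
        Unique event-code names, one per column.
    labels : ndarray of {0, 1} or None
        Binary outcome per patient; None for unlabeled matrices.
    planted_features : ndarray of int or None
        Column indices of the features that carry label signal; only set by
        :func:`generate_cohort` and used for benchmarking recovery.
    """

    values: sp.csr_matrix
    feature_names: list[str]
    labels: np.ndarray | None = None
    planted_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        n, p = self.values.shape
        if len(self.feature_names) != p:
            raise ValueError(
                f"{len(self.feature_names)} feature names for {p} columns"
            )
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")
        if self.values.nnz and self.values.data.min() < 0:
            raise ValueError("counts must be non-negative")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if self.labels.shape != (n,):
                raise ValueError(
                    f"label length {self.labels.shape} does not match {n} patients"
                )
            if not np.isin(self.labels, [0, 1]).all():
                raise ValueError("labels must be in {0, 1}")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense(self) -> np.ndarray:
        """Counts as a dense float array."""
        return np.asarray(self.values.todense(), dtype=float)

    def column_index(self, names: Sequence[str]) -> np.ndarray:
        """Map feature names to column indices, raising on unknown names."""
        lookup = {name: i for i, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in lookup]
        if missing:
            raise KeyError(f"unknown feature names: {missing[:5]}")
        return np.array([lookup[n] for n in names], dtype=int)


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator.

    Defaults describe a desk-scale stand-in for a primary-care cohort:
    2 000 patients, 500 event codes, 85 % empty cells, counts averaging 1.5
    per occupied cell, and 10 planted signal features of which one pair acts
    only through its product.
    """

    n_patients: int = 2000
    n_features: int = 500
    n_informative: int = 10
    sparsity: float = 0.85
    signal_strength: float = 5.0
    interaction_fraction: float = 0.2
    count_dispersion: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError(
                f"n_informative={self.n_informative} exceeds "
                f"n_features={self.n_features}"
            )
        if not 0.0 <= self.sparsity < 1.0:
            raise ValueError("sparsity must be in [0, 1)")
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")
        if not 0.0 <= self.interaction_fraction <= 1.0:
            raise ValueError("interaction_fraction must be in [0, 1]")
        if self.count_dispersion < 1.0:
            raise ValueError("count_dispersion (mean count per occupied cell) must be >= 1")
        if self.n_patients < 1 or self.n_features < 1:
            raise ValueError("n_patients and n_features must be positive")


@dataclass
class FoldAssignment:
    """Train/validation/test role split for one CV evaluation."""

    repeat: int
    fold: int
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


@dataclass
class FoldPlan:
    """k-fold plan with cyclic train/validation/test role rotation.

    Within a repeat every patient sits in exactly one fold; each fold serves
    as the test role exactly once, the next fold (cyclically) as validation,
    and the remaining k-2 folds as training.
    """

    assignments: list[FoldAssignment]
    k: int
    repeats: int
    seed: int


@dataclass
class NormalizationStats:
    """Per-feature min/max fitted on a reference (training) matrix."""

    col_min: np.ndarray
    col_max: np.ndarray

    @property
    def n_features(self) -> int:
        return self.col_min.shape[0]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def generate_cohort(config: SimConfig) -> EventMatrix:
    """Generate a sparse count cohort with planted label signal.

    Cell occupancy is Bernoulli(1 - sparsity); occupied cells draw a
    positive count from a geometric distribution with mean
    ``count_dispersion``.  Labels come from a logistic model on the
    standardized planted columns: a share ``interaction_fraction`` of the
    planted features (rounded down to an even count) contributes only
    through pairwise products, the rest through main effects, and the
    linear predictor is scaled by ``signal_strength`` so that
    ``signal_strength=0`` makes labels independent coin flips.

    Fully reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n, p = config.n_patients, config.n_features

    density = 1.0 - config.sparsity
    geom_p = 1.0 / config.count_dispersion
    counts = sp.random(
        n,
        p,
        density=density,
        format="csr",
        random_state=rng,
        data_rvs=lambda size: rng.geometric(geom_p, size=size).astype(float),
    )

    planted = np.sort(rng.choice(p, size=config.n_informative, replace=False))

    # Standardize planted columns; a degenerate all-constant column carries
    # no signal and standardizes to zero.
    Z = np.zeros((n, config.n_informative))
    dense_planted = np.asarray(counts[:, planted].todense(), dtype=float)
    mu = dense_planted.mean(axis=0)
    sd = dense_planted.std(axis=0)
    nonconst = sd > 0
    Z[:, nonconst] = (dense_planted[:, nonconst] - mu[nonconst]) / sd[nonconst]

    n_inter = int(config.interaction_fraction * config.n_informative) // 2 * 2
    inter_local = np.arange(config.n_informative - n_inter, config.n_informative)
    main_local = np.arange(config.n_informative - n_inter)

    eta = np.zeros(n)
    n_terms = 0
    signs_main = rng.choice([-1.0, 1.0], size=main_local.size)
    for s, j in zip(signs_main, main_local):
        eta += s * Z[:, j]
        n_terms += 1
    for a, b in zip(inter_local[0::2], inter_local[1::2]):
        eta += rng.choice([-1.0, 1.0]) * Z[:, a] * Z[:, b]
        n_terms += 1
    if n_terms:
        eta /= np.sqrt(n_terms)
    eta *= config.signal_strength

    labels = rng.binomial(1, _sigmoid(eta)).astype(int)

    width = max(5, len(str(p - 1)))
    names = [f"ev{i:0{width}d}" for i in range(p)]
    return EventMatrix(
        values=counts, feature_names=names, labels=labels, planted_features=planted
    )


def encode_events(log: EventLog) -> EventMatrix:
    """One-hot frequency encoding of an event log.

    One column per distinct event code and one row per distinct patient,
    both in lexicographic order; the cell holds the summed occurrence count
    and absent pairs are zero.  Labels are not part of an event log, so the
    returned matrix is unlabeled.
    """
    if not log.records:
        raise ValueError("cannot encode an empty event log")
    frame = pd.DataFrame(log.records, columns=["patient_id", "event_code", "count"])
    table = (
        frame.pivot_table(
            index="patient_id",
            columns="event_code",
            values="count",
            aggfunc="sum",
            fill_value=0,
        )
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    return EventMatrix(
        values=sp.csr_matrix(table.to_numpy(dtype=float)),
        feature_names=[str(c) for c in table.columns],
    )


def normalize(
    matrix: EventMatrix | sp.spmatrix | np.ndarray,
    reference_stats: NormalizationStats | None = None,
) -> tuple[np.ndarray, NormalizationStats]:
    """Per-feature min-max scaling to [0, 1].

    When ``reference_stats`` is given (fitted on the training role) it is
    applied and values outside [0, 1] are clipped; otherwise the stats are
    computed from ``matrix`` itself.  Constant features map to all-zero.
    Returns the scaled dense array and the stats used.
    """
    if isinstance(matrix, EventMatrix):
        X = matrix.dense()
    elif sp.issparse(matrix):
        X = np.asarray(matrix.todense(), dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D matrix")

    if reference_stats is None:
        stats = NormalizationStats(
            col_min=X.min(axis=0).astype(float), col_max=X.max(axis=0).astype(float)
        )
    else:
        if reference_stats.n_features != X.shape[1]:
            raise ValueError(
                f"reference stats cover {reference_stats.n_features} features, "
                f"matrix has {X.shape[1]}"
            )
        stats = reference_stats

    span = stats.col_max - stats.col_min
    scaled = np.zeros_like(X)
    ok = span > 0
    scaled[:, ok] = (X[:, ok] - stats.col_min[ok]) / span[ok]
    np.clip(scaled, 0.0, 1.0, out=scaled)
    return scaled, stats


def make_cv_folds(n: int, k: int, repeats: int, seed: int) -> FoldPlan:
    """Random k-fold plan with cyclic train/validation/test roles.

    Each repeat shuffles the patients into k folds whose sizes differ by at
    most one.  For each of the k rotations, one fold is the test set, the
    cyclically next fold the validation set, and the remaining k-2 folds the
    training set — giving k x repeats evaluations.
    """
    if k < 3:
        raise ValueError("k must be >= 3 to host train/validation/test roles")
    if n < k:
        raise ValueError(f"cannot split {n} samples into {k} folds")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")

    rng = np.random.default_rng(seed)
    assignments: list[FoldAssignment] = []
    for rep in range(repeats):
        order = rng.permutation(n)
        folds = [np.sort(chunk) for chunk in np.array_split(order, k)]
        for r in range(k):
            test = folds[r]
            validation = folds[(r + 1) % k]
            train = np.sort(
                np.concatenate(
                    [folds[i] for i in range(k) if i not in (r, (r + 1) % k)]
                )
            )
            assignments.append(
                FoldAssignment(
                    repeat=rep, fold=r, train=train, validation=validation, test=test
                )
            )
    return FoldPlan(assignments=assignments, k=k, repeats=repeats, seed=seed)
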