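"""Snapshot-ensemble training under a cyclic cosine learning-rate schedule.

A single network is trained for T epochs of mini-batch SGD.  The learning
rate follows a cosine curve that restarts M times over training:

    alpha(t) = (alpha0 / 2) * (cos(pi * mod(t-1, c) / c) + 1),  c = ceil(T/M)

Each restart spikes the rate back to alpha0, dislodging the model from its
current minimum; the parameters captured at the end of each cycle form an
M-member ensemble whose averaged probabilities are the final prediction.
The first-layer weights are projected back to [0, 1] after every step so
the entropy penalty stays well defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import TrainConfig
from .network import (
    NetworkParams,
    cross_entropy,
    entropy_penalty,
    forward,
    gradients,
    init_network,
    project_first_layer,
)

__all__ = [
    "ScheduleConfig",
    "SnapshotEnsemble",
    "cosine_lr",
    "train_snapshots",
    "ensemble_predict",
]


@dataclass
class ScheduleConfig:
    """Cyclic cosine schedule: initial rate alpha0, T epochs, M cycles."""

    alpha0: float
    T: int
    M: int

    def __post_init__(self) -> None:
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if not 1 <= self.M <= self.T:
            raise ValueError("need 1 <= M <= T")

    @property
    def cycle_length(self) -> int:
        return math.ceil(self.T / self.M)


def cosine_lr(t: int, cfg: ScheduleConfig) -> float:
    """Learning rate at 1-based epoch ``t``.

    Closed form, no state: within each cycle of length ``c = ceil(T/M)``
    the rate falls from alpha0 at the cycle start to near zero at the cycle
    end, then snaps back to alpha0.
    """
    if t < 1:
        raise ValueError(f"epoch index must be >= 1, got {t}")
    if t > cfg.T:
        raise ValueError(f"epoch index {t} exceeds T={cfg.T}")
    c = cfg.cycle_length
    return cfg.alpha0 / 2.0 * (math.cos(math.pi * ((t - 1) % c) / c) + 1.0)


@dataclass
class SnapshotEnsemble:
    """M captured parameter sets plus the schedule and history that produced
    them."""

    snapshots: list[NetworkParams]
    schedule: ScheduleConfig
    train_history: pd.DataFrame = field(repr=False)

    @property
    def n_members(self) -> int:
        return len(self.snapshots)

    @property
    def first_layers(self) -> list[np.ndarray]:
        return [s.first_layer for s in self.snapshots]


def train_snapshots(
    X_train: np.ndarray,
    y_train: np.ndarray,
    config: TrainConfig,
    X_val: np.ndarray | None = None,
    y_val: np.ndarray | None = None,
) -> SnapshotEnsemble:
    """Train one network, capturing a snapshot at the end of each cosine
    cycle.

    Plain mini-batch SGD (no momentum) so the cosine schedule is the only
    rate control; first-layer weights are clamped to [0, 1] after every
    step.  Deterministic given ``config.seed``.  Per-epoch learning rate,
    training loss (cross-entropy, penalty, total) and validation loss are
    logged in ``train_history``.

    Raises ``RuntimeError`` naming the epoch if the loss goes non-finite.
    """
    # single precision: halves the arithmetic cost of training on one CPU
    # and is far above the resolution any of the statistics here need
    X_train = np.asarray(X_train, dtype=np.float32)
    y_train = np.asarray(y_train, dtype=np.float32).reshape(-1)
    if X_train.shape[0] == 0:
        raise ValueError("training set is empty")
    if X_train.shape[0] != y_train.shape[0]:
        raise ValueError("training labels do not match rows")

    schedule = ScheduleConfig(alpha0=config.alpha0, T=config.epochs, M=config.n_snapshots)
    cycle = schedule.cycle_length
    rng = np.random.default_rng(config.seed)
    params = init_network(
        config.layer_sizes(X_train.shape[1]),
        seed=int(rng.integers(2**31)),
        first_layer_range=config.init_range,
        hidden_activation=config.hidden_activation,
    )
    params.weights = [W.astype(np.float32) for W in params.weights]
    params.biases = [b.astype(np.float32) for b in params.biases]

    n = X_train.shape[0]
    snapshots: list[NetworkParams] = []
    history: dict[str, list[float]] = {
        "epoch": [], "lr": [], "train_cross_entropy": [],
        "train_penalty": [], "train_total": [], "val_loss": [],
    }

    if X_val is not None:
        X_val = np.asarray(X_val, dtype=np.float32)
        y_val = np.asarray(y_val, dtype=np.float32).reshape(-1)

    for t in range(1, schedule.T + 1):
        lr = cosine_lr(t, schedule)
        order = rng.permutation(n)
        ce_sum = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            grad_W, grad_b, batch_ce = gradients(
                params, X_train[idx], y_train[idx], config.reg_lambda,
                return_cross_entropy=True,
            )
            ce_sum += batch_ce * idx.size
            for l in range(len(params.weights)):
                params.weights[l] -= lr * grad_W[l]
                params.biases[l] -= lr * grad_b[l]
            params.weights[0] = project_first_layer(params.weights[0])

        # epoch loss = running mean of batch cross-entropies (pre-update)
        # plus the penalty at epoch end; avoids an extra full forward pass
        ce_epoch = ce_sum / n
        penalty = entropy_penalty(params.first_layer)
        total = ce_epoch + config.reg_lambda * penalty
        if not np.isfinite(total):
            raise RuntimeError(f"non-finite training loss at epoch {t}")
        val_loss = math.nan
        if X_val is not None and len(X_val):
            val_loss = cross_entropy(forward(params, X_val), y_val)
        history["epoch"].append(t)
        history["lr"].append(lr)
        history["train_cross_entropy"].append(ce_epoch)
        history["train_penalty"].append(penalty)
        history["train_total"].append(total)
        history["val_loss"].append(val_loss)

        end_of_cycle = (t - 1) % cycle == cycle - 1
        if (end_of_cycle or (t == schedule.T and len(snapshots) < schedule.M)) and \
                len(snapshots) < schedule.M:
            snapshots.append(params.copy())

    return SnapshotEnsemble(
        snapshots=snapshots,
        schedule=schedule,
        train_history=pd.DataFrame(history),
    )


def ensemble_predict(
    ensemble: SnapshotEnsemble, X: np.ndarray, threshold: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean of the member probability outputs.

    Returns ``(probabilities, labels)`` with labels thresholded at 0.5
    (probability >= threshold maps to class 1).
    """
    if ensemble.n_members == 0:
        raise ValueError("ensemble has no snapshots")
    members = np.stack([forward(s, X) for s in ensemble.snapshots])
    # compensated mean: exact when every member output coincides, and
    # within rounding of the arithmetic mean otherwise
    probs = members[0] + (members - members[0]).mean(axis=0)
    return probs, (probs >= threshold).astype(int)
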