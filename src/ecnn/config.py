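"""Training configuration: every knob of the pipeline lives here.

Fields marked method-fixed in :data:`METHOD_FIXED` are part of the published
method description (hidden-layer sizes, the top-k selection default); the
rest are implementation defaults and are flagged as such when a config is
serialized, so downstream users can tell the two apart.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Any

__all__ = ["TrainConfig", "METHOD_FIXED"]

# Fields whose default values are fixed by the method description rather
# than chosen by this implementation.
METHOD_FIXED = frozenset({"hidden_sizes", "top_k", "cv_k", "cv_repeats"})


@dataclass
class TrainConfig:
    """Architecture, regularization, schedule, CV and selection settings.

    Parameters
    ----------
    hidden_sizes : tuple of int
        Hidden-layer perceptron counts; the input width comes from the data
        and the output layer is a single sigmoid unit.
    reg_lambda : float
        Coefficient of the entropy weight penalty (0 disables it).
    alpha0 : float
        Initial learning rate of the cyclic cosine schedule.
    epochs : int
        Total training epochs T.
    n_snapshots : int
        Number of cosine cycles M; one parameter snapshot per cycle.
    batch_size : int
        Mini-batch size for SGD.
    hidden_activation : str
        ``"leaky_relu"`` (default), ``"relu"`` or ``"linear"``.
    init_range : tuple of float
        Uniform initialization interval for the bounded first layer; kept
        below the entropy watershed 1/e so a feature disconnects unless the
        data gradient promotes it.
    seed : int
        Seed for initialization and batch shuffling.
    cv_k, cv_repeats : int
        Fold count and repeat count of the cross-validation plan.
    selection_policy : str
        ``"top_k"``, ``"sigma_outlier"`` or ``"cumulative"``.
    top_k, n_sigma, cumulative_quantile : selection-policy parameters.
    stepwise_tol : float
        Absolute validation-accuracy tolerance of backward-stepwise
        elimination.
    """

    hidden_sizes: tuple[int, ...] = (50, 30)
    reg_lambda: float = 0.01
    alpha0: float = 0.05
    epochs: int = 1000
    n_snapshots: int = 5
    batch_size: int = 64
    hidden_activation: str = "leaky_relu"
    init_range: tuple[float, float] = (0.2, 0.35)
    seed: int = 0
    cv_k: int = 5
    cv_repeats: int = 2
    selection_policy: str = "sigma_outlier"
    top_k: int = 10
    n_sigma: float = 3.0
    cumulative_quantile: float = 0.95
    stepwise_tol: float = 0.002

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        self.init_range = tuple(float(v) for v in self.init_range)
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if self.reg_lambda < 0:
            raise ValueError("reg_lambda must be >= 0")
        if self.alpha0 <= 0:
            raise ValueError("alpha0 must be > 0")
        if self.epochs < 1 or self.n_snapshots < 1:
            raise ValueError("epochs and n_snapshots must be positive")
        if self.n_snapshots > self.epochs:
            raise ValueError("n_snapshots cannot exceed epochs")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.cv_k < 3 or self.cv_repeats < 1:
            raise ValueError("cv_k must be >= 3 and cv_repeats >= 1")
        if self.selection_policy not in {"top_k", "sigma_outlier", "cumulative"}:
            raise ValueError(f"unknown selection policy {self.selection_policy!r}")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if not 0 < self.cumulative_quantile < 1:
            raise ValueError("cumulative_quantile must be in (0, 1)")
        if self.stepwise_tol < 0:
            raise ValueError("stepwise_tol must be >= 0")

    def layer_sizes(self, n_features: int) -> list[int]:
        """Full layer-size chain for a given input width."""
        return [int(n_features), *self.hidden_sizes, 1]

    def to_dict(self, flag_provenance: bool = False) -> dict[str, Any]:
        """Plain-dict form; with ``flag_provenance`` each field becomes
        ``{"value": ..., "method_fixed": bool}``."""
        raw = dataclasses.asdict(self)
        raw["hidden_sizes"] = list(self.hidden_sizes)
        raw["init_range"] = list(self.init_range)
        if not flag_provenance:
            return raw
        return {
            key: {"value": val, "method_fixed": key in METHOD_FIXED}
            for key, val in raw.items()
        }

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "TrainConfig":
        """Inverse of :meth:`to_dict`, accepting either serialized form."""
        clean: dict[str, Any] = {}
        names = {f.name for f in dataclasses.fields(cls)}
        for key, val in data.items():
            if key not in names:
                raise ValueError(f"unknown config field {key!r}")
            clean[key] = val["value"] if isinstance(val, dict) and "value" in val else val
        return cls(**clean)
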