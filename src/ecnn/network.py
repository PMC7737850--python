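"""Feed-forward classifier with bounded first-layer weights and an entropy
weight penalty.

The first layer acts as a soft gate on the input features: its weights are
constrained to [0, 1] by projection after every optimizer step, and the
training cost adds the entropy-style penalty ``-sum(w * log w)`` over those
weights.  The penalty is zero exactly when every weight sits at 0 or 1 and
is maximized per weight at 1/e, so minimizing it drives the gate towards a
binary connect/disconnect pattern — disconnected features are filtered out
of the model, which is what the downstream feature ranking exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EPS",
    "NetworkParams",
    "LossBreakdown",
    "init_network",
    "forward",
    "entropy_penalty",
    "cross_entropy",
    "total_loss",
    "gradients",
    "project_first_layer",
]

# Floor inside every log; predictions are clipped to [EPS, 1 - EPS].
EPS = 1e-12

_LEAKY_SLOPE = 0.01

_ACTIVATIONS = {
    "relu": (
        lambda z: np.maximum(z, 0.0),
        lambda z: (z > 0).astype(float),
    ),
    # leaky rectifier: keeps a small gradient on inactive units so a
    # learning-rate restart cannot kill a hidden layer irreversibly
    "leaky_relu": (
        lambda z: np.where(z > 0, z, _LEAKY_SLOPE * z),
        lambda z: np.where(z > 0, 1.0, _LEAKY_SLOPE),
    ),
    "linear": (
        lambda z: z,
        lambda z: np.ones_like(z),
    ),
}


@dataclass
class NetworkParams:
    """Layered weights and biases.

    ``weights[l]`` has shape (units in layer l, units in layer l+1); row j,
    column k is the edge from unit j to unit k of the next layer.  The first
    weight matrix therefore has one row per input feature, and that row is
    the feature's gate vector inspected by the importance metric.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    hidden_activation: str = "relu"

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.biases):
            raise ValueError("weights and biases must have the same depth")
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            if W.shape[1] != b.shape[0]:
                raise ValueError(f"layer {i}: weight/bias shape mismatch")
            if i and self.weights[i - 1].shape[1] != W.shape[0]:
                raise ValueError(f"layer {i}: shape chain broken")
        if self.hidden_activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.hidden_activation!r}")

    @property
    def layer_sizes(self) -> list[int]:
        return [self.weights[0].shape[0]] + [W.shape[1] for W in self.weights]

    @property
    def first_layer(self) -> np.ndarray:
        return self.weights[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            weights=[W.copy() for W in self.weights],
            biases=[b.copy() for b in self.biases],
            hidden_activation=self.hidden_activation,
        )


@dataclass
class LossBreakdown:
    """Cross-entropy cost plus the lambda-weighted entropy penalty."""

    cross_entropy: float
    entropy_penalty: float
    lam: float

    @property
    def total(self) -> float:
        return self.cross_entropy + self.lam * self.entropy_penalty


def init_network(
    layer_sizes: list[int],
    seed: int,
    first_layer_range: tuple[float, float] = (0.25, 0.75),
    hidden_activation: str = "relu",
) -> NetworkParams:
    """Seeded initialization.

    First-layer weights start uniform inside ``first_layer_range`` (a
    sub-interval of the [0, 1] bound) so the entropy pressure can resolve
    each weight towards either extreme; deeper layers use He-style normal
    initialization and biases start at zero.
    """
    lo, hi = first_layer_range
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("first_layer_range must satisfy 0 <= low < high <= 1")
    rng = np.random.default_rng(seed)
    weights: list[np.ndarray] = []
    biases: list[np.ndarray] = []
    for i, (fan_in, fan_out) in enumerate(zip(layer_sizes[:-1], layer_sizes[1:])):
        if i == 0:
            W = rng.uniform(lo, hi, size=(fan_in, fan_out))
        else:
            W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out))
        weights.append(W)
        biases.append(np.zeros(fan_out))
    return NetworkParams(
        weights=weights, biases=biases, hidden_activation=hidden_activation
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _forward_cached(
    params: NetworkParams, X: np.ndarray
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Forward pass keeping pre-activations and activations per layer."""
    X = np.asarray(X)
    if not np.issubdtype(X.dtype, np.floating):
        X = X.astype(float)
    if X.ndim != 2 or X.shape[1] != params.layer_sizes[0]:
        raise ValueError(
            f"input has shape {X.shape}, expected (n, {params.layer_sizes[0]})"
        )
    if not np.isfinite(X).all():
        raise ValueError("input contains non-finite values")
    act, _ = _ACTIVATIONS[params.hidden_activation]
    pre: list[np.ndarray] = []
    activations: list[np.ndarray] = [X]
    A = X
    depth = len(params.weights)
    for i, (W, b) in enumerate(zip(params.weights, params.biases)):
        Z = A @ W + b
        pre.append(Z)
        A = _sigmoid(Z) if i == depth - 1 else act(Z)
        activations.append(A)
    return pre, activations


def forward(params: NetworkParams, X: np.ndarray) -> np.ndarray:
    """Probability output of the network, one value in (0, 1) per sample.

    Hidden layers apply the configured activation (rectifier by default);
    the single output unit applies the logistic sigmoid.
    """
    _, activations = _forward_cached(params, X)
    out = activations[-1]
    out = out[:, 0] if out.ndim == 2 and out.shape[1] == 1 else out
    # double precision on the public surface regardless of training dtype
    return np.clip(out.astype(np.float64), EPS, 1.0 - EPS)


def entropy_penalty(W1: np.ndarray, tol: float = 1e-8) -> float:
    """``-sum(w * log w)`` over the first-layer weights, natural log.

    Uses the convention 0*log 0 = 0 via a floor inside the log.  Entries
    must lie in [0, 1] (up to ``tol``) — the projection step guarantees
    this during training, so a violation signals a broken contract.
    """
    W1 = np.asarray(W1, dtype=float)
    if W1.min() < -tol or W1.max() > 1.0 + tol:
        raise ValueError(
            f"first-layer weights outside [0, 1]: range "
            f"[{W1.min():.3g}, {W1.max():.3g}]"
        )
    W = np.clip(W1, 0.0, 1.0)
    return float(-np.sum(W * np.log(np.maximum(W, EPS))))


def cross_entropy(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy with predictions clipped to [EPS, 1-EPS]."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    q = np.clip(y_hat, EPS, 1.0 - EPS)
    return float(-np.mean(y * np.log(q) + (1.0 - y) * np.log(1.0 - q)))


def total_loss(
    y_hat: np.ndarray, y: np.ndarray, W1: np.ndarray, lam: float
) -> LossBreakdown:
    """Cross-entropy averaged over the batch plus ``lam`` times the entropy
    penalty on the first-layer weights."""
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return LossBreakdown(
        cross_entropy=cross_entropy(y_hat, y),
        entropy_penalty=entropy_penalty(W1),
        lam=lam,
    )


def _entropy_grad(W1: np.ndarray) -> np.ndarray:
    """Derivative of ``-w * log(max(w, EPS))`` elementwise."""
    W = np.asarray(W1)
    small = W <= EPS
    g = np.maximum(W, EPS)
    np.log(g, out=g)
    g += 1.0
    np.negative(g, out=g)
    g[small] = -np.log(EPS)
    return g


def gradients(
    params: NetworkParams,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    return_cross_entropy: bool = False,
):
    """Analytic gradients of the total loss w.r.t. every weight and bias.

    Backpropagation with the sigmoid/cross-entropy shortcut at the output
    unit; the entropy-penalty term contributes only to the first weight
    matrix.  Cross-entropy is averaged over the batch, so gradients are
    batch-size independent in scale.
    """
    pre, activations = _forward_cached(params, X)
    y = np.asarray(y, dtype=activations[0].dtype).reshape(-1)
    n = X.shape[0]
    if y.shape[0] != n:
        raise ValueError("label length does not match input rows")
    _, dact = _ACTIVATIONS[params.hidden_activation]

    depth = len(params.weights)
    grad_W: list[np.ndarray] = [np.empty(0)] * depth
    grad_b: list[np.ndarray] = [np.empty(0)] * depth

    y_hat = activations[-1][:, 0]
    delta = ((y_hat - y) / n)[:, None]
    for l in range(depth - 1, -1, -1):
        grad_W[l] = activations[l].T @ delta
        grad_b[l] = delta.sum(axis=0)
        if l:
            delta = (delta @ params.weights[l].T) * dact(pre[l - 1])

    if lam > 0:
        grad_W[0] = grad_W[0] + lam * _entropy_grad(params.weights[0])
    if return_cross_entropy:
        return grad_W, grad_b, cross_entropy(y_hat, y)
    return grad_W, grad_b


def project_first_layer(W1: np.ndarray) -> np.ndarray:
    """Elementwise clamp of the first-layer weights to [0, 1]; idempotent."""
    W1 = np.asarray(W1)
    if not np.issubdtype(W1.dtype, np.floating):
        W1 = W1.astype(float)
    if not np.isfinite(W1).all():
        raise ValueError("cannot project non-finite weights")
    return np.clip(W1, 0.0, 1.0)
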