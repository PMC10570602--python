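"""Network core: per-feature linear skip plus a single-layer ReLU RNN.

The classifier scores a subject's (Q, M) series as

    h_0 = 0
    h_t = relu(W_in x_t + W_rec h_{t-1} + b_h),   t = 1..Q
    logit = w_out . h_Q + b_out + b_skip + sum_j theta_j * mean_t x[t, j]

so each variable j owns one penalized skip coefficient ``theta_j`` and
one column ``W_in[:, j]`` of the (time-shared) input-to-hidden matrix.
The hierarchy constraint ``max_k |W_in[k, j]| <= M_hier * |theta_j]|`` is
enforced by the proximal step in :mod:`lassonet_rnn.prox`, not here.

Everything is plain NumPy with analytic gradients; the models this
package targets are small (tens of variables, a handful of waves), where
BLAS-backed NumPy is entirely adequate and keeps the dependency
footprint to the scientific base stack.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HyperParams",
    "LassoNetRNNParams",
    "AdamState",
    "init_params",
    "rnn_forward",
    "forward_batch",
    "predict_proba",
    "smooth_loss",
    "loss_and_grads",
    "adam_step",
    "save_checkpoint",
    "load_checkpoint",
]

_PARAM_FIELDS = (
    "theta",
    "input_weights",
    "recurrent_weights",
    "hidden_bias",
    "output_weights",
    "output_bias",
    "skip_bias",
)


@dataclass(frozen=True)
class HyperParams:
    """Training configuration; all positivity constraints are validated."""

    hidden_size: int = 16
    m_hier: float = 10.0  # hierarchy multiplier; math.inf = unconstrained
    lambda_start: float | None = None  # None = auto-calibrated
    path_multiplier: float = 1.02
    epochs_per_lambda: int = 100
    dense_epochs: int = 100
    learning_rate: float = 1e-3
    path_learning_rate: float | None = None  # None = same as learning_rate
    batch_size: int = 64
    seed: int = 0
    patience: int = 5

    @property
    def effective_path_lr(self) -> float:
        return self.learning_rate if self.path_learning_rate is None else self.path_learning_rate

    def __post_init__(self) -> None:
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        if not (self.m_hier > 0 or self.m_hier == 0 or math.isinf(self.m_hier)):
            raise ValueError("m_hier must be >= 0 or +inf")
        if self.m_hier < 0:
            raise ValueError("m_hier must be >= 0 or +inf")
        if self.lambda_start is not None and self.lambda_start <= 0:
            raise ValueError("lambda_start must be positive (or None for auto)")
        if self.path_multiplier <= 1:
            raise ValueError("path_multiplier must be > 1")
        for name in ("epochs_per_lambda", "dense_epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.path_learning_rate is not None and self.path_learning_rate <= 0:
            raise ValueError("path_learning_rate must be positive (or None)")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")


@dataclass
class LassoNetRNNParams:
    """All trainable parameters; ``theta[j]`` is variable j's skip weight."""

    theta: np.ndarray  # (M,)
    input_weights: np.ndarray  # (H, M), column j gates with theta[j]
    recurrent_weights: np.ndarray  # (H, H)
    hidden_bias: np.ndarray  # (H,)
    output_weights: np.ndarray  # (H,)
    output_bias: float
    skip_bias: float

    @property
    def n_features(self) -> int:
        return self.theta.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.input_weights.shape[0]

    def copy(self) -> "LassoNetRNNParams":
        return LassoNetRNNParams(
            theta=self.theta.copy(),
            input_weights=self.input_weights.copy(),
            recurrent_weights=self.recurrent_weights.copy(),
            hidden_bias=self.hidden_bias.copy(),
            output_weights=self.output_weights.copy(),
            output_bias=float(self.output_bias),
            skip_bias=float(self.skip_bias),
        )

    def feasible(self, m_hier: float, atol: float = 1e-12) -> bool:
        """Check max_k |W_in[k, j]| <= m_hier * |theta_j| for every j."""
        if math.isinf(m_hier):
            return True
        col_max = np.abs(self.input_weights).max(axis=0)
        return bool(np.all(col_max <= m_hier * np.abs(self.theta) + atol))


def init_params(hyper: HyperParams, n_features: int, n_seed_streams: int = 0) -> LassoNetRNNParams:
    """Deterministic scaled-uniform initialization; all features start active.

    theta entries are drawn away from zero so the initial active set is
    the full feature set; input columns are rescaled down if needed so
    the hierarchy constraint already holds at initialization.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    rng = np.random.default_rng((hyper.seed, n_seed_streams))
    h = hyper.hidden_size

    def unif(shape, fan_in):
        bound = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-bound, bound, size=shape)

    theta = rng.uniform(0.05, 0.2, size=n_features) * rng.choice([-1.0, 1.0], size=n_features)
    input_weights = unif((h, n_features), n_features)
    recurrent_weights = unif((h, h), h)
    hidden_bias = np.zeros(h)
    output_weights = unif(h, h)

    if not math.isinf(hyper.m_hier):
        cap = hyper.m_hier * np.abs(theta)
        col_max = np.abs(input_weights).max(axis=0)
        shrink = np.where(col_max > cap, np.where(col_max > 0, cap / np.maximum(col_max, 1e-300), 0.0), 1.0)
        input_weights = input_weights * shrink

    return LassoNetRNNParams(
        theta=theta,
        input_weights=input_weights,
        recurrent_weights=recurrent_weights,
        hidden_bias=hidden_bias,
        output_weights=output_weights,
        output_bias=0.0,
        skip_bias=0.0,
    )


def forward_batch(params: LassoNetRNNParams, x: np.ndarray, return_cache: bool = False):
    """Logits for a batch ``x`` of shape (B, Q, M).

    With ``return_cache`` the per-step hidden states (pre-ReLU sign via
    h > 0) needed for backpropagation are returned too.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim == 2:
        x = x[None]
    if x.ndim != 3 or x.shape[2] != params.n_features:
        raise ValueError(
            f"expected input of shape (B, Q, {params.n_features}), got {x.shape}"
        )
    b, q, _ = x.shape
    h_states = np.zeros((q + 1, b, params.hidden_size))
    for t in range(q):
        pre = (
            x[:, t, :] @ params.input_weights.T
            + h_states[t] @ params.recurrent_weights.T
            + params.hidden_bias
        )
        h_states[t + 1] = np.maximum(pre, 0.0)
    xbar = x.mean(axis=1)
    logits = (
        h_states[q] @ params.output_weights
        + params.output_bias
        + params.skip_bias
        + xbar @ params.theta
    )
    if return_cache:
        return logits, (x, xbar, h_states)
    return logits


def rnn_forward(params: LassoNetRNNParams, x: np.ndarray) -> float:
    """Logit for a single subject's (Q, M) series."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError(f"expected a single (Q, M) series, got shape {x.shape}")
    return float(forward_batch(params, x[None])[0])


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def predict_proba(params: LassoNetRNNParams, x: np.ndarray) -> np.ndarray:
    """P(y = 1) for a batch of series."""
    return _sigmoid(forward_batch(params, x))


def _bce_with_logits(logits: np.ndarray, y: np.ndarray) -> float:
    # numerically stable: max(z,0) - z*y + log(1 + exp(-|z|))
    return float(np.mean(np.maximum(logits, 0) - logits * y + np.log1p(np.exp(-np.abs(logits)))))


def smooth_loss(params: LassoNetRNNParams, x: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy of logistic(logit) against labels.

    This is the smooth part of the objective only; the l1 penalty on
    theta is handled exactly by the proximal step and never enters the
    gradient.
    """
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty batch")
    return _bce_with_logits(forward_batch(params, x), y)


def loss_and_grads(params: LassoNetRNNParams, x: np.ndarray, y: np.ndarray):
    """Backpropagation through time; returns (loss, gradient dict)."""
    y = np.asarray(y, dtype=np.float64)
    if y.size == 0:
        raise ValueError("empty batch")
    logits, (x, xbar, h_states) = forward_batch(params, x, return_cache=True)
    b, q, _ = x.shape
    loss = _bce_with_logits(logits, y)

    dlogit = (_sigmoid(logits) - y) / b  # (B,)
    grads = {
        "theta": xbar.T @ dlogit,
        "skip_bias": float(dlogit.sum()),
        "output_bias": float(dlogit.sum()),
        "output_weights": h_states[q].T @ dlogit,
        "input_weights": np.zeros_like(params.input_weights),
        "recurrent_weights": np.zeros_like(params.recurrent_weights),
        "hidden_bias": np.zeros_like(params.hidden_bias),
    }
    dh = dlogit[:, None] * params.output_weights  # (B, H)
    for t in range(q, 0, -1):
        da = dh * (h_states[t] > 0)
        grads["input_weights"] += da.T @ x[:, t - 1, :]
        grads["recurrent_weights"] += da.T @ h_states[t - 1]
        grads["hidden_bias"] += da.sum(axis=0)
        dh = da @ params.recurrent_weights
    return loss, grads


@dataclass
class AdamState:
    """First/second moment estimates with bias correction."""

    m: dict = field(default_factory=dict)
    v: dict = field(default_factory=dict)
    t: int = 0
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8


def adam_step(
    params: LassoNetRNNParams,
    state: AdamState,
    grads: dict,
    learning_rate: float,
) -> LassoNetRNNParams:
    """One in-place Adam update of every parameter; returns ``params``.

    Feasibility is deliberately not enforced here — the subsequent
    proximal step restores it exactly.
    """
    state.t += 1
    b1, b2 = state.beta1, state.beta2
    bc1 = 1.0 - b1**state.t
    bc2 = 1.0 - b2**state.t
    for name in _PARAM_FIELDS:
        g = grads[name]
        if name not in state.m:
            state.m[name] = np.zeros_like(np.asarray(g, dtype=np.float64))
            state.v[name] = np.zeros_like(np.asarray(g, dtype=np.float64))
        state.m[name] = b1 * state.m[name] + (1 - b1) * np.asarray(g)
        state.v[name] = b2 * state.v[name] + (1 - b2) * np.square(g)
        step = learning_rate * (state.m[name] / bc1) / (np.sqrt(state.v[name] / bc2) + state.eps)
        cur = getattr(params, name)
        if np.isscalar(cur) or np.ndim(cur) == 0:
            setattr(params, name, float(cur - step))
        else:
            cur -= step
    return params


def sgd_step(params: LassoNetRNNParams, grads: dict, learning_rate: float) -> LassoNetRNNParams:
    """Plain gradient step, in place.

    Used during path training: a non-adaptive step keeps the subsequent
    proximal update (threshold lambda * learning_rate) an exact
    proximal-gradient iteration on the penalized objective, which Adam's
    per-coordinate preconditioning would distort.
    """
    for name in _PARAM_FIELDS:
        cur = getattr(params, name)
        if np.isscalar(cur) or np.ndim(cur) == 0:
            setattr(params, name, float(cur - learning_rate * grads[name]))
        else:
            cur -= learning_rate * np.asarray(grads[name])
    return params


# ---------------------------------------------------------------------------
# checkpoint I/O: flat text-based archive + JSON hyperparameter sidecar
# ---------------------------------------------------------------------------


def save_checkpoint(params: LassoNetRNNParams, hyper: HyperParams, path: str | Path) -> None:
    path = Path(path)
    payload = {
        "hyper": {k: (None if v is None else (v if not isinstance(v, float) or math.isfinite(v) else "inf"))
                  for k, v in hyper.__dict__.items()},
        "params": {
            name: np.asarray(getattr(params, name), dtype=np.float64).tolist()
            for name in _PARAM_FIELDS
        },
    }
    path.write_text(json.dumps(payload))


def load_checkpoint(path: str | Path) -> tuple[LassoNetRNNParams, HyperParams]:
    payload = json.loads(Path(path).read_text())
    hp = dict(payload["hyper"])
    if hp.get("m_hier") == "inf":
        hp["m_hier"] = math.inf
    hyper = HyperParams(**hp)
    raw = payload["params"]
    params = LassoNetRNNParams(
        theta=np.asarray(raw["theta"], dtype=np.float64),
        input_weights=np.asarray(raw["input_weights"], dtype=np.float64),
        recurrent_weights=np.asarray(raw["recurrent_weights"], dtype=np.float64),
        hidden_bias=np.asarray(raw["hidden_bias"], dtype=np.float64),
        output_weights=np.asarray(raw["output_weights"], dtype=np.float64),
        output_bias=float(raw["output_bias"]),
        skip_bias=float(raw["skip_bias"]),
    )
    return params, hyper
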