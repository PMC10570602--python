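"""Hierarchical proximal operator and exact-zero screening.

After each gradient step, every variable j's pair (theta_j, input
column u_j) is replaced by the exact global minimizer of

    1/2 (theta - theta_j)^2 + 1/2 ||w - u_j||^2 + lambda_step * |theta|
        subject to ||w||_inf <= m_hier * |theta|

which soft-thresholds the skip coefficient and clips the hidden-layer
column jointly, so a variable's hidden weights are forced to exactly
zero the moment its skip coefficient is screened out.

The solver reduces the problem to a scalar piecewise-quadratic in
t = |theta|: with the column magnitudes sorted descending, each count m
of entries exceeding the clip level yields one stationary candidate

    t_m = max(0, (|theta_j| - lambda_step + M * sum of m largest |u|)
                 / (1 + m * M^2))

and the global optimum is the candidate with the smallest objective.
The candidate scan is exhaustive (m = 0..K), so correctness does not
depend on locating the valid segment analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from lassonet_rnn.model import LassoNetRNNParams

__all__ = ["ProxInput", "hier_prox", "prox_all", "active_set", "soft_threshold"]


def soft_threshold(x: np.ndarray | float, thresh: float):
    """sign(x) * max(|x| - thresh, 0)."""
    return np.sign(x) * np.maximum(np.abs(x) - thresh, 0.0)


@dataclass(frozen=True)
class ProxInput:
    """One variable's post-gradient state entering the proximal step."""

    theta_j: float
    u_j: np.ndarray
    lambda_step: float
    m_hier: float

    def __post_init__(self) -> None:
        u = np.atleast_1d(np.asarray(self.u_j, dtype=np.float64))
        object.__setattr__(self, "u_j", u)
        if not np.all(np.isfinite(u)) or not math.isfinite(self.theta_j):
            raise ValueError("prox inputs must be finite")
        if self.lambda_step < 0:
            raise ValueError("lambda_step must be >= 0")
        if self.m_hier < 0:
            raise ValueError("m_hier must be >= 0 or +inf")


def _hier_prox_columns(
    theta: np.ndarray, u: np.ndarray, lambda_step: float, m_hier: float
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized prox over features: theta (M,), u (K, M)."""
    theta = np.asarray(theta, dtype=np.float64)
    u = np.asarray(u, dtype=np.float64)
    if math.isinf(m_hier):
        return soft_threshold(theta, lambda_step), u.copy()
    if m_hier == 0.0:
        return soft_threshold(theta, lambda_step), np.zeros_like(u)

    k = u.shape[0]
    abs_u_sorted = -np.sort(-np.abs(u), axis=0)  # (K, M) descending
    cumsum = np.vstack([np.zeros_like(theta), np.cumsum(abs_u_sorted, axis=0)])  # (K+1, M)
    m_counts = np.arange(k + 1, dtype=np.float64)[:, None]  # (K+1, 1)

    t_cand = (np.abs(theta) - lambda_step + m_hier * cumsum) / (1.0 + m_counts * m_hier**2)
    t_cand = np.maximum(t_cand, 0.0)  # (K+1, M)

    # objective at each candidate: 1/2 (t-|b|)^2 + lam t + 1/2 sum max(|u|-Mt, 0)^2
    resid = np.maximum(abs_u_sorted[None, :, :] - m_hier * t_cand[:, None, :], 0.0)
    obj = (
        0.5 * (t_cand - np.abs(theta)) ** 2
        + lambda_step * t_cand
        + 0.5 * np.sum(resid**2, axis=1)
    )  # (K+1, M)
    best = np.argmin(obj, axis=0)
    t_opt = t_cand[best, np.arange(theta.shape[0])]

    sign = np.where(theta >= 0, 1.0, -1.0)
    theta_out = np.where(t_opt > 0, sign * t_opt, 0.0)
    u_out = np.sign(u) * np.minimum(np.abs(u), m_hier * t_opt)
    return theta_out, u_out


def hier_prox(p: ProxInput) -> tuple[float, np.ndarray]:
    """Exact solution of the single-variable hierarchical prox problem."""
    theta_out, u_out = _hier_prox_columns(
        np.array([p.theta_j]), p.u_j[:, None], p.lambda_step, p.m_hier
    )
    return float(theta_out[0]), u_out[:, 0]


def prox_all(
    params: LassoNetRNNParams,
    lam: float,
    learning_rate: float,
    m_hier: float,
) -> LassoNetRNNParams:
    """Apply the hierarchical prox to every feature in place.

    ``lambda_step = lam * learning_rate``, the standard scaling of a
    proximal-gradient scheme.  All non-gated parameters are untouched;
    the hierarchy constraint holds exactly afterwards.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if learning_rate <= 0:
        raise ValueError("learning_rate must be positive")
    lambda_step = lam * learning_rate
    if lambda_step == 0 and params.feasible(m_hier):
        return params
    theta_out, u_out = _hier_prox_columns(params.theta, params.input_weights, lambda_step, m_hier)
    params.theta = theta_out
    params.input_weights = u_out
    return params


def active_set(params: LassoNetRNNParams, tolerance: float = 0.0) -> set[int]:
    """Indices of features with |theta_j| > tolerance (exact-zero screening)."""
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return set(np.flatnonzero(np.abs(params.theta) > tolerance).tolist())
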