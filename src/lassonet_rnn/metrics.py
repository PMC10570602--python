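"""Binary classification metrics and contingency-table association.

Accuracy and F1 are computed from explicit confusion counts with class
1 as positive; AUC uses the exact Mann-Whitney rank form (tie-safe,
equal to the trapezoidal ROC area); the chi-square statistic is the
uncorrected Pearson test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "ContingencyTable",
    "confusion",
    "accuracy",
    "f1",
    "auc",
    "pearson_chi2",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ContingencyTable:
    """R x C table of non-negative counts with positive marginals."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.float64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("contingency table must be at least 2x2")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise ValueError("counts must be finite and non-negative")
        if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
            raise ValueError("every row and column sum must be positive")


def _check_binary(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v)
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1")
    return v.astype(np.int64)


def confusion(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    """Confusion counts with class 1 as positive."""
    y_true = _check_binary(y_true, "y_true")
    y_pred = _check_binary(y_pred, "y_pred")
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length, non-empty")
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


def accuracy(cc: ConfusionCounts) -> float:
    """(TP + TN) / (TP + FP + FN + TN)."""
    if cc.total == 0:
        raise ValueError("cannot compute accuracy of an empty confusion table")
    return (cc.tp + cc.tn) / cc.total


def f1(cc: ConfusionCounts) -> float:
    """2*TP / (2*TP + FN + FP); defined as 0 when no positives exist anywhere."""
    denom = 2 * cc.tp + cc.fn + cc.fp
    if denom == 0:
        warnings.warn("no positive labels or predictions; F1 defined as 0")
        return 0.0
    return 2 * cc.tp / denom


def auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 1/2 P(tie)."""
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int(y_true.sum())
    n_neg = y_true.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes present")
    ranks = rankdata(scores)  # midranks handle ties
    rank_sum_pos = ranks[y_true == 1].sum()
    return (rank_sum_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def pearson_chi2(t: ContingencyTable | np.ndarray) -> tuple[float, int, float]:
    """Uncorrected Pearson chi-square test of independence.

    Returns (statistic, degrees of freedom, upper-tail p-value).  No
    Yates continuity correction is applied, for 2x2 tables included.
    """
    if not isinstance(t, ContingencyTable):
        t = ContingencyTable(np.asarray(t))
    res = stats.chi2_contingency(t.counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def evaluate_predictions(y_true: np.ndarray, scores: np.ndarray, threshold: float = 0.5) -> dict:
    """Bundle accuracy / F1 / AUC for probability scores.

    AUC is reported as NaN when only one class is present (degenerate
    splits during tiny toy runs).
    """
    y_true = _check_binary(y_true, "y_true")
    scores = np.asarray(scores, dtype=np.float64)
    cc = confusion(y_true, (scores >= threshold).astype(np.int64))
    try:
        auc_val = auc(y_true, scores)
    except ValueError:
        auc_val = float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f1_val = f1(cc)
    return {"accuracy": accuracy(cc), "f1": f1_val, "auc": auc_val}
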