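"""Dense-to-sparse regularization path and per-variable importance.

The model is first pretrained densely (lambda = 0, no proximal step),
then trained along a geometrically increasing lambda sequence with warm
starts, applying the hierarchical prox after every Adam step, until all
skip coefficients are zero.  A variable's importance is the largest
lambda at which it was still active — the lambda recorded when it is
screened out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from lassonet_rnn.data import TimeSeriesDataset
from lassonet_rnn.metrics import evaluate_predictions
from lassonet_rnn.model import (
    AdamState,
    HyperParams,
    LassoNetRNNParams,
    adam_step,
    init_params,
    loss_and_grads,
    predict_proba,
    sgd_step,
)
from lassonet_rnn.prox import active_set, prox_all

__all__ = [
    "PathPoint",
    "ImportanceRanking",
    "fit_path",
    "feature_importance",
    "select_k_features",
    "path_to_frame",
    "importance_to_frame",
]

#: hard guard against a non-terminating path
_MAX_LAMBDA_GROWTH = 1e6


@dataclass(frozen=True)
class PathPoint:
    """State recorded after training at one lambda."""

    lam: float
    active_features: frozenset[int]
    theta_snapshot: np.ndarray
    train_metrics: dict
    test_metrics: dict
    epochs_run: int


@dataclass(frozen=True)
class ImportanceRanking:
    """Per-feature exit lambdas with descending competition ranks.

    ``exit_lambda[j]`` is the largest lambda at which feature j was
    active (0 if never active); ``order`` sorts features by importance
    descending; tied features share a rank.
    """

    exit_lambda: np.ndarray
    order: np.ndarray
    ranks: np.ndarray
    feature_names: tuple[str, ...] | None = None


def _training_arrays(ds: TimeSeriesDataset) -> tuple[np.ndarray, np.ndarray]:
    if ds.labels is None:
        raise ValueError("dataset must be labeled")
    if not ds.mask.all():
        raise ValueError("dataset must be fully imputed before fitting")
    return ds.values, ds.labels.astype(np.float64)


def _run_epochs(
    params: LassoNetRNNParams,
    x: np.ndarray,
    y: np.ndarray,
    hyper: HyperParams,
    rng: np.random.Generator,
    max_epochs: int,
    lam: float | None,
) -> int:
    """Minibatch training; one proximal step per gradient step when penalized.

    The dense phase (``lam is None``) uses Adam.  Path training uses a
    plain gradient step so that step size and prox threshold agree and
    each iteration is an exact proximal-gradient update of the penalized
    objective — an adaptive per-coordinate optimizer would decouple the
    two and distort the lambda scale.

    Early-stops when the epoch-mean training loss has not improved for
    ``hyper.patience`` consecutive epochs.  Returns epochs run.
    """
    n = x.shape[0]
    state = AdamState()
    lr = hyper.learning_rate if lam is None else hyper.effective_path_lr
    best = np.inf
    stale = 0
    epochs = 0
    for _ in range(max_epochs):
        epochs += 1
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, hyper.batch_size):
            idx = order[start : start + hyper.batch_size]
            loss, grads = loss_and_grads(params, x[idx], y[idx])
            if lam is None:
                adam_step(params, state, grads, lr)
            else:
                sgd_step(params, grads, lr)
                prox_all(params, lam, lr, hyper.m_hier)
            epoch_loss += loss * idx.size
        epoch_loss /= n
        if epoch_loss < best - 1e-6:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale > hyper.patience:
                break
    return epochs


def _auto_lambda_start(
    params: LassoNetRNNParams,
    x: np.ndarray,
    y: np.ndarray,
    hyper: HyperParams,
    seed: int,
) -> float:
    """Calibrate the path's starting lambda on the dense-pretrained model.

    Doubles a candidate lambda, each time training a throwaway copy for
    a short trial (enough proximal steps for screening to express
    itself), until more than one feature is screened out; the largest
    candidate that screened at most one feature, divided by 10, becomes
    lambda_start.  The division buys a gradual dense-to-sparse opening
    of the path instead of a mass exit at the first point.
    """
    m = params.n_features
    steps_per_epoch = max(1, -(-x.shape[0] // hyper.batch_size))
    trial_epochs = min(hyper.epochs_per_lambda, max(1, -(-30 // steps_per_epoch)))
    lam = 1e-4
    best = lam
    for _ in range(60):
        trial = params.copy()
        rng = np.random.default_rng((seed, 7))
        _run_epochs(trial, x, y, hyper, rng, max_epochs=trial_epochs, lam=lam)
        n_screened = m - len(active_set(trial))
        if n_screened > 1:
            break
        best = lam
        lam *= 2.0
    return best / 10.0


def fit_path(
    train: TimeSeriesDataset,
    test: TimeSeriesDataset | None,
    hyper: HyperParams,
    return_params: bool = False,
):
    """Train the full dense-to-sparse path; returns one PathPoint per lambda.

    The sequence is ``lambda_start * path_multiplier**k`` and stops at
    the first lambda whose trained model has an empty active set.
    """
    x, y = _training_arrays(train)
    x_test = y_test = None
    if test is not None:
        x_test, y_test = _training_arrays(test)

    params = init_params(hyper, train.n_features)
    rng = np.random.default_rng((hyper.seed, 1))
    _run_epochs(params, x, y, hyper, rng, max_epochs=hyper.dense_epochs, lam=None)

    lam0 = hyper.lambda_start
    if lam0 is None:
        lam0 = _auto_lambda_start(params, x, y, hyper, hyper.seed)

    path: list[PathPoint] = []
    lam = lam0
    while True:
        if lam > lam0 * _MAX_LAMBDA_GROWTH:
            raise RuntimeError(
                f"path failed to terminate: lambda reached {lam:.3g} "
                f"(> {_MAX_LAMBDA_GROWTH:g} * lambda_start) with features still active"
            )
        epochs = _run_epochs(params, x, y, hyper, rng, max_epochs=hyper.epochs_per_lambda, lam=lam)
        active = frozenset(active_set(params))
        train_scores = predict_proba(params, x)
        point = PathPoint(
            lam=float(lam),
            active_features=active,
            theta_snapshot=params.theta.copy(),
            train_metrics=evaluate_predictions(y.astype(int), train_scores),
            test_metrics=(
                evaluate_predictions(y_test.astype(int), predict_proba(params, x_test))
                if x_test is not None
                else {}
            ),
            epochs_run=epochs,
        )
        path.append(point)
        if not active:
            return (path, params) if return_params else path
        lam *= hyper.path_multiplier


def feature_importance(path: list[PathPoint]) -> ImportanceRanking:
    """Exit-lambda importance from a terminated path.

    ``exit_lambda[j]`` is the maximum lambda at which j was active; a
    feature that re-enters after screening takes the larger value.
    Features never active score 0.  Ranks are competition-style:
    1 + number of strictly more important features, so ties share a rank.
    """
    if not path:
        raise ValueError("empty path")
    if path[-1].active_features:
        raise ValueError("path is not terminated: last point still has active features")
    m = path[0].theta_snapshot.shape[0]
    exit_lambda = np.zeros(m)
    for point in path:
        for j in point.active_features:
            exit_lambda[j] = max(exit_lambda[j], point.lam)
    order = np.lexsort((np.arange(m), -exit_lambda))
    ranks = np.array([1 + int(np.sum(exit_lambda > exit_lambda[j])) for j in range(m)])
    return ImportanceRanking(exit_lambda=exit_lambda, order=order, ranks=ranks)


def select_k_features(ranking: ImportanceRanking, k: int) -> set[int]:
    """The k most important features; a tie at the boundary expands the set."""
    m = ranking.exit_lambda.shape[0]
    if not 1 <= k <= m:
        raise ValueError(f"k must be in [1, {m}], got {k}")
    kth_value = ranking.exit_lambda[ranking.order[k - 1]]
    return set(np.flatnonzero(ranking.exit_lambda >= kth_value).tolist())


def path_to_frame(path: list[PathPoint], feature_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """One row per path point, suitable for CSV export."""
    rows = []
    for p in path:
        names = (
            ";".join(feature_names[j] for j in sorted(p.active_features))
            if feature_names
            else ";".join(str(j) for j in sorted(p.active_features))
        )
        row = {
            "lambda": p.lam,
            "n_active": len(p.active_features),
            "active_features": names,
            "epochs_run": p.epochs_run,
        }
        row.update({f"train_{k}": v for k, v in p.train_metrics.items()})
        row.update({f"test_{k}": v for k, v in p.test_metrics.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def importance_to_frame(
    ranking: ImportanceRanking, feature_names: tuple[str, ...] | None = None
) -> pd.DataFrame:
    """Machine-readable importance table: feature, exit_lambda, rank."""
    m = ranking.exit_lambda.shape[0]
    names = feature_names if feature_names is not None else tuple(str(j) for j in range(m))
    return pd.DataFrame(
        {
            "feature": [names[j] for j in ranking.order],
            "exit_lambda": ranking.exit_lambda[ranking.order],
            "rank": ranking.ranks[ranking.order],
        }
    )
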