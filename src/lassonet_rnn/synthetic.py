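"""Synthetic survey-panel generator with planted relevant features.

Emulates a short panel (default 3 waves) of mixed binary / ordinal /
continuous variables.  The binary outcome is driven partly by *static*
effects (on a variable's time-mean) and partly by purely *temporal*
effects (on the first-to-last wave change), the latter being invisible
to any model that only sees time-averaged features — which is exactly
what the recurrent route is supposed to pick up and the linear
(m_hier = 0) reduction is supposed to miss.

All variables evolve as stationary AR(1) latents across waves, so for a
temporal-effect variable the wave change is uncorrelated with the
time-mean by symmetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from lassonet_rnn.data import TimeSeriesDataset
from lassonet_rnn.metrics import auc
from lassonet_rnn.path import ImportanceRanking

__all__ = ["SyntheticSpec", "generate", "recovery_score", "temporal_feature_recovered",
           "calibrate_intercept", "recovery_benchmark_hyper", "run_recovery_pipeline"]

#: wave-to-wave latent autocorrelation
_AR1_RHO = 0.7


def _default_kinds(m: int) -> tuple[str, ...]:
    # repeating continuous / binary / ordinal mix, survey-like
    cycle = ("continuous", "binary", "ordinal:5")
    return tuple(cycle[j % 3] for j in range(m))


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; effect dicts map feature index -> effect size."""

    n_subjects: int = 600
    n_waves: int = 3
    n_features: int = 27
    static_relevant: dict = field(default_factory=dict)
    temporal_relevant: dict = field(default_factory=dict)
    noise_sd: float = 0.5
    missing_rate: float = 0.0
    intercept: float = 0.0
    feature_kinds: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_waves < 1 or self.n_features < 1:
            raise ValueError("n_subjects, n_waves, n_features must be >= 1")
        kinds = self.feature_kinds or _default_kinds(self.n_features)
        object.__setattr__(self, "feature_kinds", tuple(kinds))
        if len(self.feature_kinds) != self.n_features:
            raise ValueError("feature_kinds length must equal n_features")
        static = {int(j): float(b) for j, b in self.static_relevant.items()}
        temporal = {int(j): float(b) for j, b in self.temporal_relevant.items()}
        object.__setattr__(self, "static_relevant", static)
        object.__setattr__(self, "temporal_relevant", temporal)
        idx = list(static) + list(temporal)
        if any(not 0 <= j < self.n_features for j in idx):
            raise ValueError("relevant feature indices out of range")
        if set(static) & set(temporal):
            raise ValueError("static and temporal relevant sets must be disjoint")
        if not all(np.isfinite(list(static.values()) + list(temporal.values()) or [0.0])):
            raise ValueError("effect sizes must be finite")
        if temporal and self.n_waves < 2:
            raise ValueError("temporal effects require at least 2 waves")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def truth(self) -> set[int]:
        return set(self.static_relevant) | set(self.temporal_relevant)

    @classmethod
    def recovery_default(cls, seed: int = 0, **overrides) -> "SyntheticSpec":
        """The standard planted-recovery benchmark: 3 relevant among 20.

        Two static effects and one purely temporal effect, all of size
        1.0, on continuous variables; 10% missingness.  The intercept is
        left at 0 (balanced classes) unless overridden.
        """
        kwargs = dict(
            n_subjects=600,
            n_waves=3,
            n_features=20,
            static_relevant={0: 1.0, 3: 1.0},
            temporal_relevant={6: 1.0},
            noise_sd=0.5,
            missing_rate=0.1,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _latent_ar1(rng: np.random.Generator, n: int, q: int) -> np.ndarray:
    """Stationary AR(1) latent path per subject, marginally N(0, 1)."""
    x = np.empty((n, q))
    x[:, 0] = rng.standard_normal(n)
    innov_sd = np.sqrt(1.0 - _AR1_RHO**2)
    for t in range(1, q):
        x[:, t] = _AR1_RHO * x[:, t - 1] + innov_sd * rng.standard_normal(n)
    return x


def _materialize(kind: str, latent: np.ndarray) -> np.ndarray:
    if kind == "continuous":
        return latent
    if kind == "binary":
        return (latent > 0).astype(np.float64)
    if kind.startswith("ordinal:"):
        levels = int(kind.split(":", 1)[1])
        if levels < 2:
            raise ValueError(f"ordinal kind needs >= 2 levels, got {kind!r}")
        from scipy.stats import norm

        cuts = norm.ppf(np.linspace(0, 1, levels + 1)[1:-1])
        return np.digitize(latent, cuts).astype(np.float64)
    raise ValueError(f"unknown feature kind {kind!r}")


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sd = x.std()
    return (x - mu) / (sd if sd > 0 else 1.0)


def generate(spec: SyntheticSpec) -> tuple[TimeSeriesDataset, set[int]]:
    """Draw a dataset and return it with the planted relevant-feature set.

    The linear predictor combines static effects on per-subject
    time-means with temporal effects on the last-minus-first wave
    change, both computed on per-feature standardized values so effect
    sizes are comparable across variable kinds; Gaussian noise is added
    and labels drawn Bernoulli(logistic(eta)).  Missing cells are then
    masked completely at random.
    """
    rng = np.random.default_rng(spec.seed)
    n, q, m = spec.n_subjects, spec.n_waves, spec.n_features

    values = np.empty((n, q, m))
    for j, kind in enumerate(spec.feature_kinds):
        values[:, :, j] = _materialize(kind, _latent_ar1(rng, n, q))

    eta = np.full(n, spec.intercept)
    for j, beta in spec.static_relevant.items():
        eta += beta * _standardize(values[:, :, j]).mean(axis=1)
    for j, gamma in spec.temporal_relevant.items():
        std_j = _standardize(values[:, :, j])
        eta += gamma * (std_j[:, -1] - std_j[:, 0])
    if spec.noise_sd > 0:
        eta += spec.noise_sd * rng.standard_normal(n)
    labels = (rng.random(n) < expit(eta)).astype(np.int64)

    mask = np.ones((n, q, m), dtype=bool)
    if spec.missing_rate > 0:
        mask = rng.random((n, q, m)) >= spec.missing_rate

    ds = TimeSeriesDataset(
        values=values,
        mask=mask,
        feature_names=tuple(f"var_{j:02d}" for j in range(m)),
        time_labels=tuple(range(q)),
        labels=labels,
        subject_ids=tuple(range(n)),
    )
    return ds, spec.truth


def calibrate_intercept(spec: SyntheticSpec, target_prevalence: float,
                        n_probe: int = 20000) -> float:
    """Intercept shift that hits a target positive-class prevalence.

    Simulates the linear predictor at scale ``n_probe`` (intercept 0)
    and bisects for the constant making mean logistic(eta + c) equal the
    target.  Deterministic in the spec's seed.
    """
    if not 0.0 < target_prevalence < 1.0:
        raise ValueError("target_prevalence must be in (0, 1)")
    probe = SyntheticSpec(**{**spec.__dict__, "n_subjects": n_probe, "intercept": 0.0,
                             "missing_rate": 0.0})
    rng = np.random.default_rng(probe.seed)
    values = np.empty((n_probe, probe.n_waves, probe.n_features))
    for j, kind in enumerate(probe.feature_kinds):
        values[:, :, j] = _materialize(kind, _latent_ar1(rng, n_probe, probe.n_waves))
    eta = np.zeros(n_probe)
    for j, beta in probe.static_relevant.items():
        eta += beta * _standardize(values[:, :, j]).mean(axis=1)
    for j, gamma in probe.temporal_relevant.items():
        std_j = _standardize(values[:, :, j])
        eta += gamma * (std_j[:, -1] - std_j[:, 0])
    if probe.noise_sd > 0:
        eta += probe.noise_sd * rng.standard_normal(n_probe)

    lo, hi = -20.0, 20.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if expit(eta + mid).mean() < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def recovery_score(ranking: ImportanceRanking, truth: set[int]) -> float:
    """AUC of exit_lambda as a classifier of planted-feature membership.

    1.0 means every planted feature outranks every noise feature; a
    random ordering scores 0.5 in expectation.  Ties contribute half.
    """
    m = ranking.exit_lambda.shape[0]
    truth = set(int(j) for j in truth)
    if not truth:
        raise ValueError("truth set must be non-empty")
    if not truth <= set(range(m)):
        raise ValueError("truth contains out-of-range feature indices")
    if len(truth) == m:
        raise ValueError("truth covers all features; recovery is undefined")
    membership = np.array([1 if j in truth else 0 for j in range(m)])
    return auc(membership, ranking.exit_lambda)


def recovery_benchmark_hyper(seed: int, m_hier: float = 10.0) -> "HyperParams":
    """Training configuration used by the planted-recovery benchmark.

    Full-batch proximal gradient along the path keeps screening
    decisions close to the exact penalized optimum, which is what makes
    exit-lambda rankings reproducible at this problem size.
    """
    from lassonet_rnn.model import HyperParams

    return HyperParams(
        seed=seed,
        hidden_size=16,
        m_hier=m_hier,
        path_multiplier=1.1,
        epochs_per_lambda=100,
        dense_epochs=100,
        learning_rate=0.01,
        path_learning_rate=0.1,
        batch_size=512,
        patience=10,
    )


def run_recovery_pipeline(seed: int, m_hier: float = 10.0):
    """Full pipeline on the default planted spec: generate -> split ->
    impute -> normalize -> fit path -> importance.

    Returns (ranking, truth, spec).
    """
    from lassonet_rnn.data import (
        apply_normalizer,
        fit_normalizer,
        impute_missing,
        train_test_split,
    )
    from lassonet_rnn.path import feature_importance, fit_path

    spec = SyntheticSpec.recovery_default(seed=seed)
    ds, truth = generate(spec)
    train, test = train_test_split(ds, 0.8, seed)
    train = impute_missing(train)
    test = impute_missing(test)
    stats = fit_normalizer(train)
    train = apply_normalizer(train, stats)
    test = apply_normalizer(test, stats)
    path = fit_path(train, test, recovery_benchmark_hyper(seed, m_hier))
    return feature_importance(path), truth, spec


def temporal_feature_recovered(ranking: ImportanceRanking, temporal_idx: int,
                               truth: set[int]) -> bool:
    """Did the temporal feature's exit lambda beat the median noise feature?"""
    noise = sorted(set(range(ranking.exit_lambda.shape[0])) - set(truth))
    if not noise:
        raise ValueError("no noise features to compare against")
    return bool(ranking.exit_lambda[temporal_idx] > np.median(ranking.exit_lambda[noise]))
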