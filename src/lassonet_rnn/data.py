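"""Dataset container, file I/O and the clean/impute/normalize/split pipeline.

The central object is :class:`TimeSeriesDataset`, a dense ``(N, Q, M)``
value tensor (subjects x time steps x variables) with a boolean
observed-mask of the same shape.  Readers exist for long CSV (one row
per subject-wave), wide CSV (one row per subject) and the sktime/UEA
multivariate ``.ts`` dialect.  Preprocessing follows the conventional
panel order: drop overly sparse subjects, impute, normalize on the
training split only, stratified subject-level split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TimeSeriesDataset",
    "NormalizationStats",
    "read_long_csv",
    "read_wide_csv",
    "read_ts_file",
    "write_ts_file",
    "write_long_csv",
    "drop_sparse_subjects",
    "impute_missing",
    "fit_normalizer",
    "apply_normalizer",
    "invert_normalizer",
    "train_test_split",
]


@dataclass(frozen=True)
class TimeSeriesDataset:
    """Multivariate panel: ``values[i, t, j]`` is subject i, time t, variable j.

    ``mask`` marks observed cells; masked-out entries are ignored by every
    downstream computation (their stored value is arbitrary).
    """

    values: np.ndarray
    mask: np.ndarray
    feature_names: tuple[str, ...]
    time_labels: tuple
    labels: np.ndarray | None = None
    subject_ids: tuple | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        object.__setattr__(self, "time_labels", tuple(self.time_labels))
        if values.ndim != 3:
            raise ValueError(f"values must be 3-D (N, Q, M), got shape {values.shape}")
        if values.shape != mask.shape:
            raise ValueError(f"values shape {values.shape} != mask shape {mask.shape}")
        n, q, m = values.shape
        if min(n, q, m) < 1:
            raise ValueError(f"all of N, Q, M must be >= 1, got {(n, q, m)}")
        if len(self.feature_names) != m:
            raise ValueError("feature_names length must equal M")
        if len(set(self.feature_names)) != m:
            raise ValueError("feature_names must be unique")
        if len(self.time_labels) != q:
            raise ValueError("time_labels length must equal Q")
        if not np.all(np.isfinite(values[mask])):
            raise ValueError("observed (mask=true) values must be finite")
        if self.labels is not None:
            labels = np.asarray(self.labels, dtype=np.int64)
            object.__setattr__(self, "labels", labels)
            if labels.shape != (n,):
                raise ValueError("labels must be a length-N vector")
        if self.subject_ids is not None:
            ids = tuple(self.subject_ids)
            object.__setattr__(self, "subject_ids", ids)
            if len(ids) != n:
                raise ValueError("subject_ids must have length N")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_waves(self) -> int:
        return self.values.shape[1]

    @property
    def n_features(self) -> int:
        return self.values.shape[2]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def subset(self, idx: np.ndarray) -> "TimeSeriesDataset":
        """Subject-level subset (boolean or integer index)."""
        idx = np.asarray(idx)
        return replace(
            self,
            values=self.values[idx],
            mask=self.mask[idx],
            labels=None if self.labels is None else self.labels[idx],
            subject_ids=None
            if self.subject_ids is None
            else tuple(np.asarray(self.subject_ids, dtype=object)[idx]),
        )

    def time_means(self) -> np.ndarray:
        """Per-subject, per-feature mean over observed waves, shape (N, M).

        Cells with no observed wave at all come out as NaN.
        """
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            vals = np.where(self.mask, self.values, np.nan)
            return np.nanmean(vals, axis=1)


@dataclass(frozen=True)
class NormalizationStats:
    """Per-feature affine transform ``(x - location) / scale``."""

    location: np.ndarray
    scale: np.ndarray
    method: str = "zscore"

    def __post_init__(self) -> None:
        loc = np.asarray(self.location, dtype=np.float64)
        scale = np.asarray(self.scale, dtype=np.float64)
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "scale", scale)
        if loc.ndim != 1 or scale.shape != loc.shape:
            raise ValueError("location and scale must be 1-D vectors of equal length")
        if not np.all(scale > 0):
            raise ValueError("scale must be strictly positive for every feature")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _coerce_binary_labels(raw: np.ndarray) -> np.ndarray:
    """Map a two-class label column to {0, 1}; general k-class to 0..k-1."""
    classes = sorted(set(raw.tolist()), key=str)
    mapping = {c: i for i, c in enumerate(classes)}
    if set(classes) <= {0, 1, 0.0, 1.0, "0", "1"}:
        mapping = {c: int(float(c)) for c in classes}
    return np.array([mapping[v] for v in raw], dtype=np.int64)


def read_long_csv(
    path: str | Path,
    id_column: str,
    time_column: str,
    feature_columns: Sequence[str],
    label_column: str | None = None,
) -> TimeSeriesDataset:
    """Read a long-format panel CSV: one row per (subject, wave).

    Subjects are ordered by first appearance, waves ascending by time
    value.  A missing (id, time) row becomes a fully mask-false wave;
    individually empty cells in present rows are also masked out.  The
    label must be constant across the waves where it is present.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in [id_column, time_column, *feature_columns]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if label_column is not None and label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")

    dup = df.duplicated(subset=[id_column, time_column], keep=False)
    if dup.any():
        pair = df.loc[dup, [id_column, time_column]].iloc[0].tolist()
        raise ValueError(f"duplicate (id, time) pair: ({pair[0]!r}, {pair[1]!r})")

    subject_ids = list(dict.fromkeys(df[id_column].tolist()))
    time_labels = sorted(set(df[time_column].tolist()))
    n, q, m = len(subject_ids), len(time_labels), len(feature_columns)
    sub_index = {s: i for i, s in enumerate(subject_ids)}
    t_index = {t: k for k, t in enumerate(time_labels)}

    values = np.zeros((n, q, m))
    mask = np.zeros((n, q, m), dtype=bool)
    feat_block = df[list(feature_columns)].to_numpy(dtype=np.float64)
    rows_i = df[id_column].map(sub_index).to_numpy()
    rows_t = df[time_column].map(t_index).to_numpy()
    values[rows_i, rows_t] = np.nan_to_num(feat_block)
    mask[rows_i, rows_t] = np.isfinite(feat_block)

    labels = None
    if label_column is not None:
        labels = np.empty(n, dtype=np.int64)
        for s, g in df.groupby(id_column, sort=False):
            lab = g[label_column].dropna()
            if lab.empty:
                raise ValueError(f"subject {s!r} has no label in any wave")
            uniq = set(lab.tolist())
            if len(uniq) > 1:
                raise ValueError(f"conflicting labels for subject {s!r}: {sorted(uniq)}")
            labels[sub_index[s]] = int(lab.iloc[-1])

    return TimeSeriesDataset(
        values=values,
        mask=mask,
        feature_names=tuple(feature_columns),
        time_labels=tuple(time_labels),
        labels=labels,
        subject_ids=tuple(subject_ids),
    )


def write_long_csv(ds: TimeSeriesDataset, path: str | Path, id_column: str = "id",
                   time_column: str = "time", label_column: str = "label") -> None:
    """Write a dataset in long format; masked cells become empty fields."""
    rows = []
    ids = ds.subject_ids if ds.subject_ids is not None else tuple(range(ds.n_subjects))
    for i in range(ds.n_subjects):
        for t in range(ds.n_waves):
            row: dict = {id_column: ids[i], time_column: ds.time_labels[t]}
            for j, name in enumerate(ds.feature_names):
                row[name] = ds.values[i, t, j] if ds.mask[i, t, j] else np.nan
            if ds.labels is not None:
                row[label_column] = int(ds.labels[i])
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_wide_csv(
    path: str | Path,
    id_column: str = "id",
    label_column: str | None = "label",
    sep: str = "__",
) -> TimeSeriesDataset:
    """Read a wide panel CSV with columns ``<feature>__<time_label>``."""
    df = pd.read_csv(path)
    if id_column not in df.columns:
        raise ValueError(f"column {id_column!r} not found in {path}")
    pairs = []
    for col in df.columns:
        if col in (id_column, label_column) or sep not in col:
            continue
        feat, tlab = col.rsplit(sep, 1)
        pairs.append((feat, tlab, col))
    if not pairs:
        raise ValueError(f"no '<feature>{sep}<time>' columns found in {path}")
    feature_names = list(dict.fromkeys(p[0] for p in pairs))
    time_labels = sorted(set(p[1] for p in pairs))
    n, q, m = len(df), len(time_labels), len(feature_names)
    values = np.zeros((n, q, m))
    mask = np.zeros((n, q, m), dtype=bool)
    for feat, tlab, col in pairs:
        j = feature_names.index(feat)
        t = time_labels.index(tlab)
        col_vals = df[col].to_numpy(dtype=np.float64)
        obs = np.isfinite(col_vals)
        values[:, t, j] = np.nan_to_num(col_vals)
        mask[:, t, j] = obs
    labels = None
    if label_column is not None and label_column in df.columns:
        labels = _coerce_binary_labels(df[label_column].to_numpy())
    return TimeSeriesDataset(
        values=values,
        mask=mask,
        feature_names=tuple(feature_names),
        time_labels=tuple(time_labels),
        labels=labels,
        subject_ids=tuple(df[id_column].tolist()),
    )


_KNOWN_TS_TAGS = {
    "problemname",
    "timestamps",
    "missing",
    "univariate",
    "dimension",
    "equallength",
    "serieslength",
    "classlabel",
    "targetlabel",
    "data",
}


def read_ts_file(path: str | Path) -> TimeSeriesDataset:
    """Read a multivariate sktime/UEA-style ``.ts`` file.

    One line per case after ``@data``; dimensions separated by ``:`` with
    the class label last.  Only equal-length series are supported.
    Two-class problems get labels in {0, 1}; multi-class gets codes
    0..k-1 in the header (or sorted) order.
    """
    path = Path(path)
    header: dict[str, str] = {}
    cases: list[list[list[float]]] = []
    raw_labels: list[str] = []
    in_data = False
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("@"):
                tag, _, rest = line[1:].partition(" ")
                tag = tag.lower()
                if tag not in _KNOWN_TS_TAGS:
                    warnings.warn(f"{path}:{lineno}: unknown header tag @{tag}, skipping")
                    continue
                if tag == "data":
                    in_data = True
                else:
                    header[tag] = rest.strip()
                continue
            if not in_data:
                raise ValueError(f"{path}:{lineno}: data line before @data tag")
            parts = line.split(":")
            raw_labels.append(parts[-1].strip())
            dims = [
                [float(v) for v in dim.split(",") if v.strip() != ""]
                for dim in parts[:-1]
            ]
            cases.append(dims)
    if not cases:
        raise ValueError(f"{path}: no data lines found")

    lengths = {len(s) for case in cases for s in case}
    n_dims = {len(case) for case in cases}
    if len(lengths) != 1 or len(n_dims) != 1:
        raise ValueError(f"{path}: ragged series (lengths {sorted(lengths)}) are unsupported")
    q = lengths.pop()
    m = n_dims.pop()
    values = np.array([[[case[j][t] for j in range(m)] for t in range(q)] for case in cases])

    class_spec = header.get("classlabel", "").split()
    if class_spec and class_spec[0].lower() == "true":
        classes = class_spec[1:]
    else:
        classes = sorted(set(raw_labels))
    mapping = {c: i for i, c in enumerate(classes)}
    if set(classes) <= {"0", "1"}:
        mapping = {c: int(c) for c in classes}
    labels = np.array([mapping[lab] for lab in raw_labels], dtype=np.int64)

    return TimeSeriesDataset(
        values=values,
        mask=np.ones_like(values, dtype=bool),
        feature_names=tuple(f"dim_{j}" for j in range(m)),
        time_labels=tuple(range(q)),
        labels=labels,
    )


def write_ts_file(ds: TimeSeriesDataset, path: str | Path, problem_name: str = "dataset") -> None:
    """Write an equal-length multivariate ``.ts`` file (labels required)."""
    if ds.labels is None:
        raise ValueError("write_ts_file requires labels")
    if not ds.mask.all():
        raise ValueError("write_ts_file requires a fully observed dataset (impute first)")
    classes = sorted(set(int(v) for v in ds.labels))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"@problemName {problem_name}\n")
        fh.write("@timeStamps false\n")
        fh.write("@missing false\n")
        fh.write(f"@univariate {'true' if ds.n_features == 1 else 'false'}\n")
        fh.write("@equalLength true\n")
        fh.write(f"@seriesLength {ds.n_waves}\n")
        fh.write(f"@classLabel true {' '.join(str(c) for c in classes)}\n")
        fh.write("@data\n")
        for i in range(ds.n_subjects):
            dims = [
                ",".join(repr(float(ds.values[i, t, j])) for t in range(ds.n_waves))
                for j in range(ds.n_features)
            ]
            fh.write(":".join(dims) + f":{int(ds.labels[i])}\n")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------


def drop_sparse_subjects(ds: TimeSeriesDataset, max_missing_fraction: float = 1.0) -> TimeSeriesDataset:
    """Remove subjects whose missing-cell fraction exceeds the threshold.

    The default threshold 1.0 keeps everyone (drops only fully empty
    subjects when the fraction is exactly exceeded, i.e. never).
    """
    if not 0.0 <= max_missing_fraction <= 1.0:
        raise ValueError("max_missing_fraction must be in [0, 1]")
    frac_missing = 1.0 - ds.mask.reshape(ds.n_subjects, -1).mean(axis=1)
    keep = frac_missing <= max_missing_fraction
    if keep.all():
        return ds
    if not keep.any():
        raise ValueError("all subjects would be dropped")
    return ds.subset(keep)


def impute_missing(
    ds: TimeSeriesDataset,
    strategy: Literal["feature_mean", "carry_forward", "constant"] = "feature_mean",
    fill_value: float = 0.0,
) -> TimeSeriesDataset:
    """Fill masked-out cells; the result has an all-true mask.

    ``feature_mean`` uses the mean over all observed cells of the feature
    (pooling subjects and waves).  ``carry_forward`` propagates the
    subject's most recent observed wave forward, falling back to the
    feature mean when nothing earlier is observed.  ``constant`` fills a
    supplied value.
    """
    if ds.mask.all():
        return ds
    values = ds.values.copy()
    mask = ds.mask

    if strategy in ("feature_mean", "carry_forward"):
        observed_per_feature = mask.reshape(-1, ds.n_features)
        if not observed_per_feature.any(axis=0).all():
            j = int(np.flatnonzero(~observed_per_feature.any(axis=0))[0])
            raise ValueError(
                f"feature {ds.feature_names[j]!r} has no observed values; cannot impute"
            )
        flat = values.reshape(-1, ds.n_features)
        sums = np.where(observed_per_feature, flat, 0.0).sum(axis=0)
        counts = observed_per_feature.sum(axis=0)
        feature_means = sums / counts

    if strategy == "feature_mean":
        values[~mask] = np.broadcast_to(feature_means, ds.shape)[~mask]
    elif strategy == "carry_forward":
        filled = np.where(mask, values, np.nan)
        for t in range(1, ds.n_waves):
            gap = np.isnan(filled[:, t, :])
            filled[:, t, :][gap] = filled[:, t - 1, :][gap]
        still = np.isnan(filled)
        filled[still] = np.broadcast_to(feature_means, ds.shape)[still]
        values = filled
    elif strategy == "constant":
        values[~mask] = float(fill_value)
    else:
        raise ValueError(f"unknown imputation strategy {strategy!r}")

    return replace(ds, values=values, mask=np.ones_like(mask))


def fit_normalizer(ds: TimeSeriesDataset, method: Literal["zscore", "minmax"] = "zscore") -> NormalizationStats:
    """Fit per-feature normalization, pooling all waves of the (training) data.

    z-score uses the population standard deviation; min-max maps the
    observed range to [0, 1].  Constant features get location = value and
    scale = 1, so they normalize to exactly zero.
    """
    if not ds.mask.all():
        raise ValueError("normalize after imputation: dataset still has missing cells")
    flat = ds.values.reshape(-1, ds.n_features)
    if method == "zscore":
        location = flat.mean(axis=0)
        scale = flat.std(axis=0)
    elif method == "minmax":
        location = flat.min(axis=0)
        scale = flat.max(axis=0) - location
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    constant = scale <= 0
    scale = np.where(constant, 1.0, scale)
    return NormalizationStats(location=location, scale=scale, method=method)


def apply_normalizer(ds: TimeSeriesDataset, stats: NormalizationStats) -> TimeSeriesDataset:
    if stats.location.shape[0] != ds.n_features:
        raise ValueError(
            f"normalizer fitted for {stats.location.shape[0]} features, dataset has {ds.n_features}"
        )
    return replace(ds, values=(ds.values - stats.location) / stats.scale)


def invert_normalizer(ds: TimeSeriesDataset, stats: NormalizationStats) -> TimeSeriesDataset:
    if stats.location.shape[0] != ds.n_features:
        raise ValueError("normalizer dimension mismatch")
    return replace(ds, values=ds.values * stats.scale + stats.location)


def train_test_split(
    ds: TimeSeriesDataset,
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[TimeSeriesDataset, TimeSeriesDataset]:
    """Random subject-level split, stratified by label, deterministic in seed.

    The training set receives ``floor(N * train_fraction)`` subjects
    overall (per-stratum rounding is reconciled to hit this total).
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if ds.labels is None:
        raise ValueError("train_test_split requires labels")
    rng = np.random.default_rng(seed)
    n = ds.n_subjects
    n_train = int(np.floor(n * train_fraction))
    if not 1 <= n_train <= n - 1:
        raise ValueError("split would leave an empty train or test set")

    if stratify:
        train_idx: list[int] = []
        strata = [np.flatnonzero(ds.labels == c) for c in np.unique(ds.labels)]
        # largest-remainder apportionment of n_train across strata
        quotas = [len(s) * train_fraction for s in strata]
        takes = [int(np.floor(qt)) for qt in quotas]
        remainders = np.array(quotas) - np.array(takes)
        for k in np.argsort(-remainders)[: n_train - sum(takes)]:
            takes[k] += 1
        for stratum, take in zip(strata, takes):
            if 2 <= len(stratum):
                take = min(max(take, 1), len(stratum) - 1)
            perm = rng.permutation(stratum)
            train_idx.extend(perm[:take].tolist())
        train_mask = np.zeros(n, dtype=bool)
        train_mask[train_idx] = True
    else:
        perm = rng.permutation(n)
        train_mask = np.zeros(n, dtype=bool)
        train_mask[perm[:n_train]] = True

    return ds.subset(train_mask), ds.subset(~train_mask)
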