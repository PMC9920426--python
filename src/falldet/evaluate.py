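"""Offline configuration study: feature tables, 5-fold cross-validation,
and the exhaustive (frequency x window x algorithm x feature-subset) grid.

The full default grid has 5 x 5 x 15 x (2^12 - 1) = 1,535,625 points;
counting is always exact, while :func:`run_grid` accepts a seeded budget
subsample because exhaustively cross-validating every point is a
cluster-scale job. Ablations (median filtering, vertical acceleration,
per-user personalisation, cohort filters) are expressed as dataset
transforms and table filters over the same machinery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from . import preprocess
from .classify import GRID_ALGORITHMS, ConfusionCounts, confusion, make_classifier, metrics
from .data_model import Recording
from .features import (
    ACCEL_POOL,
    AXES,
    FULL_POOL,
    SENSOR_SHORT,
    STATISTICS,
    feature_names,
)
from .windowing import DEFAULT_WINDOW_SIZES, WindowSpec, extract_windows

#: The configuration carried to the watch: accelerometer only, full FS-1,
#: 3NN with Euclidean distance, 9-second windows at 50 Hz.
DEPLOYED_RATE_HZ = 50.0
DEPLOYED_WINDOW_S = 9.0
DEPLOYED_ALGORITHM = "knn3"
DEPLOYED_SUBSET = ACCEL_POOL


@dataclass(frozen=True)
class GridPoint:
    rate_hz: float
    window_s: float
    algorithm: str
    subset: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class GridSpace:
    frequencies: tuple[float, ...] = tuple(preprocess.DEFAULT_RATES)
    window_sizes: tuple[float, ...] = DEFAULT_WINDOW_SIZES
    algorithms: tuple[str, ...] = GRID_ALGORITHMS
    feature_pool: tuple[tuple[str, str], ...] = FULL_POOL

    def __post_init__(self) -> None:
        if not (self.frequencies and self.window_sizes
                and self.algorithms and self.feature_pool):
            raise ValueError("grid space sets must be non-empty")


@dataclass(frozen=True)
class EvalResult:
    """Fold-aggregated metrics for one grid point."""

    config: GridPoint
    accuracy_mean: float | None
    accuracy_sd: float | None
    specificity_mean: float | None
    specificity_sd: float | None
    sensitivity_mean: float | None
    sensitivity_sd: float | None
    n_windows: int
    fold_confusions: tuple[ConfusionCounts, ...] = field(default=(), repr=False)
    undefined_folds: int = 0


def count_feature_subsets(n: int) -> int:
    """Number of non-empty feature subsets of a pool of n: 2^n - 1.

    Cross-checked against the binomial expansion sum_{k=1..n} C(n, k).
    """
    if n < 1:
        raise ValueError("pool size must be >= 1")
    total = 2**n - 1
    assert total == sum(math.comb(n, k) for k in range(1, n + 1))
    return total


def grid_size(space: GridSpace) -> int:
    """|frequencies| x |windows| x |algorithms| x (2^pool - 1)."""
    return (
        len(space.frequencies)
        * len(space.window_sizes)
        * len(space.algorithms)
        * count_feature_subsets(len(space.feature_pool))
    )


def _subset_from_mask(pool: Sequence[tuple[str, str]], mask: int) -> tuple[tuple[str, str], ...]:
    return tuple(p for i, p in enumerate(pool) if mask >> i & 1)


def index_to_grid_point(space: GridSpace, index: int) -> GridPoint:
    """Decode a flat index in [0, grid_size) to its configuration."""
    n_sub = count_feature_subsets(len(space.feature_pool))
    if not (0 <= index < grid_size(space)):
        raise IndexError("grid index out of range")
    index, sub = divmod(index, n_sub)
    index, alg = divmod(index, len(space.algorithms))
    freq, win = divmod(index, len(space.window_sizes))
    return GridPoint(
        rate_hz=space.frequencies[freq],
        window_s=space.window_sizes[win],
        algorithm=space.algorithms[alg],
        subset=_subset_from_mask(space.feature_pool, sub + 1),
    )


def iter_grid(space: GridSpace):
    """Every grid point exactly once, in flat-index order."""
    for i in range(grid_size(space)):
        yield index_to_grid_point(space, i)


# ---------------------------------------------------------------------------
# Feature tables

_SENSOR_COLS = {"accelerometer": (0, 3), "gyroscope": (0, 3), "orientation": (1, 4)}


def build_feature_table(
    recordings: Sequence[Recording],
    rate_hz: float = DEPLOYED_RATE_HZ,
    window_s: float = DEPLOYED_WINDOW_S,
    jump_s: float = 1.0,
    sensors: Sequence[str] = ("accelerometer",),
    median_window: int | None = None,
    vertical: bool = False,
) -> pd.DataFrame:
    """Window-level FS-1 feature table for a set of recordings.

    Columns: every ``<sensor>_<stat>_<axis>`` feature for the requested
    sensors, plus ``label``, ``user_id``, ``cohort``, ``activity``,
    ``trial`` and ``start``. Recordings shorter than the window contribute
    no rows. ``median_window`` applies the rolling-median filter before
    feature extraction; ``vertical`` replaces the accelerometer trace by
    its world-vertical projection (requires the orientation trace).
    """
    spec = WindowSpec(window_s=window_s, jump_s=jump_s)
    cols = [
        f"{SENSOR_SHORT[s]}_{stat}_{axis}"
        for s in sensors
        for stat in STATISTICS
        for axis in AXES
    ]
    rows: list[np.ndarray] = []
    meta: list[tuple] = []
    win_len = int(round(window_s * rate_hz))
    for rec in recordings:
        windows = extract_windows(rec, spec)
        if not windows:
            continue
        per_sensor: list[np.ndarray] = []
        for sensor in sensors:
            trace = rec.traces.get(sensor)
            if trace is None:
                raise ValueError(f"recording {rec.stem()} lacks sensor {sensor!r}")
            if vertical and sensor == "accelerometer":
                orient = rec.traces.get("orientation")
                if orient is None:
                    raise ValueError(
                        f"recording {rec.stem()} lacks orientation for vertical mode"
                    )
                trace = preprocess.vertical_acceleration(trace, orient)
            if abs(trace.rate_hz - rate_hz) > 1e-9:
                trace = preprocess.resample(trace, rate_hz)
            if median_window is not None:
                trace = preprocess.median_filter(trace, median_window)
            lo, hi = _SENSOR_COLS[sensor]
            values = trace.values[:, lo:hi]
            starts = np.array(
                [int(round(w.start * rate_hz)) for w in windows], dtype=int
            )
            keep = starts + win_len <= values.shape[0]
            idx = starts[keep][:, None] + np.arange(win_len)[None, :]
            blocks = values[idx]  # (n_win, win_len, 3)
            stats = np.concatenate(
                [
                    blocks.max(axis=1),
                    blocks.min(axis=1),
                    blocks.mean(axis=1),
                    blocks.var(axis=1, ddof=1) if win_len > 1
                    else np.zeros((blocks.shape[0], 3)),
                ],
                axis=1,
            )
            per_sensor.append(stats)
        n_win = min(s.shape[0] for s in per_sensor)
        feat = np.concatenate([s[:n_win] for s in per_sensor], axis=1)
        rows.append(feat)
        meta.extend(
            (w.label, rec.user_id, rec.cohort, rec.activity, rec.trial, w.start)
            for w in windows[:n_win]
        )
    if not rows:
        return pd.DataFrame(
            columns=cols + ["label", "user_id", "cohort", "activity", "trial", "start"]
        )
    table = pd.DataFrame(np.vstack(rows), columns=cols)
    meta_df = pd.DataFrame(
        meta, columns=["label", "user_id", "cohort", "activity", "trial", "start"]
    )
    return pd.concat([table, meta_df], axis=1)


# ---------------------------------------------------------------------------
# Cross-validation

def kfold_split(
    labels: Sequence[str],
    k: int = 5,
    seed: int = 0,
    stratified: bool = True,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded disjoint exhaustive folds as (train_idx, test_idx) pairs."""
    y = np.asarray(labels)
    if k < 2:
        raise ValueError("k must be >= 2")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < k:
            raise ValueError(
                f"smallest class has {counts.min()} points, fewer than k={k} folds"
            )
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in splitter.split(np.zeros(len(y)), y)]


def _aggregate(name: str, fold_metrics: list[dict]) -> tuple[float | None, float | None]:
    vals = [m[name] for m in fold_metrics if m[name] is not None]
    if not vals:
        return None, None
    arr = np.asarray(vals)
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd


def cross_validate(
    table: pd.DataFrame,
    config: GridPoint,
    seed: int = 0,
    n_folds: int = 5,
    group_by_recording: bool = False,
) -> EvalResult:
    """5-fold metrics of one configuration on a pre-extracted feature table.

    The table must already be at the configuration's rate and window size;
    the subset selects columns. ``group_by_recording`` keeps all windows of
    one trial in the same fold (leakage control, off by default).
    """
    cols = feature_names(config.subset)
    missing = [c for c in cols if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks columns {missing}")
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    if group_by_recording:
        from sklearn.model_selection import GroupKFold

        groups = (
            table["user_id"].astype(str)
            + "/" + table["activity"].astype(str)
            + "/" + table["trial"].astype(str)
        ).to_numpy()
        folds = list(GroupKFold(n_splits=n_folds).split(X, y, groups))
    else:
        folds = kfold_split(y, k=n_folds, seed=seed)
    fold_metrics = []
    fold_confs = []
    undefined = 0
    for tr, te in folds:
        clf = make_classifier(config.algorithm, seed=seed)
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        c = confusion(y[te], pred)
        m = metrics(c)
        if any(v is None for v in m.values()):
            undefined += 1
        fold_metrics.append(m)
        fold_confs.append(c)
    acc = _aggregate("accuracy", fold_metrics)
    spec_ = _aggregate("specificity", fold_metrics)
    sens = _aggregate("sensitivity", fold_metrics)
    return EvalResult(
        config=config,
        accuracy_mean=acc[0], accuracy_sd=acc[1],
        specificity_mean=spec_[0], specificity_sd=spec_[1],
        sensitivity_mean=sens[0], sensitivity_sd=sens[1],
        n_windows=len(y),
        fold_confusions=tuple(fold_confs),
        undefined_folds=undefined,
    )


def run_grid(
    recordings: Sequence[Recording],
    space: GridSpace = GridSpace(),
    budget: int | None = None,
    seed: int = 0,
    jump_s: float = 1.0,
    progress: Callable[[int, int], None] | None = None,
) -> list[EvalResult]:
    """Cross-validate grid configurations, caching per-(rate, window)
    feature tables so all algorithms and subsets reuse them.

    ``budget`` draws a seeded uniform subsample of grid points without
    replacement; omit it to visit every point.
    """
    total = grid_size(space)
    if budget is not None:
        if budget <= 0:
            raise ValueError("budget must be positive")
        rng = np.random.default_rng(seed)
        indices = rng.choice(total, size=min(budget, total), replace=False)
        indices = np.sort(indices)
    else:
        indices = np.arange(total)
    sensors = tuple(dict.fromkeys(s for s, _ in space.feature_pool))
    cache: dict[tuple[float, float], pd.DataFrame] = {}
    results: list[EvalResult] = []
    for j, idx in enumerate(indices):
        point = index_to_grid_point(space, int(idx))
        key = (point.rate_hz, point.window_s)
        if key not in cache:
            cache[key] = build_feature_table(
                recordings, rate_hz=point.rate_hz, window_s=point.window_s,
                jump_s=jump_s, sensors=sensors,
            )
        results.append(cross_validate(cache[key], point, seed=seed))
        if progress is not None:
            progress(j + 1, len(indices))
    return results


def best_configuration(results: Sequence[EvalResult]) -> EvalResult:
    """Highest accuracy mean; specificity then sensitivity break ties."""
    defined = [r for r in results if r.accuracy_mean is not None]
    if not defined:
        raise ValueError("no result with defined accuracy")
    return max(
        defined,
        key=lambda r: (
            r.accuracy_mean,
            r.specificity_mean or 0.0,
            r.sensitivity_mean or 0.0,
        ),
    )


def personalised_eval(
    table: pd.DataFrame,
    user_id: str,
    config: GridPoint,
    seed: int = 0,
    n_folds: int = 5,
) -> EvalResult:
    """Cross-validate on a single user's windows (personalised model)."""
    sub = table[table["user_id"] == user_id]
    if sub.empty:
        raise ValueError(f"unknown user_id {user_id!r}")
    counts = sub["label"].value_counts()
    if len(counts) < 2 or counts.min() < n_folds:
        raise ValueError(
            f"user {user_id}: insufficient per-class windows for {n_folds}-fold CV"
        )
    return cross_validate(sub.reset_index(drop=True), config, seed=seed, n_folds=n_folds)


def results_table(results: Sequence[EvalResult]) -> pd.DataFrame:
    """Results as a DataFrame mirroring the study's table columns."""
    rows = []
    for r in results:
        rows.append(
            {
                "frequency_hz": r.config.rate_hz,
                "window_s": r.config.window_s,
                "algorithm": r.config.algorithm,
                "n_features": 3 * len(r.config.subset),
                "subset": "+".join(f"{SENSOR_SHORT[s]}_{st}" for s, st in r.config.subset),
                "accuracy_mean": r.accuracy_mean,
                "accuracy_sd": r.accuracy_sd,
                "specificity_mean": r.specificity_mean,
                "specificity_sd": r.specificity_sd,
                "sensitivity_mean": r.sensitivity_mean,
                "sensitivity_sd": r.sensitivity_sd,
                "n_windows": r.n_windows,
            }
        )
    return pd.DataFrame(rows)


def deployed_config(rate_hz: float = DEPLOYED_RATE_HZ) -> GridPoint:
    """The on-watch configuration, optionally at a reduced rate."""
    return GridPoint(
        rate_hz=rate_hz,
        window_s=DEPLOYED_WINDOW_S,
        algorithm=DEPLOYED_ALGORITHM,
        subset=DEPLOYED_SUBSET,
    )
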