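"""The FS-1 feature set: maximum, minimum, mean and variance per axis.

Two routes compute the same statistics:

* :func:`batch_features` — direct vectorised computation over a window.
* :class:`StreamState` / :func:`stream_update` — one-reading-at-a-time
  recursive updates, as an on-watch detector computes them while samples
  arrive. The mean uses the running-counter recursion
  ``m_N = m_{N-1} + (x - m_{N-1}) / N``; the variance the matching
  sample-variance recursion
  ``v_N = ((N-2) v_{N-1} + (x - m_{N-1})(x - m_N)) / (N-1)``
  (v_1 = 0), so streaming and batch agree to float precision.

Variance is the sample variance (N−1 denominator) throughout. No feature
scaling or normalisation is applied anywhere: the detector runs on raw
features.

Feature tables use columns named ``<sensor>_<stat>_<axis>`` (e.g.
``accel_max_x``) plus a ``label`` column. A feature-subset element is a
(sensor, statistic) pair applied jointly to x, y and z — the granularity
under which three sensors give a pool of 12 selectable features.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

STATISTICS = ("max", "min", "mean", "var")
AXES = ("x", "y", "z")
SENSOR_SHORT = {"accelerometer": "accel", "gyroscope": "gyro", "orientation": "orient"}

#: The full selectable pool: one (sensor, statistic) pair per entry.
FULL_POOL: tuple[tuple[str, str], ...] = tuple(
    (sensor, stat) for sensor in SENSOR_SHORT for stat in STATISTICS
)
ACCEL_POOL: tuple[tuple[str, str], ...] = tuple(
    (s, st) for s, st in FULL_POOL if s == "accelerometer"
)


def feature_names(subset: Sequence[tuple[str, str]]) -> list[str]:
    """Column names for a (sensor, statistic) subset, axis-expanded."""
    return [
        f"{SENSOR_SHORT[sensor]}_{stat}_{axis}"
        for sensor, stat in subset
        for axis in AXES
    ]


@dataclass(frozen=True)
class FeatureVector:
    """Ordered FS-1 features for one window."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.names),):
            raise ValueError("names/values length mismatch")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values))


def axis_statistics(values: np.ndarray) -> np.ndarray:
    """(4, n_axes) array of max/min/mean/sample-variance per column."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[0] == 0:
        raise ValueError("need a non-empty (n, axes) array")
    var = v.var(axis=0, ddof=1) if v.shape[0] > 1 else np.zeros(v.shape[1])
    return np.vstack([v.max(axis=0), v.min(axis=0), v.mean(axis=0), var])


def batch_features(
    windows_values: dict[str, np.ndarray],
    subset: Sequence[tuple[str, str]] = ACCEL_POOL,
) -> FeatureVector:
    """FS-1 features of one window from per-sensor sample arrays.

    ``windows_values`` maps sensor name to an (n, 3) array of that sensor's
    samples inside the window (for orientation, the quaternion vector part
    qx, qy, qz serves as the three axes).
    """
    names: list[str] = []
    out: list[np.ndarray] = []
    stats_cache: dict[str, np.ndarray] = {}
    for sensor, stat in subset:
        if sensor not in windows_values:
            raise ValueError(f"window has no samples for sensor {sensor!r}")
        if sensor not in stats_cache:
            stats_cache[sensor] = axis_statistics(windows_values[sensor])
        row = stats_cache[sensor][STATISTICS.index(stat)]
        out.append(row)
        names.extend(f"{SENSOR_SHORT[sensor]}_{stat}_{axis}" for axis in AXES)
    return FeatureVector(tuple(names), np.concatenate(out))


@dataclass
class StreamState:
    """Running per-axis statistics updated one reading at a time.

    ``n`` counts readings in the current window; state with ``n == 0`` is
    empty. All arrays have one entry per axis.
    """

    n_axes: int = 3
    n: int = 0
    running_max: np.ndarray = field(default=None)  # type: ignore[assignment]
    running_min: np.ndarray = field(default=None)  # type: ignore[assignment]
    running_mean: np.ndarray = field(default=None)  # type: ignore[assignment]
    running_var: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.running_max is None:
            self.reset()

    def reset(self) -> None:
        self.n = 0
        z = np.zeros(self.n_axes)
        self.running_max = z.copy()
        self.running_min = z.copy()
        self.running_mean = z.copy()
        self.running_var = z.copy()


def stream_update(state: StreamState, reading: Iterable[float]) -> StreamState:
    """Fold one sensor reading into the running statistics (all axes)."""
    x = np.asarray(tuple(reading), dtype=float)
    if x.shape != (state.n_axes,):
        raise ValueError(f"reading must have {state.n_axes} components")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sensor reading rejected")
    if state.n == 0:
        state.n = 1
        state.running_max = x.copy()
        state.running_min = x.copy()
        state.running_mean = x.copy()
        state.running_var = np.zeros(state.n_axes)
        return state
    n = state.n + 1
    prev_mean = state.running_mean
    new_mean = prev_mean + (x - prev_mean) / n
    state.running_max = np.maximum(state.running_max, x)
    state.running_min = np.minimum(state.running_min, x)
    state.running_var = ((n - 2) * state.running_var + (x - prev_mean) * (x - new_mean)) / (n - 1)
    state.running_mean = new_mean
    state.n = n
    return state


def stream_features(state: StreamState) -> np.ndarray:
    """(4, n_axes) statistics array from a stream state (no reset)."""
    if state.n == 0:
        raise ValueError("no data in window")
    return np.vstack(
        [state.running_max, state.running_min, state.running_mean, state.running_var]
    )


def stream_finalize(
    state: StreamState,
    subset: Sequence[tuple[str, str]] = ACCEL_POOL,
    sensor: str = "accelerometer",
) -> FeatureVector:
    """Close the current window: emit its features and reset the state."""
    stats = stream_features(state)
    names: list[str] = []
    rows: list[np.ndarray] = []
    for subset_sensor, stat in subset:
        if subset_sensor != sensor:
            raise ValueError(
                f"stream carries {sensor!r} data but subset asks for {subset_sensor!r}"
            )
        rows.append(stats[STATISTICS.index(stat)])
        names.extend(f"{SENSOR_SHORT[sensor]}_{stat}_{axis}" for axis in AXES)
    state.reset()
    return FeatureVector(tuple(names), np.concatenate(rows))
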