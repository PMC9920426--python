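"""Domain types and CSV I/O for wrist-sensor fall/ADL recordings.

A *recording* is one trial of one activity by one participant: up to three
triaxial sensor traces (accelerometer, gyroscope, orientation) sampled
nominally at 50 Hz, plus metadata. Fall recordings additionally carry a
manually delimited "actual fall" interval ``[a, b]`` in seconds — the span
containing the fall's four phases (prefall, impact, adjustment, postfall).

On disk a recording is a set of sibling CSV files sharing a stem prefix,
one file per sensor, with a flat key-value metadata sidecar holding the
cohort and the actual-fall interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Class labels. Fall is the positive class throughout.
FALL = "Fall"
ADL = "ADL"

FALL_CODES = tuple(f"F{i:02d}" for i in range(1, 9))
ADL_CODES = tuple(f"D{i:02d}" for i in range(1, 12))
ACTIVITY_CODES = FALL_CODES + ADL_CODES

SENSORS = ("accelerometer", "gyroscope", "orientation")

#: ADL subsets performed by each elder participant.
EP_ACTIVITIES: dict[str, tuple[str, ...]] = {
    "U21": ("D01", "D04", "D09", "D10", "D11"),
    "U22": ("D01", "D04", "D09", "D10", "D11"),
    "U23": ("D01", "D03", "D04", "D09", "D10", "D11"),
    "U24": ("D01", "D03", "D04", "D09", "D10", "D11"),
    "U25": ("D01", "D04", "D09", "D10", "D11"),
    "U26": ("D01", "D03", "D04", "D09", "D10", "D11"),
    "U27": ("D01", "D03", "D04", "D09", "D10", "D11"),
    "U28": ("D01", "D03", "D04", "D09", "D10", "D11"),
    "U29": ("D01", "D03", "D04", "D09", "D10", "D11"),
    "U30": ("D01", "D03", "D04", "D09", "D10", "D11"),
    "U31": ("D01", "D03", "D04", "D09", "D10", "D11"),
}


class LayoutError(ValueError):
    """Raised when a CSV file does not match the expected layout."""


@dataclass(frozen=True)
class CsvLayout:
    """Describes how recording CSV files are named and laid out.

    The default layout writes ``<prefix>_<suffix>.csv`` per sensor with
    header ``t,x,y,z`` (orientation: ``t,qw,qx,qy,qz``) and a
    ``<prefix>_meta.txt`` key-value sidecar. Alternative column names of
    public datasets can be absorbed by remapping ``columns``.
    """

    sensor_suffix: Mapping[str, str] = field(
        default_factory=lambda: {
            "accelerometer": "accel",
            "gyroscope": "gyro",
            "orientation": "orient",
        }
    )
    columns: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {
            "accelerometer": ("t", "x", "y", "z"),
            "gyroscope": ("t", "x", "y", "z"),
            "orientation": ("t", "qw", "qx", "qy", "qz"),
        }
    )
    meta_suffix: str = "meta"


DEFAULT_LAYOUT = CsvLayout()


@dataclass(frozen=True)
class SensorTrace:
    """One sensor's time series: timestamps plus 3 (triaxial) or 4
    (quaternion) value columns.

    ``t`` is seconds from recording start, 0-based and non-decreasing.
    Accelerometer units are m/s^2 (gravity included), gyroscope rad/s,
    orientation a scalar-first unit quaternion (body-to-world).
    """

    sensor: str
    rate_hz: float
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.sensor not in SENSORS:
            raise ValueError(f"unknown sensor kind {self.sensor!r}")
        t = np.asarray(self.t, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "values", v)
        width = 4 if self.sensor == "orientation" else 3
        if v.ndim != 2 or v.shape[1] != width:
            raise ValueError(
                f"{self.sensor} trace needs shape (n, {width}), got {v.shape}"
            )
        if t.shape != (v.shape[0],):
            raise ValueError("t and values length mismatch")
        if t.size and (not np.all(np.isfinite(t)) or not np.all(np.isfinite(v))):
            raise ValueError("non-finite sample in trace")
        if t.size > 1 and np.any(np.diff(t) < 0):
            raise ValueError("timestamps must be non-decreasing")
        if self.rate_hz <= 0:
            raise ValueError("rate_hz must be positive")
        if self.sensor == "orientation" and t.size:
            norms = np.sum(v * v, axis=1)
            if np.max(np.abs(norms - 1.0)) > 1e-6:
                raise ValueError("orientation quaternions must be unit within 1e-6")

    @property
    def n_samples(self) -> int:
        return self.t.shape[0]

    @property
    def duration(self) -> float:
        """Nominal duration in seconds: sample count over nominal rate."""
        return self.n_samples / self.rate_hz

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SensorTrace):
            return NotImplemented
        return (
            self.sensor == other.sensor
            and math.isclose(self.rate_hz, other.rate_hz, rel_tol=1e-9)
            and self.t.shape == other.t.shape
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.values, other.values)
        )


@dataclass(frozen=True)
class Recording:
    """One activity trial: sensor traces + identity + optional fall interval."""

    user_id: str
    cohort: str
    activity: str
    trial: int
    traces: Mapping[str, SensorTrace]
    actual_fall: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.cohort not in ("YP", "EP"):
            raise ValueError(f"cohort must be YP or EP, got {self.cohort!r}")
        if self.activity not in ACTIVITY_CODES:
            raise ValueError(f"unknown activity code {self.activity!r}")
        for name, trace in self.traces.items():
            if name != trace.sensor:
                raise ValueError(f"trace keyed {name!r} has sensor {trace.sensor!r}")
        if self.is_fall:
            if self.actual_fall is None:
                raise ValueError("fall recording requires an actual_fall interval")
            a, b = self.actual_fall
            if not (0.0 <= a < b <= self.duration + 1e-9):
                raise ValueError(
                    f"actual_fall [{a}, {b}] outside recording of "
                    f"duration {self.duration}"
                )
        elif self.actual_fall is not None:
            raise ValueError("ADL recording must not carry an actual_fall interval")

    @property
    def is_fall(self) -> bool:
        return self.activity in FALL_CODES

    @property
    def duration(self) -> float:
        if not self.traces:
            return 0.0
        return max(tr.duration for tr in self.traces.values())

    @property
    def label(self) -> str:
        return FALL if self.is_fall else ADL

    def stem(self) -> str:
        return f"{self.user_id}_{self.activity}_R{self.trial:02d}"


@dataclass(frozen=True)
class Protocol:
    """Acquisition protocol: who performed which activities how many times."""

    participants: tuple[tuple[str, str, tuple[str, ...]], ...]
    repetitions: Mapping[str, int]

    def __post_init__(self) -> None:
        for _, cohort, activities in self.participants:
            if cohort not in ("YP", "EP"):
                raise ValueError(f"unknown cohort {cohort!r}")
            for act in activities:
                if act not in ACTIVITY_CODES:
                    raise ValueError(f"unknown activity code {act!r}")
        for act in self.repetitions:
            if act not in ACTIVITY_CODES:
                raise ValueError(f"unknown activity code {act!r}")

    def reps(self, activity: str) -> int:
        return self.repetitions.get(activity, 3)

    def trials(self) -> Iterable[tuple[str, str, str, int]]:
        """Yield (user_id, cohort, activity, trial) for every scheduled trial."""
        for user_id, cohort, activities in self.participants:
            for act in activities:
                for rep in range(1, self.reps(act) + 1):
                    yield user_id, cohort, act, rep


def yp_protocol(n_users: int = 14) -> Protocol:
    """Young-participant protocol: all falls and ADLs, 3 repetitions each
    except the sideways sitting fall F08 which is repeated 4 times."""
    participants = tuple(
        (f"U{i:02d}", "YP", ACTIVITY_CODES) for i in range(1, n_users + 1)
    )
    return Protocol(participants=participants, repetitions={"F08": 4})


def ep_protocol() -> Protocol:
    """Elder-participant protocol: the ADL subsets each elder performed.

    Elder repetition counts varied per person in the original acquisition;
    3 is used as the nominal count for synthetic generation. The published
    EP signal totals are metadata, never recomputed from this protocol.
    """
    participants = tuple(
        (uid, "EP", acts) for uid, acts in EP_ACTIVITIES.items()
    )
    return Protocol(participants=participants, repetitions={})


@dataclass(frozen=True)
class SignalCounts:
    falls: int
    adls: int


def expected_signal_counts(protocol: Protocol) -> dict[str, SignalCounts]:
    """Scheduled signal counts per cohort: users x activities x repetitions."""
    counts: dict[str, list[int]] = {}
    for _, cohort, activity, _ in protocol.trials():
        falls_adls = counts.setdefault(cohort, [0, 0])
        falls_adls[0 if activity in FALL_CODES else 1] += 1
    return {c: SignalCounts(f, a) for c, (f, a) in counts.items()}


# ---------------------------------------------------------------------------
# CSV I/O


def write_recording(
    rec: Recording, directory: str | Path, layout: CsvLayout = DEFAULT_LAYOUT
) -> list[Path]:
    """Write one CSV per sensor plus a metadata sidecar; returns the paths.

    Re-reading the written files with :func:`read_recording` reproduces the
    recording exactly (float round-trip via repr-precision formatting).
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = rec.stem()
    paths: list[Path] = []
    for sensor, trace in rec.traces.items():
        cols = layout.columns[sensor]
        path = directory / f"{stem}_{layout.sensor_suffix[sensor]}.csv"
        data = np.column_stack([trace.t, trace.values])
        df = pd.DataFrame(data, columns=list(cols))
        df.to_csv(path, index=False, float_format="%.17g")
        paths.append(path)
    meta = directory / f"{stem}_{layout.meta_suffix}.txt"
    lines = [
        f"user_id={rec.user_id}",
        f"cohort={rec.cohort}",
        f"activity={rec.activity}",
        f"trial={rec.trial}",
    ]
    for sensor, trace in rec.traces.items():
        lines.append(f"rate_hz_{layout.sensor_suffix[sensor]}={trace.rate_hz!r}")
    if rec.actual_fall is not None:
        lines.append(f"actual_fall_start={rec.actual_fall[0]!r}")
        lines.append(f"actual_fall_end={rec.actual_fall[1]!r}")
    meta.write_text("\n".join(lines) + "\n", encoding="utf-8")
    paths.append(meta)
    return paths


def _read_meta(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        meta[key.strip()] = value.strip()
    return meta


def _read_sensor_csv(path: Path, sensor: str, layout: CsvLayout) -> pd.DataFrame:
    cols = list(layout.columns[sensor])
    try:
        # round_trip: default fast parser can be off by one ulp, which
        # would break exact write->read identity
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise LayoutError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: missing columns {missing}")
    df = df[cols]
    for col in cols:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            # +2: header line plus 1-based numbering
            line_no = int(bad.idxmax()) + 2
            raise LayoutError(f"{path}: non-numeric value in column "
                              f"{col!r} at line {line_no}")
        if numeric.isna().any():
            line_no = int(numeric.isna().idxmax()) + 2
            raise LayoutError(f"{path}: empty value in column {col!r} "
                              f"at line {line_no}")
        df[col] = numeric
    return df


def infer_rate_hz(t: np.ndarray) -> float:
    """Nominal sampling rate from the median inter-sample gap."""
    t = np.asarray(t, dtype=float)
    if t.size < 2:
        raise ValueError("need at least two samples to infer a rate")
    gap = float(np.median(np.diff(t)))
    if gap <= 0:
        raise ValueError("non-positive median sample gap")
    return 1.0 / gap


def read_recording(
    prefix: str | Path, layout: CsvLayout = DEFAULT_LAYOUT
) -> Recording:
    """Read a recording from its file-stem prefix.

    ``prefix`` is the path up to (excluding) the ``_<sensor>.csv`` suffix,
    e.g. ``data/U01_F03_R01``. Sensors whose file is absent are simply not
    present in the returned traces map (a structured absence, not an error).
    """
    prefix = Path(prefix)
    meta_path = prefix.parent / f"{prefix.name}_{layout.meta_suffix}.txt"
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
    meta = _read_meta(meta_path)
    traces: dict[str, SensorTrace] = {}
    for sensor in SENSORS:
        suffix = layout.sensor_suffix[sensor]
        path = prefix.parent / f"{prefix.name}_{suffix}.csv"
        if not path.exists():
            continue
        df = _read_sensor_csv(path, sensor, layout)
        df = df.sort_values(df.columns[0], kind="stable")
        t = df.iloc[:, 0].to_numpy(dtype=float)
        values = df.iloc[:, 1:].to_numpy(dtype=float)
        rate_key = f"rate_hz_{suffix}"
        rate = float(meta[rate_key]) if rate_key in meta else infer_rate_hz(t)
        traces[sensor] = SensorTrace(sensor=sensor, rate_hz=rate, t=t, values=values)
    actual_fall = None
    if "actual_fall_start" in meta:
        actual_fall = (float(meta["actual_fall_start"]), float(meta["actual_fall_end"]))
    return Recording(
        user_id=meta["user_id"],
        cohort=meta["cohort"],
        activity=meta["activity"],
        trial=int(meta["trial"]),
        traces=traces,
        actual_fall=actual_fall,
    )


def list_recordings(directory: str | Path, layout: CsvLayout = DEFAULT_LAYOUT) -> list[Path]:
    """Recording prefixes found in a directory (via metadata sidecars)."""
    directory = Path(directory)
    suffix = f"_{layout.meta_suffix}.txt"
    prefixes = []
    for meta in sorted(directory.glob(f"*{suffix}")):
        prefixes.append(meta.parent / meta.name[: -len(suffix)])
    return prefixes


def with_traces(rec: Recording, traces: Mapping[str, SensorTrace]) -> Recording:
    """Copy of ``rec`` with its traces replaced (transform plumbing)."""
    return replace(rec, traces=dict(traces))
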