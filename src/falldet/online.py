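"""Simulator of the on-watch detector.

The watch has no multithreading: it alternates between collecting one
window of samples (updating the streaming FS-1 statistics as each reading
arrives) and classifying that window with kNN. Classification takes real
time — the *dead zone* — during which sensor samples are dropped, so a fall
that happens wholly inside it can never be detected. Dead time grows
linearly with the stored dataset size, calibrated to the single field
observation of ~2 s at ~650 points.

When a fall is predicted, the wearer is asked to confirm or deny it and the
window's features are appended to the on-watch dataset with the confirmed
label (no answer counts as a confirmed fall — fail-safe). A memory cap is
enforced by pruning: oldest seed ADL points first, then oldest seed falls,
then oldest feedback points, keeping class balance within a configured
ratio where possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classify import LabeledPoint, ConfusionCounts, knn_predict
from .data_model import ADL, FALL, Recording
from .features import ACCEL_POOL, StreamState, stream_finalize, stream_update
from .windowing import label_window


@dataclass(frozen=True)
class OnlineConfig:
    """Knobs of the on-watch detector.

    ``detect_cost_s_per_point`` is the linear dead-time model: seconds of
    classification per stored dataset point (default 2/650, from ~2 s
    observed at ~650 points). ``dataset_cap`` defaults to the 400-point
    seed dataset (200 falls + 200 ADLs).
    """

    window_s: float = 9.0
    rate_hz: float = 50.0
    k: int = 3
    dataset_cap: int = 400
    detect_cost_s_per_point: float = 2.0 / 650.0
    balance_ratio_max: float = 3.0
    feedback_pause_s: float = 0.0

    def __post_init__(self) -> None:
        if min(self.window_s, self.rate_hz, self.k, self.dataset_cap) <= 0:
            raise ValueError("window_s, rate_hz, k and dataset_cap must be positive")
        if self.detect_cost_s_per_point < 0 or self.feedback_pause_s < 0:
            raise ValueError("costs must be non-negative")
        if self.balance_ratio_max < 1:
            raise ValueError("balance_ratio_max must be >= 1")


@dataclass(frozen=True)
class Stream:
    """A continuous accelerometer sample stream with ground truth.

    ``samples`` is (n, 3) at ``rate_hz``; ``fall_intervals`` are the
    ground-truth actual-fall spans in stream seconds.
    """

    rate_hz: float
    samples: np.ndarray
    fall_intervals: tuple[tuple[float, float], ...] = ()

    @property
    def duration(self) -> float:
        return self.samples.shape[0] / self.rate_hz


@dataclass
class SessionLog:
    """Trace of one simulated wearing session."""

    detections: list[tuple[float, str]] = field(default_factory=list)
    feedback: list[tuple[float, str]] = field(default_factory=list)
    dataset_size_series: list[tuple[float, int]] = field(default_factory=list)
    classifications: list[tuple[float, str, str]] = field(default_factory=list)
    dead_time_total: float = 0.0
    collected_samples: int = 0
    dropped_samples: int = 0
    missed_falls_in_dead_time: int = 0
    confusion: ConfusionCounts = field(default_factory=ConfusionCounts)

    @property
    def n_calls(self) -> int:
        return len(self.classifications)

    def false_positives(self) -> list[float]:
        return [t for t, truth, pred in self.classifications
                if truth == ADL and pred == FALL]


def build_stream(
    recordings: Sequence[Recording],
    idle_s: float = 3.0,
    seed: int = 0,
    rate_hz: float = 50.0,
) -> Stream:
    """Concatenate recordings' accelerometer traces with quasi-static idle
    filler between them, carrying fall intervals through as ground truth."""
    rng = np.random.default_rng(seed)
    n_idle = int(round(idle_s * rate_hz))
    chunks: list[np.ndarray] = []
    intervals: list[tuple[float, float]] = []
    offset = 0
    for rec in recordings:
        trace = rec.traces["accelerometer"]
        if abs(trace.rate_hz - rate_hz) > 1e-9:
            raise ValueError("stream recordings must share the stream rate")
        if rec.actual_fall is not None:
            a, b = rec.actual_fall
            intervals.append((offset / rate_hz + a, offset / rate_hz + b))
        chunks.append(trace.values)
        offset += trace.values.shape[0]
        if n_idle:
            idle = np.broadcast_to([0.0, 0.0, 9.81], (n_idle, 3)) + rng.normal(
                0.0, 0.1, size=(n_idle, 3)
            )
            chunks.append(idle)
            offset += n_idle
    samples = np.vstack(chunks) if chunks else np.empty((0, 3))
    return Stream(rate_hz=rate_hz, samples=samples, fall_intervals=tuple(intervals))


def prune_dataset(
    dataset: list[LabeledPoint],
    cap: int,
    balance_ratio_max: float = 3.0,
) -> list[LabeledPoint]:
    """Enforce the memory cap.

    Removal tiers: oldest seed ADL points, then oldest seed fall points,
    then oldest feedback points. Within the cap, class balance is kept
    within ``balance_ratio_max`` where possible: when one class outnumbers
    the other beyond the ratio, removal is restricted to the majority
    class.
    """
    if cap < 2:
        raise ValueError("cap must allow at least one point per class")
    kept = list(dataset)
    tier = {("seed-dataset", ADL): 0, ("seed-dataset", FALL): 1,
            ("user-feedback", ADL): 2, ("user-feedback", FALL): 2}
    order = {id(p): i for i, p in enumerate(kept)}
    while len(kept) > cap:
        n_fall = sum(1 for p in kept if p.label == FALL)
        n_adl = len(kept) - n_fall
        majority: str | None = None
        if n_adl and n_fall:
            if n_fall > balance_ratio_max * n_adl:
                majority = FALL
            elif n_adl > balance_ratio_max * n_fall:
                majority = ADL
        candidates = [p for p in kept if majority is None or p.label == majority]
        if not candidates:
            candidates = kept
        victim = min(candidates, key=lambda p: (tier[(p.provenance, p.label)], order[id(p)]))
        kept.remove(victim)
    return kept


def truthful_oracle(time_s: float, truth: str) -> str:
    """Feedback oracle that always answers with the ground-truth label."""
    return truth


def run_detector(
    stream: Stream,
    seed_dataset: Sequence[LabeledPoint],
    config: OnlineConfig = OnlineConfig(),
    oracle: Callable[[float, str], str] = truthful_oracle,
) -> SessionLog:
    """Run the sequential collect/classify cycle over a stream.

    Each cycle collects ``window_s`` seconds of samples one reading at a
    time through the streaming statistics, classifies the finished window
    (dead time = dataset size x per-point cost, samples dropped), and on a
    Fall prediction queries the feedback oracle, appends the labeled window
    to the dataset and prunes to the cap. Ground truth per window follows
    the 50%-overlap labeling rule; a ground-truth fall wholly inside a
    dropped span is logged as missed and counted as a false negative.
    """
    if not seed_dataset:
        raise ValueError("empty seed dataset")
    dataset = list(seed_dataset)
    log = SessionLog()
    rate = config.rate_hz
    win_len = int(round(config.window_s * rate))
    n_total = stream.samples.shape[0]
    log.dataset_size_series.append((0.0, len(dataset)))

    state = StreamState()
    pos = 0
    while pos + win_len <= n_total:
        t_start = pos / rate
        t_end = t_start + config.window_s
        for i in range(pos, pos + win_len):
            stream_update(state, stream.samples[i])
        log.collected_samples += win_len
        fv = stream_finalize(state, subset=ACCEL_POOL)
        pred = knn_predict(dataset, fv.values, k=config.k)
        truth = _window_truth((t_start, t_end), stream.fall_intervals)
        log.classifications.append((t_end, truth, pred))
        log.confusion = log.confusion + _single_confusion(truth, pred)

        dead_s = len(dataset) * config.detect_cost_s_per_point
        if pred == FALL:
            log.detections.append((t_end, pred))
            answer = oracle(t_end, truth)
            log.feedback.append((t_end, answer))
            dataset.append(
                LabeledPoint(fv.values, answer, provenance="user-feedback")
            )
            dataset = prune_dataset(
                dataset, config.dataset_cap, config.balance_ratio_max
            )
            dead_s += config.feedback_pause_s
        log.dataset_size_series.append((t_end, len(dataset)))

        dead_len = int(round(dead_s * rate))
        dead_len = min(dead_len, n_total - (pos + win_len))
        if dead_len > 0:
            t_dead_end = (pos + win_len + dead_len) / rate
            missed = _count_wholly_inside(
                stream.fall_intervals, (t_end, t_dead_end)
            )
            log.missed_falls_in_dead_time += missed
            log.confusion = log.confusion + ConfusionCounts(fn=missed)
        log.dead_time_total += dead_len / rate
        log.dropped_samples += dead_len
        pos += win_len + dead_len

    log.dropped_samples += n_total - pos if pos < n_total else 0
    return log


def _window_truth(
    window: tuple[float, float], intervals: Sequence[tuple[float, float]]
) -> str:
    for interval in intervals:
        if label_window(window, interval) == FALL:
            return FALL
    return ADL


def _single_confusion(truth: str, pred: str) -> ConfusionCounts:
    return ConfusionCounts(
        tp=int(truth == FALL and pred == FALL),
        tn=int(truth == ADL and pred == ADL),
        fp=int(truth == ADL and pred == FALL),
        fn=int(truth == FALL and pred == ADL),
    )


def _count_wholly_inside(
    intervals: Sequence[tuple[float, float]], span: tuple[float, float]
) -> int:
    lo, hi = span
    return sum(1 for a, b in intervals if a >= lo and b <= hi)


def power_budget(
    capacity_wh: float,
    observed_lifetime_h: float,
    baseline_lifetime_h: float,
) -> dict[str, float]:
    """Average-draw arithmetic from battery capacity and lifetimes.

    ``app_draw_w`` is capacity over observed lifetime with the detector
    running; ``baseline_draw_w`` capacity over the factory lifetime;
    ``delta_w`` their difference — the detector's own draw — and
    ``daily_wh`` that delta over 24 h. Intermediate draws are rounded to
    3 decimals, matching how such chains are typically reported.
    """
    if min(capacity_wh, observed_lifetime_h, baseline_lifetime_h) <= 0:
        raise ValueError("inputs must be positive")
    if observed_lifetime_h >= baseline_lifetime_h:
        raise ValueError("observed lifetime must be below the baseline lifetime")
    app = round(capacity_wh / observed_lifetime_h, 3)
    base = round(capacity_wh / baseline_lifetime_h, 3)
    delta = round(app - base, 3)
    return {
        "app_draw_w": app,
        "baseline_draw_w": base,
        "delta_w": delta,
        "daily_wh": round(delta * 24.0, 3),
    }
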