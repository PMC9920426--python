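"""Sliding-window extraction and Fall/ADL labeling.

Windows are half-open intervals [start, start + window_s) taken every
``jump_s`` seconds from time 0 while they fit inside the recording. A
window from a fall file is labeled Fall when it overlaps at least half of
the actual-fall interval (ties count as Fall — the safety-first reading of
"at least 50%"); windows from ADL files are always ADL.

Sample indexing: window [t, t+w) at rate f holds samples i with
t*f <= i < (t+w)*f, exactly 450 at (9 s, 50 Hz).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .data_model import ADL, FALL, Recording

log = logging.getLogger(__name__)

DEFAULT_WINDOW_SIZES = (5.0, 6.0, 7.0, 8.0, 9.0)


@dataclass(frozen=True)
class WindowSpec:
    window_s: float = 9.0
    jump_s: float = 1.0

    def __post_init__(self) -> None:
        if self.window_s <= 0 or self.jump_s <= 0:
            raise ValueError("window_s and jump_s must be positive")


@dataclass(frozen=True)
class LabeledWindow:
    """A fixed-duration slice of a recording with its class label."""

    source: Recording
    start: float
    end: float
    label: str

    def sample_slice(self, rate_hz: float) -> slice:
        """Index slice of this window's samples in a uniform trace."""
        i0 = int(round(self.start * rate_hz))
        i1 = int(round(self.end * rate_hz))
        return slice(i0, i1)


def label_window(
    window: tuple[float, float], fall: tuple[float, float] | None
) -> str:
    """Fall iff the window covers at least 50% of the actual-fall interval."""
    start, end = window
    if end < start:
        raise ValueError("window end before start")
    if fall is None:
        return ADL
    a, b = fall
    if b < a:
        raise ValueError("fall interval end before start")
    overlap = min(end, b) - max(start, a)
    return FALL if overlap >= 0.5 * (b - a) else ADL


def count_windows(duration: float, spec: WindowSpec) -> int:
    """Closed form for the number of full windows: floor((d - w)/jump) + 1."""
    if duration < spec.window_s:
        return 0
    # Guard float noise so e.g. duration exactly w + k*jump counts the last one.
    return int(math.floor((duration - spec.window_s) / spec.jump_s + 1e-9)) + 1


def extract_windows(rec: Recording, spec: WindowSpec) -> list[LabeledWindow]:
    """All labeled windows of a recording, starts at 0, jump_s, 2*jump_s, ...

    A recording shorter than the window yields an empty list (logged).
    Remainder samples after the last full window are discarded.
    """
    duration = rec.duration
    n = count_windows(duration, spec)
    if n == 0:
        log.warning(
            "recording %s (%.2f s) shorter than window %.2f s; no windows",
            rec.stem(), duration, spec.window_s,
        )
        return []
    out = []
    for k in range(n):
        start = k * spec.jump_s
        end = start + spec.window_s
        out.append(
            LabeledWindow(
                source=rec,
                start=start,
                end=end,
                label=label_window((start, end), rec.actual_fall),
            )
        )
    return out
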