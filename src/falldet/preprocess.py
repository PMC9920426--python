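"""Signal conditioning: frequency reduction, rolling-median filtering and
vertical-acceleration projection.

Rate reduction resamples onto a uniform grid by linear interpolation (the
deterministic choice that also handles non-integer ratios such as 50->40 Hz);
an optional block-median mode is provided for sensitivity checks. The median
filter is centre-aligned with passthrough edges so trace length — and hence
window arithmetic — is preserved.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from .data_model import SensorTrace

DEFAULT_RATES = (50.0, 40.0, 25.0, 10.0, 5.0)


def resample(trace: SensorTrace, target_hz: float, mode: str = "linear") -> SensorTrace:
    """Reduce a trace to ``target_hz`` on a uniform grid spanning its duration.

    The output has ``round(duration * target_hz)`` samples at times
    ``k / target_hz``. Values are linearly interpolated per axis (mode
    ``"linear"``, default) or block medians of the samples nearest each grid
    point (mode ``"block-median"``). Upsampling is refused.
    """
    if trace.n_samples == 0:
        raise ValueError("cannot resample an empty trace")
    if target_hz <= 0:
        raise ValueError("target_hz must be positive")
    if target_hz > trace.rate_hz + 1e-9:
        raise ValueError(
            f"no upsampling: target {target_hz} Hz above source {trace.rate_hz} Hz"
        )
    n_new = int(round(trace.duration * target_hz))
    t_new = np.arange(n_new) / target_hz
    if mode == "linear":
        values = np.column_stack(
            [np.interp(t_new, trace.t, trace.values[:, j])
             for j in range(trace.values.shape[1])]
        )
    elif mode == "block-median":
        # Each output sample is the median of the source samples whose time
        # rounds to its grid cell (anti-alias sensitivity mode).
        idx = np.clip(np.round(trace.t * target_hz).astype(int), 0, n_new - 1)
        values = np.empty((n_new, trace.values.shape[1]))
        for k in range(n_new):
            sel = trace.values[idx == k]
            if sel.size == 0:
                j = np.argmin(np.abs(trace.t - t_new[k]))
                sel = trace.values[j : j + 1]
            values[k] = np.median(sel, axis=0)
    else:
        raise ValueError(f"unknown resample mode {mode!r}")
    if trace.sensor == "orientation":
        values = values / np.linalg.norm(values, axis=1, keepdims=True)
    return SensorTrace(trace.sensor, float(target_hz), t_new, values)


def median_filter(trace: SensorTrace, window: int = 5) -> SensorTrace:
    """Centre-aligned rolling median per axis; window must be odd.

    Edge samples without a full window of neighbours keep their original
    values, so the trace length is unchanged.
    """
    if window % 2 == 0 or window < 3:
        raise ValueError("median window must be odd and >= 3")
    v = trace.values
    out = v.copy()
    half = window // 2
    if v.shape[0] >= window:
        sw = np.lib.stride_tricks.sliding_window_view(v, window, axis=0)
        out[half : v.shape[0] - half] = np.median(sw, axis=-1)
    return SensorTrace(trace.sensor, trace.rate_hz, trace.t, out)


def _quat_align(orientation: SensorTrace, t: np.ndarray) -> np.ndarray:
    """Interpolate quaternion components to the given timestamps and
    renormalise (adequate for slowly varying orientation)."""
    q = np.column_stack(
        [np.interp(t, orientation.t, orientation.values[:, j]) for j in range(4)]
    )
    norms = np.linalg.norm(q, axis=1, keepdims=True)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("orientation quaternions deviate from unit norm")
    return q / norms


def vertical_acceleration(
    accel: SensorTrace, orientation: SensorTrace
) -> SensorTrace:
    """Project body-frame acceleration onto the world vertical axis.

    Each accelerometer sample is rotated into the world frame by the
    (interpolated) body-to-world unit quaternion; the world z-component —
    the acceleration along the vertically upward vector, at rest equal to
    +g — is returned as a single-axis trace stored in the z column (x and y
    are zero).
    """
    if accel.sensor != "accelerometer" or orientation.sensor != "orientation":
        raise ValueError("expected an accelerometer and an orientation trace")
    q = _quat_align(orientation, accel.t)
    rot = Rotation.from_quat(q, scalar_first=True)
    world = rot.apply(accel.values)
    values = np.zeros_like(accel.values)
    values[:, 2] = world[:, 2]
    return SensorTrace("accelerometer", accel.rate_hz, accel.t, values)
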