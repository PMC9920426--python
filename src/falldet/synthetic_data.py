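"""Seeded generator of synthetic fall and ADL recordings.

Emulates the statistical structure of a wrist-worn acquisition at 50 Hz:

* Fall files (F01-F08) of 8-16.5 s containing one four-phase fall event —
  prefall free-fall onset, an impact spike cluster, a decaying adjustment
  oscillation and a near-static postfall — whose "actual fall" interval has
  duration drawn from Normal(3.1037, 0.2731) s (truncated at 1.5 s) and is
  centred on the impact, where acceleration variation is greatest.
* ADL files (D01-D11) in four movement classes: periodic (walk, jog,
  stairs), transitional (sit/stand/crouch), impulsive (hit, clap, jump —
  deliberately fall-confusable short high-amplitude spikes) and
  quasi-static (door).

All three sensor streams are mutually consistent: orientation is a slowly
varying unit quaternion (body-to-world, scalar-first), the gyroscope is the
body angular rate that produces it, and the accelerometer reads the
body-frame gravity reaction plus movement plus Gaussian noise — so at rest,
rotating the accelerometer vector by the orientation recovers (0, 0, g).

Determinism: every generated recording is a pure function of
(code, params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .data_model import (
    ADL_CODES,
    FALL_CODES,
    Protocol,
    Recording,
    SensorTrace,
)

GRAVITY = 9.81
RATE_HZ = 50.0


@dataclass(frozen=True)
class FallShapeParams:
    """Shape of a generated fall file.

    ``impact_peak`` and ``noise_sd`` are calibration knobs (signal
    amplitudes are not dictated by the acquisition protocol); the duration
    statistics are the protocol's.
    """

    fall_duration_mean: float = 3.1037
    fall_duration_sd: float = 0.2731
    fall_duration_min: float = 1.5
    impact_peak: float = 30.0
    file_duration_range: tuple[float, float] = (8.0, 16.5)
    noise_sd: float = 0.3
    rate_hz: float = RATE_HZ

    def __post_init__(self) -> None:
        if self.fall_duration_mean <= 0 or self.fall_duration_sd <= 0:
            raise ValueError("fall duration parameters must be positive")
        if self.impact_peak <= GRAVITY:
            raise ValueError("impact_peak must exceed gravity magnitude")
        lo, hi = self.file_duration_range
        if not (0 < lo <= hi):
            raise ValueError("invalid file_duration_range")


@dataclass(frozen=True)
class AdlShapeParams:
    """Shape of a generated ADL file.

    ``movement_class`` is one of periodic / transitional / impulsive /
    quasi-static; ``fundamental_hz`` is capped at 20 Hz, the maximum
    frequency of human body movement.
    """

    movement_class: str = "periodic"
    fundamental_hz: float = 1.9
    amplitude: float = 4.0
    duration_range: tuple[float, float] = (8.0, 16.5)
    noise_sd: float = 0.3
    rate_hz: float = RATE_HZ

    def __post_init__(self) -> None:
        if self.movement_class not in (
            "periodic",
            "transitional",
            "impulsive",
            "quasi-static",
        ):
            raise ValueError(f"unknown movement class {self.movement_class!r}")
        if not (0 < self.fundamental_hz <= 20.0):
            raise ValueError("fundamental_hz must be in (0, 20] Hz")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


#: Per-code ADL profiles: (movement class, fundamental Hz, amplitude m/s^2).
#: Impulsive codes (hit table, clap) peak well above periodic ADLs, by design
#: close enough to fall impacts to be confusable.
ADL_PROFILES: dict[str, AdlShapeParams] = {
    "D01": AdlShapeParams("periodic", 1.9, 4.0),
    "D02": AdlShapeParams("periodic", 3.0, 7.0),
    "D03": AdlShapeParams("periodic", 1.7, 5.0),
    "D04": AdlShapeParams("transitional", 0.5, 3.0),
    "D05": AdlShapeParams("transitional", 0.5, 4.5),
    "D06": AdlShapeParams("transitional", 0.4, 3.5),
    "D07": AdlShapeParams("periodic", 1.9, 6.0),
    "D08": AdlShapeParams("impulsive", 0.8, 14.0),
    "D09": AdlShapeParams("impulsive", 1.5, 22.0),
    "D10": AdlShapeParams("impulsive", 2.5, 22.0),
    "D11": AdlShapeParams("quasi-static", 0.3, 1.0),
}

#: Context movement preceding the fall: walking for slips/trips while
#: walking (F01-F04), seated for the sitting falls (F05-F08).
_FALL_CONTEXT = {code: ("walking" if code <= "F04" else "sitting") for code in FALL_CODES}


def _smoothstep(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """C1 ramp from 0 at t0 to 1 at t1."""
    x = np.clip((t - t0) / max(t1 - t0, 1e-9), 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


def _tilt_quaternions(theta: np.ndarray, axis_azimuth: float) -> np.ndarray:
    """Scalar-first unit quaternions for a tilt of theta(t) about a fixed
    horizontal axis."""
    ux, uy = np.cos(axis_azimuth), np.sin(axis_azimuth)
    half = theta / 2.0
    q = np.empty((theta.size, 4))
    q[:, 0] = np.cos(half)
    s = np.sin(half)
    q[:, 1] = ux * s
    q[:, 2] = uy * s
    q[:, 3] = 0.0
    return q


def _gravity_body(q: np.ndarray) -> np.ndarray:
    """Body-frame gravity reaction (0,0,g rotated world->body)."""
    rot = Rotation.from_quat(q, scalar_first=True)
    g = np.tile([0.0, 0.0, GRAVITY], (q.shape[0], 1))
    return rot.apply(g, inverse=True)


def _spike_train(
    t: np.ndarray,
    centers: np.ndarray,
    amplitudes: np.ndarray,
    directions: np.ndarray,
    width_s: float = 0.03,
) -> np.ndarray:
    """Sum of short Gaussian-shaped spikes; shape (n, 3)."""
    out = np.zeros((t.size, 3))
    for tc, amp, d in zip(centers, amplitudes, directions):
        pulse = amp * np.exp(-(((t - tc) / width_s) ** 2))
        out += pulse[:, None] * d[None, :]
    return out


def _assemble(
    rec_id: tuple[str, str, str, int],
    t: np.ndarray,
    accel: np.ndarray,
    gyro: np.ndarray,
    quat: np.ndarray,
    rate_hz: float,
    actual_fall: tuple[float, float] | None,
) -> Recording:
    user, cohort, activity, trial = rec_id
    traces = {
        "accelerometer": SensorTrace("accelerometer", rate_hz, t, accel),
        "gyroscope": SensorTrace("gyroscope", rate_hz, t, gyro),
        "orientation": SensorTrace("orientation", rate_hz, t, quat),
    }
    return Recording(
        user_id=user,
        cohort=cohort,
        activity=activity,
        trial=trial,
        traces=traces,
        actual_fall=actual_fall,
    )


def _periodic_movement(
    t: np.ndarray, f: float, amp: float, rng: np.random.Generator
) -> np.ndarray:
    """Gait-like oscillation: dominant component at f, weak 2f harmonic."""
    phases = rng.uniform(0, 2 * np.pi, size=3)
    weights = amp * rng.uniform(0.6, 1.0, size=3)
    base = np.sin(2 * np.pi * f * t[:, None] + phases[None, :]) * weights[None, :]
    harm = 0.25 * weights[None, :] * np.sin(
        2 * np.pi * 2 * f * t[:, None] + phases[None, :] * 1.7
    )
    return base + harm


def generate_fall(
    code: str,
    params: FallShapeParams | None = None,
    seed: int = 0,
    *,
    user_id: str = "U00",
    cohort: str = "YP",
    trial: int = 1,
) -> Recording:
    """Generate one fall recording with its actual-fall interval.

    Timeline: context movement (walking or seated, per code) until the
    interval start, a free-fall dip in measured gravity up to the impact at
    the interval midpoint, an impact spike cluster near ``impact_peak``, a
    decaying adjustment oscillation, then lying still. Orientation tilts
    from upright to lying across the event.
    """
    if code not in FALL_CODES:
        raise ValueError(f"not a fall code: {code!r}")
    params = params or FallShapeParams()
    rng = np.random.default_rng(seed)
    f_hz = params.rate_hz

    lo, hi = params.file_duration_range
    duration = rng.uniform(lo, hi)
    n = int(round(duration * f_hz))
    t = np.arange(n) / f_hz

    d = rng.normal(params.fall_duration_mean, params.fall_duration_sd)
    d = max(d, params.fall_duration_min)
    a = rng.uniform(1.0, max(duration - d - 1.0, 1.0 + 1e-3))
    b = a + d
    tc = a + d / 2.0  # impact at interval midpoint

    # Orientation: upright (small base tilt) -> lying across [a, tc+0.3].
    azimuth = rng.uniform(0, 2 * np.pi)
    theta0 = 0.35 if _FALL_CONTEXT[code] == "sitting" else 0.1
    theta_lying = rng.uniform(0.85, 1.05) * (np.pi / 2)
    ramp = _smoothstep(t, a, tc + 0.3)
    theta = theta0 + (theta_lying - theta0) * ramp
    quat = _tilt_quaternions(theta, azimuth)
    g_body = _gravity_body(quat)

    # Free-fall onset: measured gravity reaction fades toward zero before
    # the impact, then recovers.
    ff = 1.0 - 0.85 * _smoothstep(t, a, max(tc - 0.15, a + 1e-3)) * (
        1.0 - _smoothstep(t, tc - 0.05, tc + 0.15)
    )
    accel = g_body * ff[:, None]

    # Context movement before the fall.
    if _FALL_CONTEXT[code] == "walking":
        walk = _periodic_movement(t, rng.uniform(1.7, 2.1), 3.5, rng)
        accel += walk * (1.0 - _smoothstep(t, a - 0.2, a))[:, None]

    # Impact spike cluster around tc.
    n_spikes = rng.integers(2, 5)
    centers = tc + rng.uniform(-0.08, 0.12, size=n_spikes)
    amps = params.impact_peak * rng.uniform(0.7, 1.0, size=n_spikes)
    amps[0] = params.impact_peak * rng.uniform(0.95, 1.05)
    dirs = rng.normal(size=(n_spikes, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    accel += _spike_train(t, centers, amps, dirs)

    # Adjustment: decaying oscillation after impact.
    adj_dur = max(0.3 * d, 0.4)
    adj_mask = (t >= tc) & (t <= tc + adj_dur)
    envelope = 8.0 * np.exp(-(t - tc) / (adj_dur / 2.0)) * adj_mask
    adj_dirs = rng.normal(size=3)
    adj_dirs /= np.linalg.norm(adj_dirs)
    accel += (envelope * np.sin(2 * np.pi * 11.0 * (t - tc)))[:, None] * adj_dirs[None, :]

    accel += rng.normal(0.0, params.noise_sd, size=accel.shape)

    # Gyroscope: rate of the tilt plus impact tumbling plus noise.
    dtheta = np.gradient(theta, 1.0 / f_hz)
    axis = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    gyro = dtheta[:, None] * axis[None, :]
    gyro += (envelope / 4.0)[:, None] * rng.normal(size=3)[None, :] * 0.5
    gyro += rng.normal(0.0, 0.05, size=gyro.shape)

    return _assemble(
        (user_id, cohort, code, trial), t, accel, gyro, quat, f_hz, (a, b)
    )


def generate_adl(
    code: str,
    params: AdlShapeParams | None = None,
    seed: int = 0,
    *,
    user_id: str = "U00",
    cohort: str = "YP",
    trial: int = 1,
) -> Recording:
    """Generate one ADL recording (no actual-fall interval)."""
    if code not in ADL_CODES:
        raise ValueError(f"not an ADL code: {code!r}")
    params = params or ADL_PROFILES[code]
    rng = np.random.default_rng(seed)
    f_hz = params.rate_hz

    lo, hi = params.duration_range
    duration = rng.uniform(lo, hi)
    n = int(round(duration * f_hz))
    t = np.arange(n) / f_hz

    azimuth = rng.uniform(0, 2 * np.pi)
    cls = params.movement_class
    if cls == "periodic":
        theta = 0.1 + 0.05 * np.sin(2 * np.pi * params.fundamental_hz * t)
        movement = _periodic_movement(t, params.fundamental_hz, params.amplitude, rng)
    elif cls == "transitional":
        # One posture change near mid-file with a moderate bump.
        t_mid = rng.uniform(0.3, 0.6) * duration
        theta = 0.15 + 0.5 * _smoothstep(t, t_mid - 1.0, t_mid + 1.0)
        bump = params.amplitude * np.exp(-(((t - t_mid) / 0.5) ** 2))
        dirs = rng.normal(size=3)
        dirs /= np.linalg.norm(dirs)
        movement = bump[:, None] * dirs[None, :]
    elif cls == "impulsive":
        # Repeated short spike clusters on a steady posture.
        theta = np.full(t.size, 0.2)
        period = 1.0 / params.fundamental_hz
        centers = np.arange(1.0, duration - 1.0, period)
        centers = centers + rng.uniform(-0.1, 0.1, size=centers.size)
        amps = params.amplitude * rng.uniform(0.7, 1.0, size=centers.size)
        dirs = rng.normal(size=(centers.size, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        movement = _spike_train(t, centers, amps, dirs)
    else:  # quasi-static
        theta = 0.15 + 0.03 * np.sin(2 * np.pi * params.fundamental_hz * t)
        movement = _periodic_movement(t, params.fundamental_hz, params.amplitude, rng)

    quat = _tilt_quaternions(theta, azimuth)
    accel = _gravity_body(quat) + movement
    accel += rng.normal(0.0, params.noise_sd, size=accel.shape)

    dtheta = np.gradient(theta, 1.0 / f_hz)
    axis = np.array([np.cos(azimuth), np.sin(azimuth), 0.0])
    gyro = dtheta[:, None] * axis[None, :]
    gyro += 0.1 * movement / max(params.amplitude, 1e-9)
    gyro += rng.normal(0.0, 0.05, size=gyro.shape)

    return _assemble((user_id, cohort, code, trial), t, accel, gyro, quat, f_hz, None)


def _user_jitter(seed: int, user_index: int, cohort: str) -> tuple[float, float]:
    """Per-user amplitude and frequency scaling so users differ more than
    repetitions. Elders move with lower amplitudes and frequencies."""
    ss = np.random.SeedSequence([seed, 1000 + user_index])
    rng = np.random.default_rng(ss)
    amp = rng.uniform(0.85, 1.15)
    freq = rng.uniform(0.92, 1.08)
    if cohort == "EP":
        amp *= 0.6
        freq *= 0.8
    return amp, freq


def generate_dataset(protocol: Protocol, seed: int = 0) -> list[Recording]:
    """One recording per scheduled (user, activity, repetition) trial.

    Per-user parameter jitter is applied on top of the per-code defaults so
    that between-user variation exceeds between-repetition variation.
    """
    users = {uid: i for i, (uid, _, _) in enumerate(protocol.participants)}
    out: list[Recording] = []
    for user_id, cohort, activity, trial in protocol.trials():
        uidx = users[user_id]
        amp_s, freq_s = _user_jitter(seed, uidx, cohort)
        act_idx = (FALL_CODES + ADL_CODES).index(activity)
        child = np.random.SeedSequence([seed, uidx, act_idx, trial])
        child_seed = int(child.generate_state(1)[0] % (2**31))
        if activity in FALL_CODES:
            params = FallShapeParams(impact_peak=FallShapeParams.impact_peak * amp_s)
            rec = generate_fall(
                activity, params, child_seed,
                user_id=user_id, cohort=cohort, trial=trial,
            )
        else:
            base = ADL_PROFILES[activity]
            params = replace(
                base,
                amplitude=base.amplitude * amp_s,
                fundamental_hz=min(base.fundamental_hz * freq_s, 20.0),
            )
            rec = generate_adl(
                activity, params, child_seed,
                user_id=user_id, cohort=cohort, trial=trial,
            )
        out.append(rec)
    return out
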