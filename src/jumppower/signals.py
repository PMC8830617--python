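"""Force-platform event detection, the criterion peak-power computation,
and padding/windowing of accelerometer series.

All VGRF series are vertical ground reaction force in newtons sampled at
1000 Hz; accelerometer series are in g at 250 Hz.  The criterion measure is
the maximum of instantaneous power (vertical velocity x VGRF) between jump
initiation and take-off, normalised to body mass (W/kg).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

G = 9.81  # gravitational acceleration, m/s^2

FS_FORCE = 1000  # force platform sampling rate, Hz
FS_ACCEL = 250   # accelerometer sampling rate, Hz

#: flight threshold on VGRF, N
FLIGHT_THRESHOLD_N = 10.0


class EventDetectionError(ValueError):
    """A jump event could not be found in the trace (non-jump trial)."""


@dataclass(frozen=True)
class JumpEvents:
    """Sample indices of the jump phases on the 1000 Hz force grid."""

    initiation: int
    takeoff: int
    landing: int

    @property
    def flight_time(self) -> float:
        return (self.landing - self.takeoff) / FS_FORCE

    def __post_init__(self):
        if not self.initiation < self.takeoff < self.landing:
            raise ValueError(
                f"event ordering violated: initiation={self.initiation}, "
                f"takeoff={self.takeoff}, landing={self.landing}"
            )


def detect_initiation(vgrf: np.ndarray, body_weight: float) -> int:
    """Locate the first sample of the countermovement.

    The jump is detected where |VGRF - BW| first exceeds 8% BW; the start of
    the movement is then taken as the first sample of the contiguous run of
    >1% BW deviation leading into that crossing (one past the latest earlier
    sample at or below 1% BW).
    """
    vgrf = np.asarray(vgrf, dtype=float)
    dev = np.abs(vgrf - body_weight)
    over8 = np.nonzero(dev > 0.08 * body_weight)[0]
    if over8.size == 0:
        raise EventDetectionError("VGRF never deviates by more than 8% BW")
    i8 = int(over8[0])
    under1 = np.nonzero(dev[: i8 + 1] <= 0.01 * body_weight)[0]
    if under1.size == 0:
        # deviation exceeds 1% BW from the very first sample
        return 0
    return int(under1[-1]) + 1


def detect_takeoff_landing(vgrf: np.ndarray) -> tuple[int, int, float]:
    """Take-off (first sample < 10 N), landing (first subsequent sample
    > 10 N) and flight time in seconds."""
    vgrf = np.asarray(vgrf, dtype=float)
    below = np.nonzero(vgrf < FLIGHT_THRESHOLD_N)[0]
    if below.size == 0:
        raise EventDetectionError("VGRF never drops below 10 N (no flight)")
    takeoff = int(below[0])
    above = np.nonzero(vgrf[takeoff:] > FLIGHT_THRESHOLD_N)[0]
    if above.size == 0:
        raise EventDetectionError("VGRF never rises above 10 N after take-off")
    landing = takeoff + int(above[0])
    return takeoff, landing, (landing - takeoff) / FS_FORCE


def detect_events(vgrf: np.ndarray, body_weight: float) -> JumpEvents:
    initiation = detect_initiation(vgrf, body_weight)
    takeoff, landing, _ = detect_takeoff_landing(vgrf)
    return JumpEvents(initiation, takeoff, landing)


def compute_criterion_peak_power(
    vgrf: np.ndarray,
    body_mass: float,
    body_weight: float | None = None,
    fs: int = FS_FORCE,
) -> float:
    """Criterion peak external power from the force platform, W/kg.

    Net force is integrated with the trapezoidal rule from jump initiation
    to give vertical velocity; instantaneous power is velocity x VGRF and
    the criterion is its maximum between initiation and take-off, divided
    by body mass.
    """
    if body_mass <= 0:
        raise ValueError("body_mass must be positive")
    vgrf = np.asarray(vgrf, dtype=float)
    bw = body_mass * G if body_weight is None else body_weight
    initiation = detect_initiation(vgrf, bw)
    takeoff, _, _ = detect_takeoff_landing(vgrf)
    seg = vgrf[initiation : takeoff + 1]
    accel = (seg - bw) / body_mass
    velocity = cumulative_trapezoid(accel, dx=1.0 / fs, initial=0.0)
    power = velocity * seg
    return float(np.max(power)) / body_mass


def pad_series(
    values: np.ndarray, target_length: int, pad_value: float, n_pre: int | None = None
) -> np.ndarray:
    """Pad a 1-d series to ``target_length`` with a constant value.

    ``n_pre`` samples are inserted at the start (split evenly by default)
    and the remainder at the end.
    """
    values = np.asarray(values, dtype=float)
    n_extra = target_length - values.shape[-1]
    if n_extra < 0:
        raise ValueError("target_length shorter than series")
    if n_pre is None:
        n_pre = n_extra // 2
    if not 0 <= n_pre <= n_extra:
        raise ValueError("n_pre outside [0, target_length - len(values)]")
    return np.pad(values, (n_pre, n_extra - n_pre), constant_values=pad_value)


def leadin_mean(accel: np.ndarray, fs: int = FS_ACCEL, duration: float = 0.5) -> np.ndarray:
    """Mean acceleration per channel over the first ``duration`` seconds of
    quiet standing — the pad value for accelerometer series."""
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    n = max(1, int(round(fs * duration)))
    return accel[:, :n].mean(axis=1)


def pad_trial(
    vgrf_normalised: np.ndarray,
    accel: np.ndarray,
    target_length_vgrf: int,
    n_pre_vgrf: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pad a body-weight-normalised VGRF series (with 1.0) and the matching
    accelerometer series (with its quiet-standing lead-in mean) to a common
    standard length.

    The accelerometer target length is scaled by the sampling-rate ratio.
    Returns the padded (vgrf, accel) pair; accel is returned 2-d
    (channels x samples).
    """
    vgrf_normalised = np.asarray(vgrf_normalised, dtype=float)
    accel2d = np.atleast_2d(np.asarray(accel, dtype=float))
    ratio = FS_ACCEL / FS_FORCE
    target_accel = int(round(target_length_vgrf * ratio))
    n_extra_v = target_length_vgrf - vgrf_normalised.size
    if n_extra_v < 0:
        raise ValueError("target_length shorter than series")
    if n_pre_vgrf is None:
        n_pre_vgrf = n_extra_v // 2
    padded_v = pad_series(vgrf_normalised, target_length_vgrf, 1.0, n_pre_vgrf)
    n_pre_a = int(round(n_pre_vgrf * ratio))
    means = leadin_mean(accel2d)
    n_extra_a = target_accel - accel2d.shape[1]
    if n_extra_a < 0:
        raise ValueError("accelerometer series longer than target")
    n_pre_a = min(n_pre_a, n_extra_a)
    padded_a = np.stack(
        [pad_series(ch, target_accel, m, n_pre_a) for ch, m in zip(accel2d, means)]
    )
    return padded_v, padded_a


def window_accel(
    accel: np.ndarray,
    takeoff_time: float,
    t_pre: float,
    t_post: float,
    fs: int = FS_ACCEL,
) -> np.ndarray:
    """Extract the half-open window [T - t_pre, T + t_post) around take-off.

    ``takeoff_time`` is the take-off time in seconds on the (padded) series'
    own time base, taken from the synchronised VGRF; it is mapped to the
    nearest accelerometer sample.  Window length is exactly
    round(fs * (t_pre + t_post)) samples.
    """
    accel = np.asarray(accel, dtype=float)
    n = accel.shape[-1]
    if t_pre + t_post <= 0:
        raise ValueError("window length must be positive")
    i_t = int(round(fs * takeoff_time))
    start = i_t - int(round(fs * t_pre))
    stop = i_t + int(round(fs * t_post))
    if start < 0 or stop > n:
        raise ValueError(
            f"window [{start}, {stop}) exceeds padded series of length {n}"
        )
    return accel[..., start:stop]


def resultant(accel: np.ndarray) -> np.ndarray:
    """Per-sample Euclidean norm of a triaxial series (channels x samples)."""
    accel = np.atleast_2d(np.asarray(accel, dtype=float))
    return np.sqrt(np.sum(accel**2, axis=0))
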