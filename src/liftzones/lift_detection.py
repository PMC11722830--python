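"""Rule-based detection of discrete lifting events.

A lift shows up as a sustained excursion of the forearm's sagittal
angular speed.  The detector smooths |d theta/dt| of the fused forearm
angle with a short centred moving average and applies hysteresis: an
event opens when the speed stays above ``omega_on`` for at least
``min_on`` seconds, its boundaries extend outward to where the speed
falls below ``omega_off``, events separated by less than ``min_off``
seconds of rest are merged, and events shorter than ``min_duration``
are dropped.  The result is deterministic for a fixed input and
parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensor_fusion import AngleSeries, ImuStream

__all__ = ["DetectionParams", "LiftEvent", "angular_speed", "detect_lifts"]


@dataclass(frozen=True)
class DetectionParams:
    """Hysteresis thresholds for the event detector.

    omega_on : rad/s -- speed that must be sustained to open an event.
    omega_off : rad/s -- speed below which an event closes.
    min_on : s -- minimum supra-``omega_on`` duration to open.
    min_off : s -- rest duration below ``omega_off`` separating events.
    min_duration : s -- events shorter than this are discarded.
    smooth_window : samples -- centred moving-average window (odd).
    """

    omega_on: float = 0.3
    omega_off: float = 0.1
    min_on: float = 0.3
    min_off: float = 0.4
    min_duration: float = 0.5
    smooth_window: int = 5

    def __post_init__(self) -> None:
        if not 0 <= self.omega_off <= self.omega_on:
            raise ValueError("need 0 <= omega_off <= omega_on")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be a positive odd integer")


@dataclass(frozen=True)
class LiftEvent:
    """One detected lift: [t_start, t_end] with the sample indices."""

    t_start: float
    t_end: float
    i_start: int
    i_end: int

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("event must have t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def angular_speed(angles: AngleSeries, window: int = 5) -> np.ndarray:
    """Smoothed |d theta/dt| (rad/s) of an angle series.

    Central differences via ``np.gradient`` followed by a centred
    moving average of ``window`` samples (edges use a shrunken window).
    """
    if len(angles) < 2:
        return np.zeros(len(angles))
    speed = np.abs(np.gradient(angles.theta, angles.t))
    if window <= 1:
        return speed
    kernel = np.ones(window) / window
    smoothed = np.convolve(speed, kernel, mode="same")
    # correct the shrunken support at the edges
    norm = np.convolve(np.ones_like(speed), kernel, mode="same")
    return smoothed / norm


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index pairs of True runs in a boolean mask."""
    if not mask.any():
        return []
    padded = np.diff(np.concatenate([[0], mask.astype(int), [0]]))
    starts = np.flatnonzero(padded == 1)
    stops = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), stops.tolist()))


def detect_lifts(
    forearm_angles: AngleSeries,
    forearm_stream: ImuStream | None = None,
    params: DetectionParams = DetectionParams(),
) -> list[LiftEvent]:
    """Find lifting events in a forearm angle series.

    ``forearm_stream``, when given, must share timestamps with the
    angle series (it is the provenance of the angles; a mismatch means
    the caller paired the wrong trial's files).

    Returns time-ordered, non-overlapping events.
    """
    if len(forearm_angles) == 0:
        raise ValueError("empty angle series")
    if forearm_stream is not None and (
        len(forearm_stream.t) != len(forearm_angles.t)
        or not np.allclose(forearm_stream.t, forearm_angles.t)
    ):
        raise ValueError("angle series and IMU stream timestamps do not match")

    t = forearm_angles.t
    speed = angular_speed(forearm_angles, params.smooth_window)

    # candidate cores: sustained supra-omega_on runs
    cores = [
        (a, b)
        for a, b in _runs(speed >= params.omega_on)
        if t[b] - t[a] >= params.min_on
    ]
    if not cores:
        return []

    # extend each core outward while the speed stays at/above omega_off
    above_off = speed >= params.omega_off
    extended = []
    for a, b in cores:
        while a > 0 and above_off[a - 1]:
            a -= 1
        n = len(t) - 1
        while b < n and above_off[b + 1]:
            b += 1
        extended.append((a, b))

    # merge events separated by less than min_off seconds of rest
    merged = [extended[0]]
    for a, b in extended[1:]:
        pa, pb = merged[-1]
        if a <= pb or t[a] - t[pb] < params.min_off:
            merged[-1] = (pa, max(pb, b))
        else:
            merged.append((a, b))

    return [
        LiftEvent(t_start=float(t[a]), t_end=float(t[b]), i_start=a, i_end=b)
        for a, b in merged
        if t[b] - t[a] >= params.min_duration
    ]
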