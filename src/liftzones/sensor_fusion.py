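"""Drift-corrected sagittal inclination angles from raw IMU streams.

Each body-worn sensor is mounted with its z axis along the segment's
long axis, x pointing anteriorly, and y medio-laterally (the sagittal
rotation axis).  A stationary sensor on a vertical segment therefore
reads accel = (0, 0, g); tilting the segment forward by theta gives
accel = g*(sin theta, 0, cos theta) and a positive y gyroscope rate.

Gyroscope integration alone drifts because of rate bias; the
accelerometer's gravity direction is drift-free but noisy during
motion.  A first-order complementary filter blends the two:

    theta[k] = alpha*(theta[k-1] + omega_y[k]*dt)
             + (1 - alpha)*atan2(a_x[k], a_z[k])

For a static sensor with constant gyro bias b the steady-state error is
alpha*b*dt/(1 - alpha), i.e. bounded, unlike pure integration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GRAVITY",
    "NOMINAL_DT",
    "ImuStream",
    "AngleSeries",
    "accel_inclination",
    "complementary_filter",
    "read_imu_csv",
    "write_imu_csv",
]

GRAVITY = 9.81  # m/s^2

#: Nominal sampling interval of the wearable sensors (25 Hz).
NOMINAL_DT = 0.04

#: Acceleration-magnitude window (m/s^2) inside which the gravity
#: direction is trusted.  Outside it (free-fall-like or impact) the
#: filter falls back to a gyro-only update for that step.
ACCEL_TRUST_MIN = 2.0
ACCEL_TRUST_MAX = 25.0

IMU_CSV_COLUMNS = ["t", "gx", "gy", "gz", "ax", "ay", "az"]


@dataclass
class ImuStream:
    """Raw gyro + accel time series for one body segment.

    Attributes
    ----------
    segment : str
        Segment label (forearm | upper_arm | back | thigh | calf).
    t : ndarray, shape (n,)
        Sample times in seconds, strictly increasing.
    gyro : ndarray, shape (n, 3)
        Angular rates in rad/s, device frame.
    accel : ndarray, shape (n, 3)
        Specific force in m/s^2, device frame (includes gravity).
    mounting_offset : float
        Fixed angle (rad) between the device longitudinal axis and the
        segment long axis; subtracted from the fused angle.
    """

    segment: str
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    mounting_offset: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float)
        n = self.t.shape[0]
        if n == 0:
            raise ValueError("empty IMU stream")
        if self.gyro.shape != (n, 3) or self.accel.shape != (n, 3):
            raise ValueError(
                f"gyro/accel shapes {self.gyro.shape}/{self.accel.shape} "
                f"do not match {n} timestamps x 3 axes"
            )
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.accel)) or not np.all(np.isfinite(self.gyro)):
            raise ValueError("non-finite IMU samples")

    def __len__(self) -> int:
        return len(self.t)

    def gap_mask(self, nominal_dt: float = NOMINAL_DT, tol: float = 0.5) -> np.ndarray:
        """Boolean mask of inter-sample gaps larger than (1+tol)*nominal_dt.

        Gaps are flagged, never silently interpolated.
        """
        return np.diff(self.t) > (1.0 + tol) * nominal_dt


@dataclass
class AngleSeries:
    """Sagittal inclination-from-vertical angle (rad) per time sample.

    Positive angles are forward (anterior) tilt; values are wrapped to
    [-pi, pi] and share timestamps with the source stream.
    """

    segment: str
    t: np.ndarray
    theta: np.ndarray
    trusted: np.ndarray = field(default=None)  # accel trusted at each step

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if self.t.shape != self.theta.shape:
            raise ValueError("t and theta must have the same shape")
        if self.trusted is None:
            self.trusted = np.ones(self.t.shape, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    def at(self, time: float) -> float:
        """Angle at the sample nearest to ``time``."""
        return float(self.theta[int(np.argmin(np.abs(self.t - time)))])


def _wrap(angle):
    """Wrap angle(s) to (-pi, pi]."""
    return -((-np.asarray(angle) + np.pi) % (2.0 * np.pi) - np.pi)


def accel_inclination(accel) -> float:
    """Signed sagittal inclination from a single accelerometer reading.

    ``accel`` is a 3-vector (ax, ay, az) in the device frame.  Returns
    atan2(ax, az): 0 for a vertical longitudinal axis, +pi/2 for a
    horizontal, forward-pointing one.  Raises ``ValueError`` when the
    magnitude is too small for the gravity direction to be meaningful.
    """
    ax, _, az = np.asarray(accel, dtype=float)
    if math.hypot(ax, az) < 1e-9:
        raise ValueError("acceleration magnitude too small to define inclination")
    return math.atan2(ax, az)


def complementary_filter(
    stream: ImuStream,
    alpha: float = 0.98,
    accel_min: float = ACCEL_TRUST_MIN,
    accel_max: float = ACCEL_TRUST_MAX,
) -> AngleSeries:
    """Fuse one segment's gyro and accel into an inclination series.

    Parameters
    ----------
    stream : ImuStream
        Raw samples; timestamps strictly increasing.
    alpha : float in [0, 1]
        Gyro weight.  ``alpha=0`` reproduces the accelerometer
        inclination pointwise; ``alpha=1`` is pure gyro integration.

    Returns
    -------
    AngleSeries
        Same timestamps as the stream.  ``trusted`` marks steps where
        the accelerometer magnitude was inside the trust window; on
        untrusted steps the update is gyro-only (the previous estimate
        is carried forward by integration).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    t = stream.t
    omega = stream.gyro[:, 1]  # sagittal rate about the device y axis
    ax = stream.accel[:, 0]
    az = stream.accel[:, 2]
    mag = np.linalg.norm(stream.accel, axis=1)
    trusted = (mag >= accel_min) & (mag <= accel_max)
    incl = np.arctan2(ax, az)

    n = len(t)
    theta = np.empty(n)
    theta[0] = incl[0] if trusted[0] else 0.0
    for k in range(1, n):
        dt = t[k] - t[k - 1]
        predicted = theta[k - 1] + omega[k] * dt
        if trusted[k]:
            theta[k] = alpha * predicted + (1.0 - alpha) * incl[k]
        else:
            theta[k] = predicted
        theta[k] = _wrap(theta[k])
    theta = _wrap(theta - stream.mounting_offset)
    return AngleSeries(segment=stream.segment, t=t, theta=theta, trusted=trusted)


def write_imu_csv(stream: ImuStream, path: str | Path, sidecar: bool = True) -> None:
    """Write a stream in the package CSV dialect (t,gx,gy,gz,ax,ay,az).

    A sidecar ``<name>.json`` records the segment label and mounting
    offset so the file is self-describing.
    """
    path = Path(path)
    df = pd.DataFrame(
        np.column_stack([stream.t, stream.gyro, stream.accel]),
        columns=IMU_CSV_COLUMNS,
    )
    df.to_csv(path, index=False, float_format="%.9g")
    if sidecar:
        meta = {"segment": stream.segment, "mounting_offset": stream.mounting_offset}
        path.with_suffix(".json").write_text(json.dumps(meta))


def read_imu_csv(path: str | Path, segment: str | None = None) -> ImuStream:
    """Read a stream written by :func:`write_imu_csv`.

    The segment label and mounting offset come from the sidecar JSON if
    present; ``segment`` overrides or supplies the label.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in IMU_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing IMU columns {missing}")
    offset = 0.0
    label = segment
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        offset = float(meta.get("mounting_offset", 0.0))
        label = label or meta.get("segment")
    return ImuStream(
        segment=label or path.stem,
        t=df["t"].to_numpy(),
        gyro=df[["gx", "gy", "gz"]].to_numpy(),
        accel=df[["ax", "ay", "az"]].to_numpy(),
        mounting_offset=offset,
    )
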