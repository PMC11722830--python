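import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from liftzones import ImuStream, SegmentLengths
from liftzones.sensor_fusion import GRAVITY, NOMINAL_DT

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("default")


@pytest.fixture
def example_lengths() -> SegmentLengths:
    """The worked-example chain: FA 0.25, UA 0.30, back 0.50, thigh 0.45,
    calf 0.43 m."""
    return SegmentLengths(forearm=0.25, upper_arm=0.30, back=0.50, thigh=0.45, calf=0.43)


def make_stream(
    theta: np.ndarray,
    dt: float = NOMINAL_DT,
    gyro_y: np.ndarray | None = None,
    segment: str = "forearm",
    t0: float = 0.0,
) -> ImuStream:
    """Build a stream whose accel encodes the given inclination series and
    whose sagittal gyro is either supplied or the finite-difference rate."""
    theta = np.asarray(theta, dtype=float)
    n = len(theta)
    t = t0 + np.arange(n) * dt
    if gyro_y is None:
        gyro_y = np.gradient(theta, t) if n > 1 else np.zeros(n)
    gyro = np.zeros((n, 3))
    gyro[:, 1] = gyro_y
    accel = np.zeros((n, 3))
    accel[:, 0] = GRAVITY * np.sin(theta)
    accel[:, 2] = GRAVITY * np.cos(theta)
    return ImuStream(segment=segment, t=t, gyro=gyro, accel=accel)
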