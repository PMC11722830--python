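"""Planar forward kinematics of the five-link lifting chain.

The body is modelled in the sagittal plane as calf -> thigh -> back ->
upper arm -> forearm, with the calf held vertical (its angle is not
sensed and contributes its full length to V and nothing to H).  All
angles are inclinations from the gravity vertical, positive forward;
the arms hang downward from the shoulder, so their cosine terms are
subtracted from the stack of leg/trunk heights:

    V = L_back*cos(th_back) + L_thigh*cos(th_thigh) + L_calf
        - L_ua*cos(th_ua) - L_fa*cos(th_fa)
    H = L_ua*sin(th_ua) + L_fa*sin(th_fa)
        + L_back*sin(th_back) - L_thigh*sin(th_thigh)

V is the hand height above the ground and H the horizontal distance
from the ankles to the hands -- the two inputs the ACGIH TLV lifting
zones bin.  The thigh sine term is subtracted because a forward knee
displaces the hip (and everything above it) backward relative to the
ankles.  Postures with the hands above the shoulder need arm angles
beyond pi/2 in magnitude; they are allowed, not clamped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

from .anthropometry import SegmentLengths

__all__ = ["PostureAngles", "HandLocation", "estimate_v", "estimate_h", "hand_location"]


@dataclass(frozen=True)
class PostureAngles:
    """Sagittal inclination-from-vertical angles (rad) at one instant."""

    forearm: float
    upper_arm: float
    back: float
    thigh: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not (-math.pi <= value <= math.pi) or math.isnan(value):
                raise ValueError(f"angle '{f.name}'={value!r} outside [-pi, pi]")


@dataclass(frozen=True)
class HandLocation:
    """Hand-centre location: V = height above ground, H = distance from
    the ankle centre, both in metres.

    Values outside the plausible lifting envelope (negative H, V above
    head) are representable here; zoning flags them downstream.
    """

    v: float
    h: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.v) and math.isfinite(self.h)):
            raise ValueError("hand location must be finite")


def estimate_v(angles: PostureAngles, lengths: SegmentLengths) -> float:
    """Vertical hand height V (m) from posture angles and segment lengths."""
    return (
        lengths.back * math.cos(angles.back)
        + lengths.thigh * math.cos(angles.thigh)
        + lengths.calf
        - lengths.upper_arm * math.cos(angles.upper_arm)
        - lengths.forearm * math.cos(angles.forearm)
    )


def estimate_h(angles: PostureAngles, lengths: SegmentLengths) -> float:
    """Horizontal ankle-to-hand distance H (m)."""
    return (
        lengths.upper_arm * math.sin(angles.upper_arm)
        + lengths.forearm * math.sin(angles.forearm)
        + lengths.back * math.sin(angles.back)
        - lengths.thigh * math.sin(angles.thigh)
    )


def hand_location(angles: PostureAngles, lengths: SegmentLengths) -> HandLocation:
    """Bundle :func:`estimate_v` and :func:`estimate_h` into one location."""
    return HandLocation(v=estimate_v(angles, lengths), h=estimate_h(angles, lengths))
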