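"""ACGIH TLV lifting zones: 4 vertical x 3 horizontal bands and risk groups.

The TLV for lifting bins the hand location at the lift origin into a
4x3 grid.  Vertical bands, numbered from the top: V1 1.45-1.70 m
(shoulder height), V2 1.00-1.45 m, V3 0.50-1.00 m, V4 0-0.50 m.
Horizontal bands, numbered from the body: H1 0-0.25 m, H2 0.25-0.457 m,
H3 0.457-0.712 m.  Zones are numbered row-major from the top-near cell,
zone = 3*(v_band-1) + h_band, and grouped into three practical risk
levels (low/medium/high).

Intervals are lower-closed and upper-open, with the top band of each
axis closed at its upper edge; the printed ranges share endpoints, so a
deterministic histogram convention is imposed.  Locations outside the
grid are clamped to the nearest band with an explicit out-of-range
flag, because estimated hand locations routinely land outside the true
envelope and must still be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZoneBoundaries",
    "DEFAULT_BOUNDARIES",
    "Zone",
    "RISK_LEVELS",
    "DEFAULT_GROUPING",
    "LOS_ALAMOS_GROUPING",
    "classify_v",
    "classify_h",
    "zone_from_vh",
    "group_from_zone",
]

RISK_LEVELS = ("low", "medium", "high")

#: Default grouping of the 12 zones into risk levels.
DEFAULT_GROUPING: dict[int, str] = {
    **{z: "low" for z in (4, 5)},
    **{z: "medium" for z in (6, 7, 8, 9)},
    **{z: "high" for z in (1, 2, 3, 10, 11, 12)},
}

#: The original Los Alamos National Laboratory simplification (zone 4
#: only low; 1, 5, 7, 8, 10 medium), kept as a named alternative.
LOS_ALAMOS_GROUPING: dict[int, str] = {
    4: "low",
    **{z: "medium" for z in (1, 5, 7, 8, 10)},
    **{z: "high" for z in (2, 3, 6, 9, 11, 12)},
}


@dataclass(frozen=True)
class ZoneBoundaries:
    """Band edges (m), ascending.  ``v_edges`` has 5 entries (4 bands),
    ``h_edges`` 4 entries (3 bands).  Configurable to support
    subject-height-scaled zones; defaults are the standard ranges."""

    v_edges: tuple[float, ...] = (0.0, 0.5, 1.0, 1.45, 1.70)
    h_edges: tuple[float, ...] = (0.0, 0.25, 0.457, 0.712)

    def __post_init__(self) -> None:
        for name, edges, n in (("v_edges", self.v_edges, 5), ("h_edges", self.h_edges, 4)):
            if len(edges) != n:
                raise ValueError(f"{name} must have {n} entries")
            if edges[0] < 0 or any(b <= a for a, b in zip(edges, edges[1:])):
                raise ValueError(f"{name} must be non-negative and strictly ascending")


DEFAULT_BOUNDARIES = ZoneBoundaries()


@dataclass(frozen=True)
class Zone:
    """One of the 12 lifting zones.  ``index = 3*(v_band-1) + h_band``;
    ``out_of_range`` marks a location clamped into the grid."""

    v_band: int
    h_band: int
    out_of_range: bool = False

    def __post_init__(self) -> None:
        if self.v_band not in (1, 2, 3, 4) or self.h_band not in (1, 2, 3):
            raise ValueError(f"invalid bands V{self.v_band}/H{self.h_band}")

    @property
    def index(self) -> int:
        return 3 * (self.v_band - 1) + self.h_band

    @classmethod
    def from_index(cls, index: int, out_of_range: bool = False) -> "Zone":
        if not 1 <= index <= 12:
            raise ValueError(f"zone index must be 1-12, got {index}")
        return cls(v_band=(index - 1) // 3 + 1, h_band=(index - 1) % 3 + 1,
                   out_of_range=out_of_range)


def _band(value: float, edges: tuple[float, ...], axis: str) -> tuple[int, bool]:
    """0-based band from the bottom edge; lower-closed/upper-open, top
    band closed; out-of-range values clamp to the nearest band."""
    if math.isnan(value):
        raise ValueError(f"{axis} is NaN")
    if value < edges[0]:
        return 0, True
    if value > edges[-1]:
        return len(edges) - 2, True
    if value == edges[-1]:
        return len(edges) - 2, False
    return int(np.searchsorted(edges, value, side="right")) - 1, False


def classify_v(v: float, boundaries: ZoneBoundaries = DEFAULT_BOUNDARIES) -> tuple[int, bool]:
    """Vertical band 1-4 (1 = top) and an out-of-range flag."""
    i, oor = _band(v, boundaries.v_edges, "V")
    return 4 - i, oor


def classify_h(h: float, boundaries: ZoneBoundaries = DEFAULT_BOUNDARIES) -> tuple[int, bool]:
    """Horizontal band 1-3 (1 = nearest the body) and out-of-range flag."""
    i, oor = _band(h, boundaries.h_edges, "H")
    return i + 1, oor


def zone_from_vh(v: float, h: float,
                 boundaries: ZoneBoundaries = DEFAULT_BOUNDARIES) -> Zone:
    """Bin a hand location into its lifting zone."""
    v_band, v_oor = classify_v(v, boundaries)
    h_band, h_oor = classify_h(h, boundaries)
    return Zone(v_band=v_band, h_band=h_band, out_of_range=v_oor or h_oor)


def group_from_zone(zone: Zone | int, grouping: dict[int, str] = DEFAULT_GROUPING) -> str:
    """Risk level ('low' | 'medium' | 'high') for a zone."""
    index = zone.index if isinstance(zone, Zone) else int(zone)
    if not 1 <= index <= 12:
        raise ValueError(f"zone index must be 1-12, got {index}")
    return grouping[index]
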