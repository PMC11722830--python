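"""Body-segment lengths for the planar five-link lifting model.

Hand-location estimation uses a sagittal-plane chain of five segments:
forearm, upper arm, back (hip to shoulder), thigh, and calf (ankle to
knee).  Segment lengths come either from direct measurement of each
segment (the "ratio + length" model) or from a single forearm
measurement scaled by population segment-to-forearm ratios (the
"ratio" model, which minimizes field setup).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

__all__ = [
    "SEGMENTS",
    "MAX_SEGMENT_LENGTH",
    "SegmentLengths",
    "SegmentRatios",
    "DEFAULT_RATIOS",
    "segments_from_forearm",
    "segments_from_measurements",
    "load_anthropometry",
]

#: Segment names, proximal order of the planar chain types.
SEGMENTS = ("forearm", "upper_arm", "back", "thigh", "calf")

#: Sanity bound (m).  No adult body segment approaches 1.5 m; values above
#: it almost always mean centimetres were passed where metres were expected.
MAX_SEGMENT_LENGTH = 1.5


@dataclass(frozen=True)
class SegmentLengths:
    """Lengths (m) of the five links of the sagittal lifting chain."""

    forearm: float
    upper_arm: float
    back: float
    thigh: float
    calf: float

    def __post_init__(self) -> None:
        for f in fields(self):
            value = getattr(self, f.name)
            if not (0.0 < value < MAX_SEGMENT_LENGTH):
                raise ValueError(
                    f"segment '{f.name}' length {value!r} m outside "
                    f"(0, {MAX_SEGMENT_LENGTH}) m"
                )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class SegmentRatios:
    """Segment length divided by forearm length, per segment.

    The forearm ratio is 1 by definition; the remaining entries let a
    single forearm measurement stand in for the whole chain.
    """

    forearm: float = 1.0
    upper_arm: float = 1.27
    back: float = 1.99
    thigh: float = 1.68
    calf: float = 1.69

    def __post_init__(self) -> None:
        if self.forearm != 1.0:
            raise ValueError("forearm ratio must be exactly 1.0")
        for f in fields(self):
            if getattr(self, f.name) <= 0.0:
                raise ValueError(f"ratio '{f.name}' must be strictly positive")

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


#: Default population ratios, derived from the Drillis–Contini stature
#: proportions (forearm 0.146·stature, upper arm 0.186, trunk 0.288,
#: thigh 0.245, calf 0.246) re-expressed relative to the forearm.
DEFAULT_RATIOS = SegmentRatios()


def segments_from_forearm(
    forearm_length: float, ratios: SegmentRatios = DEFAULT_RATIOS
) -> SegmentLengths:
    """Scale a single forearm measurement into full segment lengths.

    Parameters
    ----------
    forearm_length : float
        Measured forearm length in metres; must be strictly positive.
    ratios : SegmentRatios
        Population segment-to-forearm ratios.

    Returns
    -------
    SegmentLengths
        ``segment = forearm_length * ratio`` for every segment; the
        forearm entry equals the input exactly.
    """
    if not forearm_length > 0.0:
        raise ValueError(f"forearm length must be positive, got {forearm_length!r}")
    return SegmentLengths(
        forearm=forearm_length,
        upper_arm=forearm_length * ratios.upper_arm,
        back=forearm_length * ratios.back,
        thigh=forearm_length * ratios.thigh,
        calf=forearm_length * ratios.calf,
    )


def segments_from_measurements(
    forearm: float, upper_arm: float, back: float, thigh: float, calf: float
) -> SegmentLengths:
    """Build segment lengths from five direct measurements (m).

    Values pass through bit-exactly; non-positive or absurd (> 1.5 m)
    values raise ``ValueError``.
    """
    return SegmentLengths(
        forearm=forearm, upper_arm=upper_arm, back=back, thigh=thigh, calf=calf
    )


def load_anthropometry(path: str | Path) -> SegmentLengths:
    """Load segment lengths from a JSON or YAML config.

    Two schemas are accepted: five explicit lengths
    (``{"forearm": .., "upper_arm": .., ...}``, metres) or a forearm
    measurement plus optional ratio table
    (``{"forearm": .., "ratios": {...}}``).
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    if "ratios" in data or set(data) == {"forearm"}:
        ratios = SegmentRatios(**data.get("ratios", {})) if "ratios" in data else DEFAULT_RATIOS
        return segments_from_forearm(float(data["forearm"]), ratios)
    missing = set(SEGMENTS) - set(data)
    if missing:
        raise ValueError(f"{path}: missing segment lengths {sorted(missing)}")
    return segments_from_measurements(*(float(data[s]) for s in SEGMENTS))
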