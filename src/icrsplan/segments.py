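"""KeraRing-style intracorneal ring segment catalog.

Two families by tunnel diameter: SI5 (5 mm) with arcs 90/120/160/210 and
SI6 (6 mm) with arcs 90/120/150/210 degrees.  A segment's angular position
is given by its bisecting line: the meridian through the midpoint of the
arc, in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "SegmentSpec",
    "SEGMENT_MODELS",
    "SEGMENT_ARCS",
    "SEGMENT_CATALOG",
    "DEFAULT_THICKNESSES_UM",
]

SEGMENT_MODELS = ("SI5", "SI6")
SEGMENT_ARCS = {"SI5": (90, 120, 160, 210), "SI6": (90, 120, 150, 210)}
#: (model, arc) pairs in catalog order — the eight simulated segment types.
SEGMENT_CATALOG = tuple(
    (model, arc) for model in SEGMENT_MODELS for arc in SEGMENT_ARCS[model]
)
#: manufacturer-typical thickness range, μm (configurable everywhere).
DEFAULT_THICKNESSES_UM = (150, 200, 250, 300, 350)

#: ring tunnel radius in mm per family (diameter / 2).
TRACK_RADIUS_MM = {"SI5": 2.5, "SI6": 3.0}


@dataclass(frozen=True)
class SegmentSpec:
    """One arc segment: family, arc length, thickness and bisecting line."""

    model: str
    arc_deg: int
    thickness_um: float
    bisecting_line_deg: float

    def __post_init__(self) -> None:
        if self.model not in SEGMENT_MODELS:
            raise ValueError(f"unknown segment model {self.model!r}")
        if self.arc_deg not in SEGMENT_ARCS[self.model]:
            raise ValueError(
                f"arc {self.arc_deg}° is not in the {self.model} family "
                f"{SEGMENT_ARCS[self.model]}"
            )
        if self.thickness_um < 0:
            raise ValueError("thickness_um must be non-negative")
        object.__setattr__(
            self, "bisecting_line_deg", float(self.bisecting_line_deg) % 360.0
        )

    @property
    def track_radius_mm(self) -> float:
        return TRACK_RADIUS_MM[self.model]

    def sort_key(self) -> tuple:
        return (self.model, self.arc_deg, self.thickness_um, self.bisecting_line_deg)

    def label(self) -> str:
        return (
            f"{self.model}-{self.arc_deg}/{self.thickness_um:g}um"
            f"@{self.bisecting_line_deg:g}deg"
        )


def arcs_overlap(a: SegmentSpec, b: SegmentSpec) -> bool:
    """True when the two arcs overlap angularly on the ring circle."""
    d = abs(a.bisecting_line_deg - b.bisecting_line_deg)
    d = min(d, 360.0 - d)
    return d < (a.arc_deg + b.arc_deg) / 2.0
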