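"""Geometry of the artificial aorta.

The vessel is a 1:1 replica of the human central aorta: an aortic arch
(constant 28 mm inner diameter, modelled as a half circle of 50 mm radius of
curvature), an abdominal aorta tapering linearly from 26 to 16 mm over
512 mm, and a femoral branch (14 mm) after the aortic bifurcation, for a
total path length of 743 mm with a 2 mm wall throughout.  The path
coordinate ``s`` is arc length from the aortic root (valve outlet); the two
iliac branches are symmetric, so a single branch is followed through the
bifurcation and the terminal load represents their parallel combination.

Pressure sensors are evenly distributed every 100 mm along the path; the
named aortic-arch (AA) and aortic-bifurcation (AB) sensors used for transit
time measurements are 551 mm apart.

Three lengths that are easy to conflate are kept as distinct constants:
the 743 mm total path, the 712 mm "aortic length" quoted for the transit
time error budget, and the 551 mm AA-AB sensor distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

# Distinct published lengths -- never interchangeable.
TOTAL_LENGTH_M = 0.743
PTT_REFERENCE_LENGTH_M = 0.712
SENSOR_DISTANCE_AA_AB_M = 0.551

ARCH_RADIUS_M = 0.050
ARCH_LENGTH_M = math.pi * ARCH_RADIUS_M  # half-circle arch
ABDOMINAL_LENGTH_M = 0.512
WALL_THICKNESS_M = 0.002
BIFURCATION_ANGLE_DEG = 80.0

AA_SENSOR_POSITION_M = 0.100
AB_SENSOR_POSITION_M = AA_SENSOR_POSITION_M + SENSOR_DISTANCE_AA_AB_M


@dataclass(frozen=True)
class VesselSegment:
    """A straight or curved vessel run with linearly tapering diameter."""

    name: str
    length: float
    diameter_proximal: float
    diameter_distal: float
    wall_thickness: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"segment {self.name!r}: length must be > 0")
        if self.diameter_proximal <= 0 or self.diameter_distal <= 0:
            raise ValueError(f"segment {self.name!r}: diameters must be > 0")
        if self.wall_thickness <= 0:
            raise ValueError(f"segment {self.name!r}: wall thickness must be > 0")

    def diameter_at(self, x: float) -> float:
        """Diameter at local coordinate x in [0, length] (linear taper)."""
        if not 0.0 <= x <= self.length + 1e-12:
            raise ValueError(f"local coordinate {x} outside segment {self.name!r}")
        frac = min(x / self.length, 1.0)
        return self.diameter_proximal + frac * (self.diameter_distal - self.diameter_proximal)


@dataclass(frozen=True)
class AortaGeometry:
    """Ordered tube network plus sensor layout, addressed by path coordinate."""

    segments: tuple[VesselSegment, ...]
    bifurcation_angle_deg: float
    sensor_positions: tuple[float, ...]
    aa_position: float
    ab_position: float
    reflection_position: float = field(default=0.0)

    def __post_init__(self) -> None:
        total = self.total_length
        for s in (*self.sensor_positions, self.aa_position, self.ab_position):
            if not 0.0 <= s <= total + 1e-12:
                raise ValueError(f"sensor position {s} outside [0, {total}]")
        if not 0.0 < self.reflection_position <= total:
            raise ValueError("reflection site must lie on the path")

    @property
    def total_length(self) -> float:
        return sum(seg.length for seg in self.segments)

    @property
    def sensor_distance_aa_ab(self) -> float:
        return self.ab_position - self.aa_position

    @property
    def wall_thickness(self) -> float:
        return self.segments[0].wall_thickness

    def to_dict(self) -> dict:
        """Serializable form; lengths in millimetres, as in config files."""
        return {
            "segments": [
                {
                    "name": seg.name,
                    "length_mm": seg.length * 1e3,
                    "diameter_proximal_mm": seg.diameter_proximal * 1e3,
                    "diameter_distal_mm": seg.diameter_distal * 1e3,
                    "wall_thickness_mm": seg.wall_thickness * 1e3,
                }
                for seg in self.segments
            ],
            "bifurcation_angle_deg": self.bifurcation_angle_deg,
            "sensor_positions_mm": [s * 1e3 for s in self.sensor_positions],
            "aa_position_mm": self.aa_position * 1e3,
            "ab_position_mm": self.ab_position * 1e3,
            "reflection_position_mm": self.reflection_position * 1e3,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AortaGeometry":
        return cls(
            segments=tuple(
                VesselSegment(
                    name=sd["name"],
                    length=sd["length_mm"] / 1e3,
                    diameter_proximal=sd["diameter_proximal_mm"] / 1e3,
                    diameter_distal=sd["diameter_distal_mm"] / 1e3,
                    wall_thickness=sd["wall_thickness_mm"] / 1e3,
                )
                for sd in d["segments"]
            ),
            bifurcation_angle_deg=d["bifurcation_angle_deg"],
            sensor_positions=tuple(s / 1e3 for s in d["sensor_positions_mm"]),
            aa_position=d["aa_position_mm"] / 1e3,
            ab_position=d["ab_position_mm"] / 1e3,
            reflection_position=d["reflection_position_mm"] / 1e3,
        )


def build_standard_aorta() -> AortaGeometry:
    """The published 743 mm artificial aorta with the default sensor layout."""
    arch = VesselSegment("aortic_arch", ARCH_LENGTH_M, 0.028, 0.028, WALL_THICKNESS_M)
    abdominal = VesselSegment("abdominal_aorta", ABDOMINAL_LENGTH_M, 0.026, 0.016, WALL_THICKNESS_M)
    femoral_length = TOTAL_LENGTH_M - ARCH_LENGTH_M - ABDOMINAL_LENGTH_M
    femoral = VesselSegment("femoral_branch", femoral_length, 0.014, 0.014, WALL_THICKNESS_M)
    sensors = tuple(round(0.1 * k, 6) for k in range(8))  # 0 .. 700 mm every 100 mm
    return AortaGeometry(
        segments=(arch, abdominal, femoral),
        bifurcation_angle_deg=BIFURCATION_ANGLE_DEG,
        sensor_positions=sensors,
        aa_position=AA_SENSOR_POSITION_M,
        ab_position=AB_SENSOR_POSITION_M,
        reflection_position=ARCH_LENGTH_M + ABDOMINAL_LENGTH_M,
    )


def diameter_at(geometry: AortaGeometry, s: float) -> float:
    """Inner diameter at path coordinate s (piecewise linear within segments)."""
    if not 0.0 <= s <= geometry.total_length + 1e-12:
        raise ValueError(f"path coordinate {s} outside [0, {geometry.total_length}]")
    x = s
    for seg in geometry.segments:
        if x <= seg.length or seg is geometry.segments[-1]:
            return seg.diameter_at(min(x, seg.length))
        x -= seg.length
    raise AssertionError("unreachable")


def effective_diameter(geometry: AortaGeometry, s0: float, s1: float) -> float:
    """Length-weighted mean diameter over the path interval [s0, s1].

    Exact for the piecewise-linear taper (trapezoid rule per sub-segment).
    """
    if not 0.0 <= s0 < s1 <= geometry.total_length + 1e-12:
        raise ValueError(f"need 0 <= s0 < s1 <= total length, got [{s0}, {s1}]")
    acc = 0.0
    start = 0.0
    for seg in geometry.segments:
        end = start + seg.length
        lo, hi = max(s0, start), min(s1, end)
        if hi > lo:
            d_lo = seg.diameter_at(lo - start)
            d_hi = seg.diameter_at(hi - start)
            acc += 0.5 * (d_lo + d_hi) * (hi - lo)
        start = end
    return acc / (s1 - s0)
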