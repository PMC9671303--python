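"""Parametric bilateral nasal-airway geometry.

The airway is represented as a network of tapered duct segments grouped into
three anatomical regions per the usual nasal-CFD decomposition:

* ``AREA1_VESTIBULE`` — the anterior vestibule and nasal valve, lined by
  squamous epithelium and therefore treated as a *dry* wall (no latent
  exchange);
* ``AREA2_CAVITY`` — the turbinate-bearing nasal cavity from the valve to the
  choana, a *wet* mucosal wall;
* ``AREA3_NASOPHARYNX`` — the shared passage downstream of the choanae.

Each side runs nostril → choana (vestibule segments strictly before cavity
segments); the two sides merge at the choanae into a shared nasopharyngeal
path.  Plane-1 stations sit at the choanal end of each side and Plane-2
immediately downstream of the merge; in this reduced-order model they are
bookkeeping stations, not geometric cuts, so "immediately before/after the
choanae" is exact by construction.

All quantities are SI internally (m, m²); the reporting layer converts to
clinical units.  Cross-sections taper linearly in area and perimeter along a
segment, which keeps every derived integral closed-form testable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

from .errors import DomainError, InvalidGeometryError

__all__ = [
    "Region",
    "CrossSection",
    "Side",
    "SubjectState",
    "AirwaySegment",
    "SegmentGeometry",
    "BilateralAirwayModel",
    "derive_segment_geometry",
    "validate_airway",
    "region_surface_areas",
    "segment_surface_area",
    "slit_gap_and_width",
    "make_circular_segment",
    "make_slit_segment",
    "scale_slit_gap",
    "default_template",
    "TEMPLATE_DEFAULTS",
]


class Region(Enum):
    AREA1_VESTIBULE = "AREA1_VESTIBULE"
    AREA2_CAVITY = "AREA2_CAVITY"
    AREA3_NASOPHARYNX = "AREA3_NASOPHARYNX"


class CrossSection(Enum):
    """Selects the laminar friction and Nusselt constants for a segment."""

    CIRCULAR = "CIRCULAR"
    SLIT = "SLIT"


class Side(Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"

    @property
    def other(self) -> "Side":
        return Side.RIGHT if self is Side.LEFT else Side.LEFT


class SubjectState(Enum):
    PREOP = "PREOP"
    POSTOP = "POSTOP"


# Tolerance for the isoperimetric inequality P^2 >= 4*pi*A: a circle attains
# equality, so a strict check would reject circular segments to rounding.
_ISOPERIMETRIC_RTOL = 1e-9


@dataclass(frozen=True)
class AirwaySegment:
    """One tapered duct segment.

    ``area_in``/``area_out`` and ``perimeter_in``/``perimeter_out`` are the
    cross-sectional area (m²) and wetted perimeter (m) at the upstream and
    downstream ends; both interpolate linearly in between.
    """

    label: str
    region: Region
    length: float
    area_in: float
    area_out: float
    perimeter_in: float
    perimeter_out: float
    cross_section_kind: CrossSection = CrossSection.CIRCULAR
    wall_is_wet: bool = True

    def violations(self) -> list[str]:
        """Structural problems with this segment; empty when valid."""
        out: list[str] = []
        if not (self.length > 0.0 and math.isfinite(self.length)):
            out.append(f"segment {self.label!r}: length must be positive")
        for name, val in (
            ("area_in", self.area_in),
            ("area_out", self.area_out),
            ("perimeter_in", self.perimeter_in),
            ("perimeter_out", self.perimeter_out),
        ):
            if not (val > 0.0 and math.isfinite(val)):
                out.append(f"segment {self.label!r}: {name} must be positive")
                return out
        for end, area, per in (
            ("inlet", self.area_in, self.perimeter_in),
            ("outlet", self.area_out, self.perimeter_out),
        ):
            if per * per < 4.0 * math.pi * area * (1.0 - _ISOPERIMETRIC_RTOL):
                out.append(
                    f"segment {self.label!r}: {end} violates the isoperimetric "
                    f"inequality (perimeter² < 4π·area)"
                )
        if self.region is Region.AREA1_VESTIBULE and self.wall_is_wet:
            out.append(
                f"segment {self.label!r}: vestibule walls are squamous and dry "
                f"(wall_is_wet must be False in AREA1)"
            )
        return out


@dataclass(frozen=True)
class SegmentGeometry:
    """Local cross-section at a fractional station of a segment."""

    area: float
    perimeter: float
    hydraulic_diameter: float


def derive_segment_geometry(segment: AirwaySegment, x: float) -> SegmentGeometry:
    """Interpolated cross-section at fractional position ``x`` in [0, 1].

    The hydraulic diameter is ``4·area/perimeter``; for a circular duct this
    equals the geometric diameter.
    """
    if not 0.0 <= x <= 1.0:
        raise DomainError(f"fractional position must be in [0, 1], got {x}")
    bad = segment.violations()
    if bad:
        raise InvalidGeometryError("; ".join(bad))
    area = segment.area_in + (segment.area_out - segment.area_in) * x
    perimeter = segment.perimeter_in + (segment.perimeter_out - segment.perimeter_in) * x
    return SegmentGeometry(area, perimeter, 4.0 * area / perimeter)


def segment_surface_area(segment: AirwaySegment) -> float:
    """Lateral (wall) surface: length × mean perimeter, exact for linear taper."""
    return segment.length * 0.5 * (segment.perimeter_in + segment.perimeter_out)


@dataclass(frozen=True)
class BilateralAirwayModel:
    """One subject state: two unilateral paths merging into a shared path."""

    subject_id: str
    state: SubjectState
    left_path: tuple[AirwaySegment, ...]
    right_path: tuple[AirwaySegment, ...]
    shared_path: tuple[AirwaySegment, ...]

    def __init__(
        self,
        subject_id: str,
        state: SubjectState,
        left_path: Sequence[AirwaySegment],
        right_path: Sequence[AirwaySegment],
        shared_path: Sequence[AirwaySegment],
    ):
        object.__setattr__(self, "subject_id", subject_id)
        object.__setattr__(self, "state", state)
        object.__setattr__(self, "left_path", tuple(left_path))
        object.__setattr__(self, "right_path", tuple(right_path))
        object.__setattr__(self, "shared_path", tuple(shared_path))

    def side_path(self, side: Side) -> tuple[AirwaySegment, ...]:
        return self.left_path if side is Side.LEFT else self.right_path


def _unilateral_path_violations(path: Sequence[AirwaySegment], name: str) -> list[str]:
    out: list[str] = []
    regions = [s.region for s in path]
    if Region.AREA3_NASOPHARYNX in regions:
        seg = path[regions.index(Region.AREA3_NASOPHARYNX)]
        out.append(f"{name}: segment {seg.label!r} is AREA3 but lies on a unilateral path")
    if not any(r is Region.AREA1_VESTIBULE for r in regions):
        out.append(f"{name}: needs at least one AREA1 vestibule segment")
    if not any(r is Region.AREA2_CAVITY for r in regions):
        out.append(f"{name}: needs at least one AREA2 cavity segment")
    seen_area2 = False
    for seg in path:
        if seg.region is Region.AREA2_CAVITY:
            seen_area2 = True
        elif seg.region is Region.AREA1_VESTIBULE and seen_area2:
            out.append(
                f"{name}: segment {seg.label!r} is AREA1 but follows an AREA2 "
                f"segment (vestibule must precede cavity)"
            )
    return out


def validate_airway(model: BilateralAirwayModel) -> list[str]:
    """Every invariant violation in the model; an empty list means solvable.

    Validation never raises: malformed models come back as a list of
    human-readable messages, each naming the offending segment.
    """
    out: list[str] = []
    for path, name in ((model.left_path, "left path"), (model.right_path, "right path")):
        for seg in path:
            out.extend(seg.violations())
        out.extend(_unilateral_path_violations(path, name))
    for seg in model.shared_path:
        out.extend(seg.violations())
        if seg.region is not Region.AREA3_NASOPHARYNX:
            out.append(
                f"shared path: segment {seg.label!r} must be AREA3 "
                f"(got {seg.region.value})"
            )
    if not model.shared_path:
        out.append("shared path: needs at least one AREA3 segment")
    return out


def region_surface_areas(model: BilateralAirwayModel, side: Side) -> dict[str, float]:
    """Wall surface per region on one side, plus the Area-2 : Area-1 ratio.

    The cavity-to-vestibule surface ratio is the quantity that makes the
    posterior mucosal domain dominate total heat/water exchange despite the
    vestibule's higher thermoreceptor density.
    """
    bad = validate_airway(model)
    if bad:
        raise InvalidGeometryError("; ".join(bad))
    area1 = sum(
        segment_surface_area(s)
        for s in model.side_path(side)
        if s.region is Region.AREA1_VESTIBULE
    )
    area2 = sum(
        segment_surface_area(s)
        for s in model.side_path(side)
        if s.region is Region.AREA2_CAVITY
    )
    if area1 <= 0.0:
        raise InvalidGeometryError(f"{side.value}: zero AREA1 surface (degenerate geometry)")
    return {"AREA1": area1, "AREA2": area2, "ratio_area2_to_area1": area2 / area1}


# ---------------------------------------------------------------------------
# constructors


def make_circular_segment(
    label: str,
    region: Region,
    length: float,
    diameter_in: float,
    diameter_out: float | None = None,
    wall_is_wet: bool = True,
) -> AirwaySegment:
    """Circular duct with linearly tapering diameter (SI units)."""
    d_out = diameter_in if diameter_out is None else diameter_out
    return AirwaySegment(
        label=label,
        region=region,
        length=length,
        area_in=math.pi * diameter_in**2 / 4.0,
        area_out=math.pi * d_out**2 / 4.0,
        perimeter_in=math.pi * diameter_in,
        perimeter_out=math.pi * d_out,
        cross_section_kind=CrossSection.CIRCULAR,
        wall_is_wet=wall_is_wet,
    )


def make_slit_segment(
    label: str,
    region: Region,
    length: float,
    gap_in: float,
    width: float,
    gap_out: float | None = None,
    wall_is_wet: bool = True,
) -> AirwaySegment:
    """Rectangular slit of fixed width and linearly tapering gap (SI units)."""
    g_out = gap_in if gap_out is None else gap_out
    return AirwaySegment(
        label=label,
        region=region,
        length=length,
        area_in=gap_in * width,
        area_out=g_out * width,
        perimeter_in=2.0 * (gap_in + width),
        perimeter_out=2.0 * (g_out + width),
        cross_section_kind=CrossSection.SLIT,
        wall_is_wet=wall_is_wet,
    )


def slit_gap_and_width(area: float, perimeter: float) -> tuple[float, float]:
    """Recover (gap, width) of a rectangle from its area and perimeter.

    Gap and width are the two roots of z² − (P/2)·z + A = 0; the smaller root
    is the gap.  Raises :class:`DomainError` when no rectangle exists.
    """
    half_p = perimeter / 2.0
    disc = half_p * half_p - 4.0 * area
    if disc < 0.0:
        raise DomainError("no rectangle has this (area, perimeter) pair")
    root = math.sqrt(disc)
    gap = (half_p - root) / 2.0
    width = (half_p + root) / 2.0
    return gap, width


def scale_slit_gap(segment: AirwaySegment, factor: float) -> AirwaySegment:
    """Scale the gap of a slit segment by ``factor``, keeping its width.

    This is the geometric primitive of the virtual-surgery model: septal
    deviation narrows the gap, septoplasty restores it, turbinate reduction
    widens it slightly on both sides.  The slit resistance then follows the
    cubic-gap law of plane Poiseuille flow.
    """
    if segment.cross_section_kind is not CrossSection.SLIT:
        raise DomainError(f"segment {segment.label!r} is not a slit")
    if factor <= 0.0:
        raise DomainError("gap factor must be positive")
    g_in, w_in = slit_gap_and_width(segment.area_in, segment.perimeter_in)
    g_out, w_out = slit_gap_and_width(segment.area_out, segment.perimeter_out)
    return replace(
        segment,
        area_in=factor * g_in * w_in,
        area_out=factor * g_out * w_out,
        perimeter_in=2.0 * (factor * g_in + w_in),
        perimeter_out=2.0 * (factor * g_out + w_out),
    )


# ---------------------------------------------------------------------------
# default template
#
# A symmetric, idealized bilateral airway whose derived metrics (unilateral
# and bilateral resistance, flow partition, Area-2:Area-1 surface ratio)
# fall in the ranges reported for real post-surgical airways.  Per side:
# a circular vestibule, a narrow slit "nasal valve" carrying most of the
# anterior resistance, and a wide slit cavity; the two sides merge into a
# circular nasopharynx.  The valve/cavity boundary is a modeling station,
# not an anatomical claim.

TEMPLATE_DEFAULTS: dict[str, float] = {
    "vestibule_length": 12e-3,
    "vestibule_diameter": 8e-3,
    "valve_length": 4e-3,
    "valve_gap": 1.45e-3,
    "valve_width": 8e-3,
    "cavity_length": 60e-3,
    "cavity_gap": 3.0e-3,
    "cavity_width": 45e-3,
    "nasopharynx_length": 30e-3,
    "nasopharynx_diameter": 12e-3,
}


def _one_side(side: Side, gap_factor: float, p: dict[str, float]) -> tuple[AirwaySegment, ...]:
    tag = side.value.lower()
    return (
        make_circular_segment(
            f"{tag}_vestibule",
            Region.AREA1_VESTIBULE,
            p["vestibule_length"],
            p["vestibule_diameter"],
            wall_is_wet=False,
        ),
        make_slit_segment(
            f"{tag}_valve",
            Region.AREA1_VESTIBULE,
            p["valve_length"],
            p["valve_gap"],
            p["valve_width"],
            wall_is_wet=False,
        ),
        make_slit_segment(
            f"{tag}_cavity",
            Region.AREA2_CAVITY,
            p["cavity_length"],
            p["cavity_gap"] * gap_factor,
            p["cavity_width"],
            wall_is_wet=True,
        ),
    )


def default_template(
    subject_id: str = "template",
    state: SubjectState = SubjectState.POSTOP,
    left_gap_factor: float = 1.0,
    right_gap_factor: float = 1.0,
    **overrides: float,
) -> BilateralAirwayModel:
    """Build the symmetric template, optionally scaling each cavity gap.

    ``overrides`` replace entries of :data:`TEMPLATE_DEFAULTS` (SI units).
    """
    unknown = set(overrides) - set(TEMPLATE_DEFAULTS)
    if unknown:
        raise DomainError(f"unknown template parameters: {sorted(unknown)}")
    p = {**TEMPLATE_DEFAULTS, **overrides}
    shared = (
        make_circular_segment(
            "nasopharynx",
            Region.AREA3_NASOPHARYNX,
            p["nasopharynx_length"],
            p["nasopharynx_diameter"],
            wall_is_wet=True,
        ),
    )
    return BilateralAirwayModel(
        subject_id=subject_id,
        state=state,
        left_path=_one_side(Side.LEFT, left_gap_factor, p),
        right_path=_one_side(Side.RIGHT, right_gap_factor, p),
        shared_path=shared,
    )
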