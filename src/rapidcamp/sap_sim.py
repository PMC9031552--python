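"""Geometric proxy of a 10-2 static-perimetry exam.

Standard automated perimetry presents a fixed-size stimulus (Goldmann
size III, 4 mm² ≈ 0.43°) at each point of a static grid.  Whether a
defect registers as *absolute* there is, to first order, a containment
question: the stimulus can only disappear completely if it fits wholly
inside the absolute region.  This module applies exactly that geometric
rule to the same ground-truth fields the kinetic engine runs against —
no staircases, no dB thresholds — which is sufficient to reproduce the
central comparison: a band narrower than 0.43° but wider than the
kinetic dot is absolute to the kinetic exam yet at most relative to the
static one.

The 10-2 grid is the 68-point odd lattice with 2° spacing offset 1° from
both meridians; the radius rule x² + y² <= 82 is the unique odd-lattice
cutoff yielding exactly 68 points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .errors import ConfigurationError, DomainError
from .exam_engine import ExamRecord
from .field_model import (
    DepthKind,
    VisualFieldMap,
    classify_point,
    disc_coverage_fraction,
)
from .geometry import FieldPoint

__all__ = [
    "StaticGrid",
    "PointClass",
    "StaticExamResult",
    "MethodComparison",
    "RegionComparison",
    "grid_10_2",
    "simulate_static_exam",
    "compare_methods",
    "GOLDMANN_III_DIAMETER_DEG",
]

#: Angular subtense of the standard 4 mm² Goldmann size III stimulus.
GOLDMANN_III_DIAMETER_DEG = 0.43

_GRID_RADIUS_SQ = 82  # odd-lattice cutoff giving exactly 68 points


class PointClass(enum.Enum):
    NORMAL = "NORMAL"
    RELATIVE_DEFECT = "RELATIVE_DEFECT"
    ABSOLUTE_DEFECT = "ABSOLUTE_DEFECT"


@dataclass(frozen=True)
class StaticGrid:
    points: tuple[FieldPoint, ...]
    stimulus_diameter_deg: float = GOLDMANN_III_DIAMETER_DEG
    label: str = "10-2"

    def __post_init__(self) -> None:
        if self.stimulus_diameter_deg <= 0:
            raise ConfigurationError("stimulus diameter must be > 0")
        if not self.points:
            raise ConfigurationError("grid must contain at least one point")


def grid_10_2(stimulus_diameter_deg: float = GOLDMANN_III_DIAMETER_DEG) -> StaticGrid:
    """The 68-point central 10° grid: all (x, y) with odd coordinates in
    [-9, 9] and x² + y² <= 82."""
    coords = [-9, -7, -5, -3, -1, 1, 3, 5, 7, 9]
    pts = tuple(
        FieldPoint(float(x), float(y))
        for y in reversed(coords)
        for x in coords
        if x * x + y * y <= _GRID_RADIUS_SQ
    )
    return StaticGrid(points=pts, stimulus_diameter_deg=stimulus_diameter_deg)


@dataclass(frozen=True)
class StaticExamResult:
    grid: StaticGrid
    classifications: tuple[PointClass, ...]
    field_fingerprint: str

    def __post_init__(self) -> None:
        if len(self.classifications) != len(self.grid.points):
            raise ConfigurationError("one classification per grid point required")

    def count(self, cls: PointClass) -> int:
        return sum(1 for c in self.classifications if c is cls)

    @property
    def n_absolute(self) -> int:
        return self.count(PointClass.ABSOLUTE_DEFECT)

    @property
    def n_relative(self) -> int:
        return self.count(PointClass.RELATIVE_DEFECT)


def simulate_static_exam(field: VisualFieldMap, grid: StaticGrid | None = None) -> StaticExamResult:
    """Classify every grid point by stimulus containment.

    ABSOLUTE_DEFECT iff the stimulus disc fits wholly inside absolute
    regions; RELATIVE_DEFECT if it partially overlaps an absolute region
    or its centre lies in a relative region; NORMAL otherwise.
    """
    grid = grid if grid is not None else grid_10_2()
    out = []
    for p in grid.points:
        frac = disc_coverage_fraction(
            field, p, grid.stimulus_diameter_deg, DepthKind.ABSOLUTE
        )
        if frac >= 1.0 - 1e-12:
            out.append(PointClass.ABSOLUTE_DEFECT)
        elif frac > 0.0 or classify_point(field, p).kind is DepthKind.RELATIVE:
            out.append(PointClass.RELATIVE_DEFECT)
        else:
            out.append(PointClass.NORMAL)
    return StaticExamResult(grid, tuple(out), field.fingerprint())


# --------------------------------------------------------------------------
# Method comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class RegionComparison:
    """Per ground-truth region: what each method saw."""

    region_index: int
    region_type: str
    depth_kind: str
    kinetic_segments: int
    kinetic_detected_absolute: bool
    static_absolute_points: int
    static_relative_points: int
    static_detected_absolute: bool
    discordant: bool  # kinetic absolute, static at most relative


@dataclass(frozen=True)
class MethodComparison:
    field_fingerprint: str
    regions: tuple[RegionComparison, ...]
    n_kinetic_segments: int
    n_static_absolute: int
    any_discordance: bool


# Tolerance when attributing segments/points to a region: event centres sit
# up to one dot radius inside the region rim, grid points may graze it.
_ATTRIBUTION_BUFFER_DEG = 0.5


def compare_methods(
    exam: ExamRecord,
    static_result: StaticExamResult,
    field: VisualFieldMap,
) -> MethodComparison:
    """Cross-tabulate kinetic segments and static classifications against
    the ground-truth regions (blind spot excluded from the headline flags).

    Raises :class:`DomainError` if the exams do not derive from ``field``.
    """
    fp = field.fingerprint()
    if exam.field_fingerprint != fp or static_result.field_fingerprint != fp:
        raise DomainError("exam and static result must derive from the same field")

    import shapely
    from shapely.geometry import LineString, Point

    segs = [s for s in exam.segments if s.path_label != "blind_spot_line"]
    seg_geoms = [
        LineString(
            [
                (s.off_point.x_deg, s.off_point.y_deg),
                (s.on_point.x_deg, s.on_point.y_deg),
            ]
        )
        if (s.off_point.x_deg, s.off_point.y_deg)
        != (s.on_point.x_deg, s.on_point.y_deg)
        else Point(s.off_point.x_deg, s.off_point.y_deg)
        for s in segs
    ]

    regions = []
    any_disc = False
    for i, (region, poly) in enumerate(
        zip(field.regions(), field.region_polygons())
    ):
        probe = poly.buffer(_ATTRIBUTION_BUFFER_DEG)
        shapely.prepare(probe)
        n_seg = sum(1 for g in seg_geoms if probe.intersects(g))
        kin_abs = (
            region.depth.kind is DepthKind.ABSOLUTE and n_seg > 0 and i > 0
        ) or (i == 0 and any(s.path_label == "blind_spot_line" for s in exam.segments))
        n_abs = n_rel = 0
        for p, c in zip(static_result.grid.points, static_result.classifications):
            if probe.covers(Point(p.x_deg, p.y_deg)):
                if c is PointClass.ABSOLUTE_DEFECT:
                    n_abs += 1
                elif c is PointClass.RELATIVE_DEFECT:
                    n_rel += 1
        stat_abs = n_abs > 0
        discordant = bool(i > 0 and kin_abs and not stat_abs)
        any_disc = any_disc or discordant
        regions.append(
            RegionComparison(
                region_index=i,
                region_type=type(region).__name__,
                depth_kind=region.depth.kind.name,
                kinetic_segments=n_seg if i > 0 else len(exam.segments) - len(segs),
                kinetic_detected_absolute=kin_abs,
                static_absolute_points=n_abs,
                static_relative_points=n_rel,
                static_detected_absolute=stat_abs,
                discordant=discordant,
            )
        )
    return MethodComparison(
        field_fingerprint=fp,
        regions=tuple(regions),
        n_kinetic_segments=len(segs),
        n_static_absolute=static_result.n_absolute,
        any_discordance=any_disc,
    )
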