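"""Tangent-screen geometry, stimulus sizing and coverage accounting.

This module owns every metric conversion in the package:

* visual-field **degrees** <-> flat-screen **centimetres** (separable
  per-axis tangent mapping, fixation at the screen origin),
* centimetres <-> **pixels** (a density, px/cm),
* path length <-> **time** at the constant linear dot speed,
* dot **diameter** as a function of eccentricity (the linear size ladder
  of the kinetic test point), and its angular subtense,
* the **trapezoid coverage model**: the strip swept by the moving,
  eccentricity-growing dot along one path is well approximated by a
  rectangle of width (thickest + thinnest diameter) and length half the
  run, which is how the fraction of the paracentral field actually
  examined is accounted.

Degrees are the canonical unit everywhere outside this module; screen
centimetres and pixels only ever appear inside geometric computations.
The coordinate convention is right-eye: +x temporal, +y superior.  Left
eyes are mirrored at I/O time, never internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "FieldPoint",
    "ScreenGeometry",
    "StimulusSpec",
    "PathSpec",
    "TrajectoryLayout",
    "PathCoverageRow",
    "CoverageReport",
    "deg_to_cm",
    "cm_to_deg",
    "eccentricity_deg",
    "dot_diameter_mm",
    "angular_diameter_deg",
    "angular_speed_ratio",
    "traversal_time_s",
    "path_pixel_count",
    "trapezoid_path_area",
    "coverage_report",
    "reference_coverage_report",
    "static_grid_coverage_percent",
    "disc_region_area_cm2",
    "build_screening_trajectory",
    "trajectory_screen_length_cm",
    "path_coverage_rows",
    "REFERENCE_COVERAGE_INPUTS",
    "REFERENCE_SQUARE_AREA_CM2",
]


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldPoint:
    """A position in the visual field, degrees of visual angle.

    +x is temporal for the tested (right-convention) eye, +y superior.
    """

    x_deg: float
    y_deg: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_deg) and math.isfinite(self.y_deg)):
            raise DomainError("FieldPoint coordinates must be finite")

    def eccentricity_deg(self) -> float:
        return math.hypot(self.x_deg, self.y_deg)


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical testing setup: flat screen viewed from a fixed distance.

    Defaults describe the reference setup: 40 cm viewing distance, 60 Hz
    frame rate, and the tested-area pixel density of 442 px over 21.4 cm.
    ``screen_width_cm``/``screen_height_cm`` are the full monitor extents
    centred on fixation (defaults correspond to a common 21.5-inch 16:9
    clinic monitor, comfortably containing the ±10° square and the
    blind-spot line at 15° temporal).
    """

    viewing_distance_cm: float = 40.0
    screen_width_cm: float = 47.6
    screen_height_cm: float = 26.8
    px_per_cm: float = 442.0 / 21.4
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        for name in (
            "viewing_distance_cm",
            "screen_width_cm",
            "screen_height_cm",
            "px_per_cm",
            "frame_rate_hz",
        ):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"ScreenGeometry.{name} must be > 0")

    def tested_region_edge_cm(self, half_angle_deg: float = 10.0) -> float:
        """Edge length of the centred square covering ±half_angle degrees."""
        return 2.0 * self.viewing_distance_cm * math.tan(math.radians(half_angle_deg))

    def contains_cm(self, x_cm: float, y_cm: float) -> bool:
        return (
            abs(x_cm) <= self.screen_width_cm / 2.0
            and abs(y_cm) <= self.screen_height_cm / 2.0
        )


#: Legal linear speed range for the moving dot, cm/s (the extremes at which
#: scotoma detection degenerates in practice: too slow and too fast).
SPEED_RANGE_CM_S = (0.18, 24.0)


@dataclass(frozen=True)
class StimulusSpec:
    """Kinetic test-dot parameters.

    The dot is a bright disc (140 cd/m²) on a near-black background
    (0.8 cd/m²); luminances are carried as metadata only, never rendered.
    Its physical diameter grows linearly with eccentricity from
    ``d0_mm`` at fixation to ``d15_mm`` at ``ecc_max_deg`` and is clamped
    outside that range; the slope uses the exact achieved endpoints,
    (d15-d0)/15 ≈ 0.1113 mm/°.
    """

    d0_mm: float = 1.05
    d15_mm: float = 2.72
    ecc_max_deg: float = 15.0
    dot_luminance_cdm2: float = 140.0
    background_luminance_cdm2: float = 0.8
    fixation_diameter_deg: float = 1.39
    speed_cm_s: float = 3.0

    def __post_init__(self) -> None:
        if not (self.d15_mm > self.d0_mm > 0):
            raise ConfigurationError("require d15_mm > d0_mm > 0")
        if self.ecc_max_deg <= 0:
            raise ConfigurationError("ecc_max_deg must be > 0")
        lo, hi = SPEED_RANGE_CM_S
        if not (lo <= self.speed_cm_s <= hi):
            raise ConfigurationError(
                f"speed_cm_s={self.speed_cm_s} outside legal range [{lo}, {hi}]"
            )
        if self.dot_luminance_cdm2 <= self.background_luminance_cdm2:
            raise ConfigurationError("dot must be brighter than the background")

    @property
    def slope_mm_per_deg(self) -> float:
        return (self.d15_mm - self.d0_mm) / self.ecc_max_deg

    def diameter_mm(self, ecc_deg) -> float | np.ndarray:
        return dot_diameter_mm(ecc_deg, self)


@dataclass(frozen=True)
class PathSpec:
    """One straight screen-space line swept by the dot at constant speed.

    ``speed_divisor`` is 1 during screening; delineation reruns a path at
    speed/4 or speed/8.
    """

    label: str
    start: FieldPoint
    end: FieldPoint
    speed_divisor: int = 1

    def __post_init__(self) -> None:
        if (self.start.x_deg, self.start.y_deg) == (self.end.x_deg, self.end.y_deg):
            raise ConfigurationError(f"path {self.label!r}: start == end")
        if self.speed_divisor < 1:
            raise ConfigurationError("speed_divisor must be a positive integer")

    def screen_length_cm(self, geom: ScreenGeometry) -> float:
        x0, y0 = deg_to_cm(self.start, geom)
        x1, y1 = deg_to_cm(self.end, geom)
        return math.hypot(x1 - x0, y1 - y0)


# --------------------------------------------------------------------------
# Metric conversions
# --------------------------------------------------------------------------


def deg_to_cm(p: FieldPoint, geom: ScreenGeometry) -> tuple[float, float]:
    """Project a visual-field position onto the flat screen, cm from fixation.

    Separable per-axis tangent mapping: x_cm = D·tan(x°), likewise y.  This
    is the mapping under which the ±10° square has edge 2·D·tan(10°)
    (≈14.1 cm at D = 40 cm).
    """
    if abs(p.x_deg) >= 90.0 or abs(p.y_deg) >= 90.0:
        raise DomainError("tangent projection undefined at or beyond 90 degrees")
    d = geom.viewing_distance_cm
    return (d * math.tan(math.radians(p.x_deg)), d * math.tan(math.radians(p.y_deg)))


def cm_to_deg(p_cm: tuple[float, float], geom: ScreenGeometry) -> FieldPoint:
    """Inverse of :func:`deg_to_cm` (per-axis arctangent)."""
    x_cm, y_cm = p_cm
    if not (math.isfinite(x_cm) and math.isfinite(y_cm)):
        raise DomainError("screen position must be finite")
    d = geom.viewing_distance_cm
    return FieldPoint(math.degrees(math.atan(x_cm / d)), math.degrees(math.atan(y_cm / d)))


def _cm_to_deg_arrays(x_cm: np.ndarray, y_cm: np.ndarray, geom: ScreenGeometry):
    d = geom.viewing_distance_cm
    return np.degrees(np.arctan(x_cm / d)), np.degrees(np.arctan(y_cm / d))


def eccentricity_deg(p: FieldPoint) -> float:
    """Radial distance from fixation in degrees (governs the dot size)."""
    return p.eccentricity_deg()


def dot_diameter_mm(ecc_deg, spec: StimulusSpec | None = None):
    """Physical dot diameter at a given eccentricity.

    Linear in eccentricity between the achieved endpoints and clamped to
    [d0, d15]; accepts scalars or arrays.
    """
    spec = spec if spec is not None else StimulusSpec()
    ecc = np.asarray(ecc_deg, dtype=float)
    if np.any(ecc < 0):
        raise DomainError("eccentricity must be >= 0")
    d = np.clip(spec.d0_mm + spec.slope_mm_per_deg * ecc, spec.d0_mm, spec.d15_mm)
    return float(d) if np.isscalar(ecc_deg) else d


def angular_diameter_deg(d_mm, geom: ScreenGeometry | None = None):
    """Angular subtense of a physical diameter at the viewing distance.

    Small-angle conversion d/D in radians, expressed in degrees — the
    convention that reproduces the printed size-ladder angle column (e.g.
    2.72 mm at 40 cm -> 0.39°).  Accepts scalars or arrays.
    """
    geom = geom if geom is not None else ScreenGeometry()
    d = np.asarray(d_mm, dtype=float)
    if np.any(d < 0):
        raise DomainError("diameter must be >= 0")
    ang = (d / (10.0 * geom.viewing_distance_cm)) * (180.0 / math.pi)
    return float(ang) if np.isscalar(d_mm) else ang


def angular_speed_ratio(ecc_deg: float) -> float:
    """Instantaneous angular speed of constant linear motion on the tangent
    screen, relative to the on-axis value: cos²(eccentricity).

    At 10° the deviation from unity is ≈3% — small enough that the flat
    screen can be treated as speed-equivalent to a perimeter bowl over the
    central field.
    """
    if not 0 <= ecc_deg < 90:
        raise DomainError("eccentricity must lie in [0, 90) degrees")
    return math.cos(math.radians(ecc_deg)) ** 2


def traversal_time_s(length_cm: float, speed_cm_s: float) -> float:
    if speed_cm_s <= 0:
        raise DomainError("speed must be > 0")
    if length_cm < 0:
        raise DomainError("length must be >= 0")
    return length_cm / speed_cm_s


# --------------------------------------------------------------------------
# Pixel rasterization
# --------------------------------------------------------------------------

# Arc-length sampling step for rasterization, in pixel units.  A quarter
# pixel guarantees every cell the continuous centre path passes through is
# visited (supercover), at negligible cost.
_RASTER_STEP_PX = 0.25
# Pull the path endpoint strictly inside its final cell so that a path
# ending exactly on a pixel boundary does not spill into an extra cell
# (half-open convention along the direction of travel).
_ENDPOINT_CLIP_CM = 1e-6


def path_pixel_count(
    paths: Iterable[PathSpec | tuple[FieldPoint, FieldPoint]],
    geom: ScreenGeometry | None = None,
) -> int:
    """Number of distinct pixel cells visited by the dot centre.

    The continuous screen-space centre path is sampled at quarter-pixel
    arc-length steps and each sample is binned into the pixel grid
    (``floor(pos · px_per_cm)``); the union of cells over all paths is
    counted.  A full-width horizontal sweep of the 21.4 cm tested area at
    442 px therefore yields exactly 442 cells.
    """
    geom = geom if geom is not None else ScreenGeometry()
    ppc = geom.px_per_cm
    step_cm = _RASTER_STEP_PX / ppc
    cells: set[tuple[int, int]] = set()
    paths = list(paths)
    if not paths:
        raise DomainError("path_pixel_count requires at least one path")
    for item in paths:
        if isinstance(item, PathSpec):
            start, end = item.start, item.end
        else:
            start, end = item
        x0, y0 = deg_to_cm(start, geom)
        x1, y1 = deg_to_cm(end, geom)
        length = math.hypot(x1 - x0, y1 - y0)
        if length == 0.0:
            cells.add((_pixel_index(x0, ppc), _pixel_index(y0, ppc)))
            continue
        n = max(1, math.ceil(length / step_cm))
        s = np.linspace(0.0, length, n + 1)
        s[-1] = max(0.0, length - _ENDPOINT_CLIP_CM)
        xs = x0 + (x1 - x0) * s / length
        ys = y0 + (y1 - y0) * s / length
        ix = np.floor(xs * ppc + 1e-9).astype(int)
        iy = np.floor(ys * ppc + 1e-9).astype(int)
        cells.update(zip(ix.tolist(), iy.tolist()))
    return len(cells)


def _pixel_index(v_cm: float, ppc: float) -> int:
    return int(math.floor(v_cm * ppc + 1e-9))


# --------------------------------------------------------------------------
# Coverage model
# --------------------------------------------------------------------------


def trapezoid_path_area(thickest_cm: float, thinnest_cm: float, half_run_cm: float) -> float:
    """Area swept by the eccentricity-growing dot along one path.

    The swept strip is two congruent trapezoids which, set side by side,
    form a rectangle of length half the running distance and width the sum
    of the largest and smallest dot diameters: area = (a + b) · h/2-run.
    """
    if not (thickest_cm >= thinnest_cm > 0):
        raise DomainError("require thickest >= thinnest > 0")
    if not half_run_cm > 0:
        raise DomainError("half_run must be > 0")
    return (thickest_cm + thinnest_cm) * half_run_cm


@dataclass(frozen=True)
class PathCoverageRow:
    label: str
    thickest_cm: float
    thinnest_cm: float
    half_run_cm: float
    area_cm2: float

    @property
    def sum_cm(self) -> float:
        return self.thickest_cm + self.thinnest_cm


@dataclass(frozen=True)
class CoverageReport:
    """Per-path swept areas and their share of the tested region."""

    rows: tuple[PathCoverageRow, ...]
    total_area_cm2: float
    region_area_cm2: float
    percent_covered: float

    def __post_init__(self) -> None:
        if not 0 < self.percent_covered < 100:
            raise DomainError("percent_covered must lie strictly in (0, 100)")


#: Printed per-path coverage inputs of the reference screening layout:
#: (label, thickest diameter cm, thinnest diameter cm, half running distance
#: cm).  Diagonal and horizontal pairs are congruent and pooled into single
#: rows whose half-run is the sum over the pair.
REFERENCE_COVERAGE_INPUTS: tuple[tuple[str, float, float, float], ...] = (
    ("vertical_1", 0.26, 0.22, 7.0),
    ("vertical_2", 0.24, 0.18, 7.0),
    ("vertical_3", 0.22, 0.13, 7.0),
    ("diagonal_1+2", 0.24, 0.14, 7.44),
    ("horizontal_1+2", 0.19, 0.14, 5.6),
)

#: Area of the ±10° square at 40 cm with the conventional 14.1 cm edge.
REFERENCE_SQUARE_AREA_CM2 = 198.81


def coverage_report(
    path_rows: Iterable[tuple[str, float, float, float] | PathCoverageRow],
    region_area_cm2: float,
) -> CoverageReport:
    """Sum the trapezoid model over per-path rows and express the total as a
    percentage of the tested region."""
    if region_area_cm2 <= 0:
        raise DomainError("region area must be > 0")
    rows = []
    for row in path_rows:
        if isinstance(row, PathCoverageRow):
            label, a, b, h = row.label, row.thickest_cm, row.thinnest_cm, row.half_run_cm
        else:
            label, a, b, h = row
        rows.append(PathCoverageRow(label, a, b, h, trapezoid_path_area(a, b, h)))
    if not rows:
        raise DomainError("coverage_report requires at least one path row")
    total = sum(r.area_cm2 for r in rows)
    return CoverageReport(
        rows=tuple(rows),
        total_area_cm2=total,
        region_area_cm2=region_area_cm2,
        percent_covered=100.0 * total / region_area_cm2,
    )


def reference_coverage_report() -> CoverageReport:
    """Coverage of the default screening layout over the ±10° square."""
    return coverage_report(REFERENCE_COVERAGE_INPUTS, REFERENCE_SQUARE_AREA_CM2)


def static_grid_coverage_percent(
    n_points: int, stimulus_area_mm2: float, region_area_cm2: float
) -> float:
    """Fraction of a region covered by n static stimuli of fixed area.

    The static-perimetry analogue of the trapezoid model: coverage is just
    n·a/A (100 mm² per cm²)."""
    if n_points < 0 or stimulus_area_mm2 <= 0 or region_area_cm2 <= 0:
        raise DomainError("inputs must be positive (n_points >= 0)")
    return 100.0 * (n_points * stimulus_area_mm2 / 100.0) / region_area_cm2


def disc_region_area_cm2(radius_cm: float) -> float:
    """Area of a circular tested region, π r²."""
    if radius_cm <= 0:
        raise DomainError("radius must be > 0")
    return math.pi * radius_cm**2


# --------------------------------------------------------------------------
# Screening trajectory
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrajectoryLayout:
    """Placement of the screening lines.

    The exact line placement is configurable; the defaults are chosen so
    that the per-path dot-thickness extremes and run lengths reproduce the
    reference coverage table: verticals spanning ±10° at x = 10°, 6.5° and
    2.5° temporal (labelled outermost-first), two 7.44 cm diagonals at ±45°
    in the nasal half starting near 3.1° eccentricity, and two 5.6 cm
    horizontals at y = ±3.2°.  The blind-spot line runs vertically at 15°
    temporal.
    """

    blind_spot_x_deg: float = 15.0
    blind_spot_half_span_deg: float = 7.0
    vertical_x_deg: tuple[float, float, float] = (10.0, 6.5, 2.5)
    vertical_half_span_deg: float = 10.0
    diagonal_inner_ecc_deg: float = 3.1
    diagonal_length_cm: float = 7.44
    horizontal_y_deg: float = 3.2
    horizontal_length_cm: float = 5.6


def build_screening_trajectory(
    geom: ScreenGeometry | None = None,
    layout: TrajectoryLayout | None = None,
) -> list[PathSpec]:
    """Ordered screening paths: blind-spot pass first, then the seven lines
    through the central 10° field (three vertical, two diagonal, two
    horizontal), each straight in screen space.

    Raises :class:`ConfigurationError` if any endpoint leaves the screen.
    """
    geom = geom if geom is not None else ScreenGeometry()
    layout = layout if layout is not None else TrajectoryLayout()
    d = geom.viewing_distance_cm

    paths: list[PathSpec] = []
    bs = layout.blind_spot_x_deg
    half = layout.blind_spot_half_span_deg
    paths.append(PathSpec("blind_spot_line", FieldPoint(bs, half), FieldPoint(bs, -half)))

    v = layout.vertical_half_span_deg
    for i, x in enumerate(layout.vertical_x_deg, start=1):
        top, bottom = FieldPoint(x, v), FieldPoint(x, -v)
        # boustrophedon: alternate sweep direction between successive lines
        start, end = (bottom, top) if i % 2 == 1 else (top, bottom)
        paths.append(PathSpec(f"vertical_{i}", start, end))

    # diagonals: 45° rays through the origin in the nasal half, running from
    # screen radius s1 (inner eccentricity) outward by diagonal_length_cm
    a1 = layout.diagonal_inner_ecc_deg / math.sqrt(2.0)
    s1 = math.sqrt(2.0) * d * math.tan(math.radians(a1))
    s2 = s1 + layout.diagonal_length_cm
    a2 = math.degrees(math.atan((s2 / math.sqrt(2.0)) / d))
    paths.append(PathSpec("diagonal_1", FieldPoint(-a1, a1), FieldPoint(-a2, a2)))
    paths.append(PathSpec("diagonal_2", FieldPoint(-a2, -a2), FieldPoint(-a1, -a1)))

    hy = layout.horizontal_y_deg
    hx = math.degrees(math.atan(layout.horizontal_length_cm / d))
    paths.append(PathSpec("horizontal_1", FieldPoint(0.0, hy), FieldPoint(hx, hy)))
    paths.append(PathSpec("horizontal_2", FieldPoint(hx, -hy), FieldPoint(0.0, -hy)))

    for p in paths:
        for endpoint in (p.start, p.end):
            if not geom.contains_cm(*deg_to_cm(endpoint, geom)):
                raise ConfigurationError(
                    f"path {p.label!r} endpoint {endpoint} lies outside the screen"
                )
    return paths


def trajectory_screen_length_cm(
    paths: Sequence[PathSpec],
    geom: ScreenGeometry | None = None,
    include_blind_spot: bool = False,
) -> float:
    """Total screen length of a trajectory; the blind-spot pass is excluded
    by default (the convention under which the reference layout totals
    ≈68.4 cm and completes in under 30 s at 3 cm/s)."""
    geom = geom if geom is not None else ScreenGeometry()
    return sum(
        p.screen_length_cm(geom)
        for p in paths
        if include_blind_spot or p.label != "blind_spot_line"
    )


def path_coverage_rows(
    paths: Sequence[PathSpec],
    geom: ScreenGeometry | None = None,
    spec: StimulusSpec | None = None,
    n_samples: int = 512,
    include_blind_spot: bool = False,
) -> list[PathCoverageRow]:
    """Derive trapezoid-model inputs from an explicit trajectory.

    For each path the thickest and thinnest dot diameters actually swept
    are read off the eccentricity profile along the screen-space line; the
    half-run is half the screen length.  This ties the coverage table to
    the layout instead of to printed constants.
    """
    geom = geom if geom is not None else ScreenGeometry()
    spec = spec if spec is not None else StimulusSpec()
    rows = []
    for p in paths:
        if p.label == "blind_spot_line" and not include_blind_spot:
            continue
        x0, y0 = deg_to_cm(p.start, geom)
        x1, y1 = deg_to_cm(p.end, geom)
        t = np.linspace(0.0, 1.0, n_samples)
        xs, ys = x0 + (x1 - x0) * t, y0 + (y1 - y0) * t
        xd, yd = _cm_to_deg_arrays(xs, ys, geom)
        ecc = np.hypot(xd, yd)
        diam_cm = dot_diameter_mm(ecc, spec) / 10.0
        length = math.hypot(x1 - x0, y1 - y0)
        a, b, h = float(diam_cm.max()), float(diam_cm.min()), length / 2.0
        rows.append(PathCoverageRow(p.label, a, b, h, trapezoid_path_area(a, b, h)))
    return rows
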