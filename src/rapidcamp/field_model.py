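"""Synthetic ground-truth visual fields.

A :class:`VisualFieldMap` is the physiological blind spot plus a list of
parametric scotoma regions, each carrying a depth class: ABSOLUTE (no
light perception inside), RELATIVE (sensitivity attenuated by some dB)
or the NORMAL background.  Regions live in visual-field degree space and
are backed by shapely polygons; classification of a point is total and
deterministic, with the deepest class winning on overlap
(ABSOLUTE > RELATIVE > NORMAL).

Two scotoma shapes cover the defects of interest in glaucoma screening:

* :class:`ArcuateScotoma` — a circular-arc band emulating a nerve-fibre
  bundle (Bjerrum) defect.  The nerve-fibre preset constructs the arc so
  that it passes through the blind-spot centre with its centre on the
  extension of the vertical meridian, sweeping from the blind spot around
  fixation to the nasal horizontal raphe — a deliberate geometric
  simplification of retinal fibre anatomy.
* :class:`WedgeScotoma` — an annular sector (e.g. a quadrant defect).

Visibility questions reduce to disc containment:
:func:`disc_coverage_fraction` measures what fraction of a stimulus disc
falls inside regions of at least a given depth, on a fixed deterministic
polar sampling grid, so the whole pipeline is seed-free and exact to the
stated sampler resolution.
"""

from __future__ import annotations

import enum
import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .errors import ConfigurationError, DomainError
from .geometry import FieldPoint

__all__ = [
    "DepthKind",
    "DepthClass",
    "NORMAL",
    "ABSOLUTE",
    "relative",
    "BlindSpot",
    "ArcuateScotoma",
    "WedgeScotoma",
    "VisualFieldMap",
    "classify_point",
    "disc_coverage_fraction",
    "disc_coverage_fractions",
    "make_preset_field",
    "region_boundary_polyline",
    "PRESET_NAMES",
    "OUTER_SAMPLE_FRACTION",
]


# --------------------------------------------------------------------------
# Depth classes
# --------------------------------------------------------------------------


class DepthKind(enum.IntEnum):
    """Ordered by depth: deeper defects shadow shallower ones on overlap."""

    NORMAL = 0
    RELATIVE = 1
    ABSOLUTE = 2


@dataclass(frozen=True)
class DepthClass:
    kind: DepthKind
    attenuation_db: float | None = None

    def __post_init__(self) -> None:
        if self.kind is DepthKind.RELATIVE:
            if self.attenuation_db is None or self.attenuation_db <= 0:
                raise ConfigurationError("RELATIVE depth requires attenuation_db > 0")
        elif self.attenuation_db is not None:
            raise ConfigurationError(f"{self.kind.name} depth carries no attenuation")

    def to_dict(self) -> dict:
        d: dict = {"kind": self.kind.name}
        if self.attenuation_db is not None:
            d["attenuation_db"] = self.attenuation_db
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DepthClass":
        return cls(DepthKind[d["kind"]], d.get("attenuation_db"))


NORMAL = DepthClass(DepthKind.NORMAL)
ABSOLUTE = DepthClass(DepthKind.ABSOLUTE)


def relative(attenuation_db: float) -> DepthClass:
    """A relative (attenuating but not extinguishing) depth class."""
    return DepthClass(DepthKind.RELATIVE, attenuation_db)


# --------------------------------------------------------------------------
# Regions
# --------------------------------------------------------------------------

_ELLIPSE_SEGMENTS = 128
_ARC_STEP_DEG = 0.25  # angular sampling step along arcuate bands


@dataclass(frozen=True)
class BlindSpot:
    """Physiological absolute scotoma at the optic-nerve head, modelled as
    an ellipse ~15° temporal, slightly below the horizontal meridian."""

    center: FieldPoint = FieldPoint(15.0, -1.5)
    semi_axes_deg: tuple[float, float] = (2.75, 3.75)

    depth: DepthClass = ABSOLUTE

    def __post_init__(self) -> None:
        if not (10.0 < self.center.x_deg < 20.0):
            raise ConfigurationError("blind-spot centre must lie 10°–20° temporal")
        if min(self.semi_axes_deg) <= 0:
            raise ConfigurationError("blind-spot semi-axes must be > 0")
        if self.depth.kind is not DepthKind.ABSOLUTE:
            raise ConfigurationError("the blind spot is an absolute scotoma")

    def polygon(self) -> Polygon:
        t = np.linspace(0.0, 2.0 * math.pi, _ELLIPSE_SEGMENTS, endpoint=False)
        a, b = self.semi_axes_deg
        xs = self.center.x_deg + a * np.cos(t)
        ys = self.center.y_deg + b * np.sin(t)
        return Polygon(np.column_stack([xs, ys]))

    def to_dict(self) -> dict:
        return {
            "center": [self.center.x_deg, self.center.y_deg],
            "semi_axes_deg": list(self.semi_axes_deg),
            "depth": self.depth.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BlindSpot":
        return cls(
            FieldPoint(*d["center"]),
            tuple(d["semi_axes_deg"]),
            DepthClass.from_dict(d["depth"]),
        )


@dataclass(frozen=True)
class ArcuateScotoma:
    """A band of constant width following a circular arc.

    The band is the set of points whose distance to ``arc_center`` lies
    within ``width_deg``/2 of ``arc_radius_deg``, restricted to the angular
    span (degrees, measured anticlockwise from +x at the arc centre).
    """

    arc_center: FieldPoint
    arc_radius_deg: float
    angular_span_deg: tuple[float, float]
    width_deg: float
    depth: DepthClass = ABSOLUTE

    def __post_init__(self) -> None:
        if self.width_deg <= 0:
            raise ConfigurationError("band width must be > 0")
        if self.arc_radius_deg <= self.width_deg / 2.0:
            raise ConfigurationError("arc radius must exceed half the band width")
        if self.angular_span_deg[1] <= self.angular_span_deg[0]:
            raise ConfigurationError("angular span must be increasing")

    @classmethod
    def from_nerve_fiber_course(
        cls,
        blind_spot_center: FieldPoint = FieldPoint(15.0, -1.5),
        meridian_crossing_ecc_deg: float = 8.0,
        width_deg: float = 2.0,
        depth: DepthClass = ABSOLUTE,
        hemifield: str = "superior",
    ) -> "ArcuateScotoma":
        """Arc through the blind-spot centre with centre on the vertical
        meridian, crossing that meridian at the requested eccentricity and
        ending at the nasal horizontal raphe.

        Solves for the centre (0, yc): for the superior hemifield
        yc + R = m with R the distance to the blind-spot centre, giving
        yc = (m² − bx² − by²) / (2 (m − by)).
        """
        bx, by = blind_spot_center.x_deg, blind_spot_center.y_deg
        m = meridian_crossing_ecc_deg
        if m <= 0:
            raise ConfigurationError("meridian crossing eccentricity must be > 0")
        if hemifield == "superior":
            yc = (m**2 - bx**2 - by**2) / (2.0 * (m - by))
        elif hemifield == "inferior":
            yc = (bx**2 + by**2 - m**2) / (2.0 * (m + by))
        else:
            raise ConfigurationError("hemifield must be 'superior' or 'inferior'")
        radius = math.hypot(bx, by - yc)
        theta_bs = math.degrees(math.atan2(by - yc, bx))
        # end of the arc: where it returns to the horizontal meridian (y=0)
        # on the nasal side
        sin_end = -yc / radius
        sin_end = max(-1.0, min(1.0, sin_end))
        if hemifield == "superior":
            theta_end = 180.0 - math.degrees(math.asin(sin_end))
            span = (theta_bs, theta_end)
        else:
            theta_end = -180.0 - math.degrees(math.asin(sin_end))
            span = (theta_end, theta_bs)
        return cls(FieldPoint(0.0, yc), radius, span, width_deg, depth)

    def polygon(self) -> Polygon:
        t0, t1 = self.angular_span_deg
        n = max(16, int(math.ceil((t1 - t0) / _ARC_STEP_DEG)))
        theta = np.radians(np.linspace(t0, t1, n + 1))
        cx, cy = self.arc_center.x_deg, self.arc_center.y_deg
        r_out = self.arc_radius_deg + self.width_deg / 2.0
        r_in = self.arc_radius_deg - self.width_deg / 2.0
        outer = np.column_stack([cx + r_out * np.cos(theta), cy + r_out * np.sin(theta)])
        inner = np.column_stack([cx + r_in * np.cos(theta), cy + r_in * np.sin(theta)])
        return Polygon(np.vstack([outer, inner[::-1]]))

    def to_dict(self) -> dict:
        return {
            "type": "arcuate",
            "arc_center": [self.arc_center.x_deg, self.arc_center.y_deg],
            "arc_radius_deg": self.arc_radius_deg,
            "angular_span_deg": list(self.angular_span_deg),
            "width_deg": self.width_deg,
            "depth": self.depth.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArcuateScotoma":
        return cls(
            FieldPoint(*d["arc_center"]),
            d["arc_radius_deg"],
            tuple(d["angular_span_deg"]),
            d["width_deg"],
            DepthClass.from_dict(d["depth"]),
        )


@dataclass(frozen=True)
class WedgeScotoma:
    """An annular sector: apex point, angular sector and radial extent."""

    apex: FieldPoint = FieldPoint(0.0, 0.0)
    sector_deg: tuple[float, float] = (90.0, 180.0)
    inner_deg: float = 0.0
    outer_deg: float = 10.0
    depth: DepthClass = ABSOLUTE

    def __post_init__(self) -> None:
        if not (self.outer_deg > self.inner_deg >= 0):
            raise ConfigurationError("require outer > inner >= 0")
        if self.sector_deg[1] <= self.sector_deg[0]:
            raise ConfigurationError("sector must be increasing")

    def polygon(self) -> Polygon:
        t0, t1 = self.sector_deg
        n = max(16, int(math.ceil((t1 - t0) / _ARC_STEP_DEG)))
        theta = np.radians(np.linspace(t0, t1, n + 1))
        ax, ay = self.apex.x_deg, self.apex.y_deg
        outer = np.column_stack(
            [ax + self.outer_deg * np.cos(theta), ay + self.outer_deg * np.sin(theta)]
        )
        if self.inner_deg == 0.0:
            pts = np.vstack([[ax, ay], outer])
        else:
            inner = np.column_stack(
                [ax + self.inner_deg * np.cos(theta), ay + self.inner_deg * np.sin(theta)]
            )
            pts = np.vstack([outer, inner[::-1]])
        return Polygon(pts)

    def to_dict(self) -> dict:
        return {
            "type": "wedge",
            "apex": [self.apex.x_deg, self.apex.y_deg],
            "sector_deg": list(self.sector_deg),
            "inner_deg": self.inner_deg,
            "outer_deg": self.outer_deg,
            "depth": self.depth.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "WedgeScotoma":
        return cls(
            FieldPoint(*d["apex"]),
            tuple(d["sector_deg"]),
            d["inner_deg"],
            d["outer_deg"],
            DepthClass.from_dict(d["depth"]),
        )


_SCOTOMA_TYPES = {"arcuate": ArcuateScotoma, "wedge": WedgeScotoma}

Scotoma = ArcuateScotoma | WedgeScotoma


# --------------------------------------------------------------------------
# The field container
# --------------------------------------------------------------------------


@dataclass
class VisualFieldMap:
    """Ground-truth field: blind spot + scotomas over a NORMAL background.

    Internally both eyes use the temporal=+x convention; ``eye`` only
    affects rendering/export.  Treat instances as immutable once used —
    region unions are cached.
    """

    eye: str = "OD"
    blind_spot: BlindSpot = dc_field(default_factory=BlindSpot)
    scotomas: tuple[Scotoma, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        if self.eye not in ("OD", "OS"):
            raise ConfigurationError("eye must be 'OD' or 'OS'")
        self.scotomas = tuple(self.scotomas)
        self._union_cache: dict[DepthKind, object] = {}
        self._polygon_cache: list[Polygon] | None = None

    # -- regions ----------------------------------------------------------

    def regions(self) -> list[BlindSpot | Scotoma]:
        """Blind spot first, then scotomas in declaration order."""
        return [self.blind_spot, *self.scotomas]

    def region_polygons(self) -> list[Polygon]:
        if self._polygon_cache is None:
            self._polygon_cache = [r.polygon() for r in self.regions()]
        return self._polygon_cache

    def region_union(self, min_kind: DepthKind):
        """Cached union of all regions at least as deep as ``min_kind``."""
        if min_kind not in self._union_cache:
            polys = [
                poly
                for r, poly in zip(self.regions(), self.region_polygons())
                if r.depth.kind >= min_kind
            ]
            union = unary_union(polys) if polys else Polygon()
            shapely.prepare(union)
            self._union_cache[min_kind] = union
        return self._union_cache[min_kind]

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "eye": self.eye,
            "name": self.name,
            "blind_spot": self.blind_spot.to_dict(),
            "scotomas": [s.to_dict() for s in self.scotomas],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VisualFieldMap":
        scotomas = tuple(
            _SCOTOMA_TYPES[s["type"]].from_dict(s) for s in d.get("scotomas", [])
        )
        return cls(
            eye=d.get("eye", "OD"),
            blind_spot=BlindSpot.from_dict(d["blind_spot"]),
            scotomas=scotomas,
            name=d.get("name", ""),
        )

    def fingerprint(self) -> str:
        """Stable digest of the field definition, used to tie exam results
        back to the ground truth they were produced from."""
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]


# --------------------------------------------------------------------------
# Classification and disc coverage
# --------------------------------------------------------------------------


def classify_point(field: VisualFieldMap, p: FieldPoint) -> DepthClass:
    """Total, deterministic ground-truth lookup; deepest class wins, ties
    broken toward the larger attenuation (so the result is independent of
    the order of the scotoma list)."""
    best = NORMAL
    pt = Point(p.x_deg, p.y_deg)
    for region, poly in zip(field.regions(), field.region_polygons()):
        if poly.covers(pt):
            d = region.depth
            if d.kind > best.kind or (
                d.kind == best.kind
                and (d.attenuation_db or 0.0) > (best.attenuation_db or 0.0)
            ):
                best = d
    return best


# Deterministic polar sampling grid for disc containment: 16 equal-area
# rings (midpoint radii) x 32 spokes, plus the centre = 513 samples.
_N_RINGS = 16
_N_SPOKES = 32


def _unit_disc_samples() -> np.ndarray:
    radii = np.sqrt((np.arange(1, _N_RINGS + 1) - 0.5) / _N_RINGS)
    angles = 2.0 * math.pi * np.arange(_N_SPOKES) / _N_SPOKES
    r, a = np.meshgrid(radii, angles, indexing="ij")
    pts = np.column_stack([(r * np.cos(a)).ravel(), (r * np.sin(a)).ravel()])
    return np.vstack([[0.0, 0.0], pts])


_DISC_SAMPLES = _unit_disc_samples()
N_DISC_SAMPLES = _DISC_SAMPLES.shape[0]

#: Radius (unit-disc units) of the outermost sampling ring.  Containment
#: decided on the sampler is equivalent to geometric containment of a disc
#: shrunk by this factor, which the delineation rim correction uses.
OUTER_SAMPLE_FRACTION = float(math.sqrt((_N_RINGS - 0.5) / _N_RINGS))


def disc_coverage_fraction(
    field: VisualFieldMap,
    center: FieldPoint,
    diameter_deg: float,
    target_kind: DepthKind = DepthKind.ABSOLUTE,
) -> float:
    """Fraction of a stimulus disc lying in regions at least ``target_kind``
    deep, estimated on the fixed 513-point polar grid (hence deterministic
    and seed-free).  Returns exactly 1.0 only when every sample is inside.
    """
    if diameter_deg <= 0:
        raise DomainError("disc diameter must be > 0")
    return float(
        disc_coverage_fractions(
            field,
            np.array([[center.x_deg, center.y_deg]]),
            np.array([diameter_deg / 2.0]),
            target_kind,
        )[0]
    )


def disc_coverage_fractions(
    field: VisualFieldMap,
    centers_deg: np.ndarray,
    radii_deg: np.ndarray,
    target_kind: DepthKind = DepthKind.ABSOLUTE,
) -> np.ndarray:
    """Vectorized :func:`disc_coverage_fraction` over many discs.

    Discs whose centre is farther than its radius from the target union
    are zero by construction and skipped, which keeps frame-by-frame exam
    simulation cheap.
    """
    centers_deg = np.asarray(centers_deg, dtype=float)
    radii_deg = np.asarray(radii_deg, dtype=float)
    n = centers_deg.shape[0]
    out = np.zeros(n)
    union = field.region_union(target_kind)
    if union.is_empty or n == 0:
        return out
    rmax = float(radii_deg.max())
    near_region = union.buffer(rmax * 1.001)
    shapely.prepare(near_region)
    near = shapely.contains_xy(near_region, centers_deg[:, 0], centers_deg[:, 1])
    idx = np.nonzero(near)[0]
    if idx.size == 0:
        return out
    pts = (
        centers_deg[idx, None, :]
        + radii_deg[idx, None, None] * _DISC_SAMPLES[None, :, :]
    )
    flat = pts.reshape(-1, 2)
    inside = shapely.contains_xy(union, flat[:, 0], flat[:, 1])
    out[idx] = inside.reshape(idx.size, N_DISC_SAMPLES).mean(axis=1)
    return out


# --------------------------------------------------------------------------
# Presets
# --------------------------------------------------------------------------

PRESET_NAMES = (
    "clean",
    "narrow_arcuate_035",
    "superior_arcuate",
    "inferior_arcuate",
    "quadrant_superior",
)


def make_preset_field(
    preset_name: str, params: dict | None = None, eye: str = "OD"
) -> VisualFieldMap:
    """Construct one of the canonical synthetic fields.

    * ``clean`` — blind spot only.
    * ``narrow_arcuate_035`` — a 0.35°-wide absolute nerve-fibre band
      crossing the superior Bjerrum region ~8° from fixation, anchored at
      the blind spot: the defect narrow enough to swallow the kinetic dot
      but not a conventional 0.43° static stimulus.
    * ``superior_arcuate`` / ``inferior_arcuate`` — broader (default 2°)
      arcuate defects; ``params`` may set ``width_deg``,
      ``crossing_ecc_deg``, ``depth`` ("absolute"/"relative") and
      ``attenuation_db``.
    * ``quadrant_superior`` — an upper-quadrant wedge; ``params`` may set
      ``sector_deg``, ``inner_deg``, ``outer_deg``, ``depth``.
    """
    params = dict(params or {})
    bs = BlindSpot()

    def depth_from_params(default: DepthClass = ABSOLUTE) -> DepthClass:
        kind = params.get("depth")
        if kind is None:
            return default
        if kind == "absolute":
            return ABSOLUTE
        if kind == "relative":
            return relative(params.get("attenuation_db", 10.0))
        raise ConfigurationError(f"unknown depth {kind!r}")

    if preset_name == "clean":
        scotomas: tuple[Scotoma, ...] = ()
    elif preset_name == "narrow_arcuate_035":
        scotomas = (
            ArcuateScotoma.from_nerve_fiber_course(
                blind_spot_center=bs.center,
                meridian_crossing_ecc_deg=params.get("crossing_ecc_deg", 8.0),
                width_deg=params.get("width_deg", 0.35),
                depth=depth_from_params(),
                hemifield="superior",
            ),
        )
    elif preset_name in ("superior_arcuate", "inferior_arcuate"):
        scotomas = (
            ArcuateScotoma.from_nerve_fiber_course(
                blind_spot_center=bs.center,
                meridian_crossing_ecc_deg=params.get("crossing_ecc_deg", 8.0),
                width_deg=params.get("width_deg", 2.0),
                depth=depth_from_params(),
                hemifield=preset_name.split("_")[0],
            ),
        )
    elif preset_name == "quadrant_superior":
        scotomas = (
            WedgeScotoma(
                apex=FieldPoint(0.0, 0.0),
                sector_deg=tuple(params.get("sector_deg", (90.0, 180.0))),
                inner_deg=params.get("inner_deg", 1.0),
                outer_deg=params.get("outer_deg", 10.0),
                depth=depth_from_params(),
            ),
        )
    else:
        raise ConfigurationError(
            f"unknown preset {preset_name!r}; choose from {PRESET_NAMES}"
        )
    return VisualFieldMap(eye=eye, blind_spot=bs, scotomas=scotomas, name=preset_name)


def region_boundary_polyline(
    field: VisualFieldMap, region_index: int, resolution_deg: float = 0.1
) -> np.ndarray:
    """Closed boundary polyline of a region (index 0 = blind spot, then
    scotomas in order), vertices spaced at most ``resolution_deg`` apart.
    Serves as the ground-truth outline against which delineation accuracy
    is measured."""
    regions = field.regions()
    if not 0 <= region_index < len(regions):
        raise DomainError(f"region index {region_index} out of range")
    if resolution_deg <= 0:
        raise DomainError("resolution must be > 0")
    poly = field.region_polygons()[region_index]
    dense = shapely.segmentize(poly.exterior, resolution_deg)
    return np.asarray(dense.coords)
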