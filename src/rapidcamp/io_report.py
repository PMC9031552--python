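"""Serialization, rendering and test-fixture plumbing.

Degrees are the canonical unit in every file this module writes; screen
centimetres and pixels never leave the geometry layer.  Exam records and
field definitions round-trip losslessly through versioned JSON (Python's
JSON float formatting is exact for binary64), events additionally export
to CSV, and exam printouts render to SVG — chosen over raster output
because every coordinate in the document can be parsed back and checked.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from xml.etree import ElementTree as ET

import numpy as np
import shapely

from .errors import DomainError, SchemaError
from .exam_engine import ExamEvent, ExamRecord, ScotomaSegment
from .field_model import (
    DepthKind,
    VisualFieldMap,
    make_preset_field,
    _DISC_SAMPLES,
)
from .geometry import (
    CoverageReport,
    FieldPoint,
    PathSpec,
    ScreenGeometry,
    StimulusSpec,
    TrajectoryLayout,
    angular_diameter_deg,
    build_screening_trajectory,
    deg_to_cm,
)
from .observer import ObserverParams

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "write_field_json",
    "read_field_json",
    "write_exam_json",
    "read_exam_json",
    "exam_to_dict",
    "exam_from_dict",
    "events_to_csv",
    "static_result_to_csv",
    "coverage_report_to_csv",
    "render_exam_svg",
    "analytic_scotoma_segments",
    "Fixture",
    "fixture_suite",
]

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# Config and simple dataclass (de)serialization
# --------------------------------------------------------------------------


def _geometry_to_dict(g: ScreenGeometry) -> dict:
    return {
        "viewing_distance_cm": g.viewing_distance_cm,
        "screen_width_cm": g.screen_width_cm,
        "screen_height_cm": g.screen_height_cm,
        "px_per_cm": g.px_per_cm,
        "frame_rate_hz": g.frame_rate_hz,
    }


def _stimulus_to_dict(s: StimulusSpec) -> dict:
    return {
        "d0_mm": s.d0_mm,
        "d15_mm": s.d15_mm,
        "ecc_max_deg": s.ecc_max_deg,
        "dot_luminance_cdm2": s.dot_luminance_cdm2,
        "background_luminance_cdm2": s.background_luminance_cdm2,
        "fixation_diameter_deg": s.fixation_diameter_deg,
        "speed_cm_s": s.speed_cm_s,
    }


def _observer_to_dict(o: ObserverParams) -> dict:
    return {
        "containment_threshold": o.containment_threshold,
        "latency_mean_s": o.latency_mean_s,
        "latency_sd_s": o.latency_sd_s,
        "lapse_rate": o.lapse_rate,
        "false_alarm_rate": o.false_alarm_rate,
        "rng_seed": o.rng_seed,
    }


def _path_to_dict(p: PathSpec) -> dict:
    return {
        "label": p.label,
        "start": [p.start.x_deg, p.start.y_deg],
        "end": [p.end.x_deg, p.end.y_deg],
        "speed_divisor": p.speed_divisor,
    }


def _path_from_dict(d: dict) -> PathSpec:
    return PathSpec(
        d["label"], FieldPoint(*d["start"]), FieldPoint(*d["end"]), d["speed_divisor"]
    )


@dataclass(frozen=True)
class RunConfig:
    """One exam run's complete configuration; round-trips losslessly."""

    geometry: ScreenGeometry = dc_field(default_factory=ScreenGeometry)
    stimulus: StimulusSpec = dc_field(default_factory=StimulusSpec)
    observer: ObserverParams = dc_field(default_factory=ObserverParams)
    layout: TrajectoryLayout = dc_field(default_factory=TrajectoryLayout)
    field_path: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "geometry": _geometry_to_dict(self.geometry),
            "stimulus": _stimulus_to_dict(self.stimulus),
            "observer": _observer_to_dict(self.observer),
            "layout": {
                "blind_spot_x_deg": self.layout.blind_spot_x_deg,
                "blind_spot_half_span_deg": self.layout.blind_spot_half_span_deg,
                "vertical_x_deg": list(self.layout.vertical_x_deg),
                "vertical_half_span_deg": self.layout.vertical_half_span_deg,
                "diagonal_inner_ecc_deg": self.layout.diagonal_inner_ecc_deg,
                "diagonal_length_cm": self.layout.diagonal_length_cm,
                "horizontal_y_deg": self.layout.horizontal_y_deg,
                "horizontal_length_cm": self.layout.horizontal_length_cm,
            },
            "field_path": self.field_path,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_version(d)
        lay = d["layout"]
        return cls(
            geometry=ScreenGeometry(**d["geometry"]),
            stimulus=StimulusSpec(**d["stimulus"]),
            observer=ObserverParams(**d["observer"]),
            layout=TrajectoryLayout(
                blind_spot_x_deg=lay["blind_spot_x_deg"],
                blind_spot_half_span_deg=lay["blind_spot_half_span_deg"],
                vertical_x_deg=tuple(lay["vertical_x_deg"]),
                vertical_half_span_deg=lay["vertical_half_span_deg"],
                diagonal_inner_ecc_deg=lay["diagonal_inner_ecc_deg"],
                diagonal_length_cm=lay["diagonal_length_cm"],
                horizontal_y_deg=lay["horizontal_y_deg"],
                horizontal_length_cm=lay["horizontal_length_cm"],
            ),
            field_path=d.get("field_path"),
            seed=d.get("seed", 0),
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        return path

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _check_version(d: dict) -> None:
    v = d.get("schema_version")
    if v != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {v!r} (expected {SCHEMA_VERSION})")


# --------------------------------------------------------------------------
# Field and exam JSON
# --------------------------------------------------------------------------


def write_field_json(field: VisualFieldMap, path: str | Path) -> Path:
    path = Path(path)
    doc = {"schema_version": SCHEMA_VERSION, **field.to_dict()}
    path.write_text(json.dumps(doc, indent=2, sort_keys=True))
    return path


def read_field_json(path: str | Path) -> VisualFieldMap:
    doc = json.loads(Path(path).read_text())
    _check_version(doc)
    return VisualFieldMap.from_dict(doc)


def exam_to_dict(exam: ExamRecord) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "geometry": _geometry_to_dict(exam.geometry),
        "stimulus": _stimulus_to_dict(exam.stimulus),
        "observer": _observer_to_dict(exam.observer),
        "paths": [_path_to_dict(p) for p in exam.paths],
        "field_fingerprint": exam.field_fingerprint,
        "field_eye": exam.field_eye,
        "frames": {
            "time_s": exam.frame_time_s.tolist(),
            "x_deg": exam.frame_x_deg.tolist(),
            "y_deg": exam.frame_y_deg.tolist(),
            "diameter_mm": exam.frame_diameter_mm.tolist(),
            "diameter_deg": exam.frame_diameter_deg.tolist(),
            "path_index": exam.frame_path_index.tolist(),
        },
        "events": [
            {
                "path_index": e.path_index,
                "path_label": e.path_label,
                "frame": e.frame,
                "time_s": e.time_s,
                "point": [e.point.x_deg, e.point.y_deg],
                "kind": e.kind,
            }
            for e in exam.events
        ],
        "segments": [
            {
                "path_index": s.path_index,
                "path_label": s.path_label,
                "off_point": [s.off_point.x_deg, s.off_point.y_deg],
                "on_point": [s.on_point.x_deg, s.on_point.y_deg],
                "off_time_s": s.off_time_s,
                "on_time_s": s.on_time_s,
                "opened_at_path_start": s.opened_at_path_start,
                "closed_at_path_end": s.closed_at_path_end,
            }
            for s in exam.segments
        ],
        "path_durations_s": list(exam.path_durations_s),
        "total_duration_s": exam.total_duration_s,
    }


def exam_from_dict(d: dict) -> ExamRecord:
    _check_version(d)
    fr = d["frames"]
    return ExamRecord(
        geometry=ScreenGeometry(**d["geometry"]),
        stimulus=StimulusSpec(**d["stimulus"]),
        observer=ObserverParams(**d["observer"]),
        paths=tuple(_path_from_dict(p) for p in d["paths"]),
        field_fingerprint=d["field_fingerprint"],
        field_eye=d["field_eye"],
        frame_time_s=np.array(fr["time_s"]),
        frame_x_deg=np.array(fr["x_deg"]),
        frame_y_deg=np.array(fr["y_deg"]),
        frame_diameter_mm=np.array(fr["diameter_mm"]),
        frame_diameter_deg=np.array(fr["diameter_deg"]),
        frame_path_index=np.array(fr["path_index"], dtype=int),
        events=tuple(
            ExamEvent(
                e["path_index"],
                e["path_label"],
                e["frame"],
                e["time_s"],
                FieldPoint(*e["point"]),
                e["kind"],
            )
            for e in d["events"]
        ),
        segments=tuple(
            ScotomaSegment(
                s["path_index"],
                s["path_label"],
                FieldPoint(*s["off_point"]),
                FieldPoint(*s["on_point"]),
                s["off_time_s"],
                s["on_time_s"],
                s["opened_at_path_start"],
                s["closed_at_path_end"],
            )
            for s in d["segments"]
        ),
        path_durations_s=tuple(d["path_durations_s"]),
        total_duration_s=d["total_duration_s"],
    )


def write_exam_json(exam: ExamRecord, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(exam_to_dict(exam), sort_keys=True))
    return path


def read_exam_json(path: str | Path) -> ExamRecord:
    return exam_from_dict(json.loads(Path(path).read_text()))


# --------------------------------------------------------------------------
# CSV exports
# --------------------------------------------------------------------------


def events_to_csv(exam: ExamRecord, path: str | Path) -> Path:
    """Event stream as CSV: frame, time_s, x_deg, y_deg, event."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["frame", "time_s", "x_deg", "y_deg", "event"])
        for e in exam.events:
            w.writerow([e.frame, repr(e.time_s), repr(e.point.x_deg), repr(e.point.y_deg), e.kind])
    return path


def static_result_to_csv(result, path: str | Path) -> Path:
    """Static exam result as CSV: x_deg, y_deg, classification."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["x_deg", "y_deg", "classification"])
        for p, c in zip(result.grid.points, result.classifications):
            w.writerow([repr(p.x_deg), repr(p.y_deg), c.value])
    return path


def coverage_report_to_csv(report: CoverageReport, path: str | Path) -> Path:
    """Coverage table as CSV mirroring the per-path trapezoid inputs."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["label", "thickest_cm", "thinnest_cm", "sum_cm", "half_run_cm", "area_cm2"]
        )
        for r in report.rows:
            w.writerow(
                [r.label, r.thickest_cm, r.thinnest_cm, r.sum_cm, r.half_run_cm, r.area_cm2]
            )
        w.writerow(["total", "", "", "", "", report.total_area_cm2])
        w.writerow(["region_area_cm2", "", "", "", "", report.region_area_cm2])
        w.writerow(["percent_covered", "", "", "", "", report.percent_covered])
    return path


# --------------------------------------------------------------------------
# SVG rendering
# --------------------------------------------------------------------------

_SVG_NS = "http://www.w3.org/2000/svg"


def render_exam_svg(
    exam: ExamRecord,
    field: VisualFieldMap | None = None,
    out: str | Path | None = None,
    scale_px_per_deg: float = 20.0,
) -> bytes:
    """Render the exam printout: dashed trajectory lines, red OFF and green
    ON dots connected by grey scotoma segments, the fixation cross and the
    blind-spot outline; optionally the ground-truth regions underneath.

    Coordinates inside the drawing group are raw visual-field degrees (a
    single group transform maps them to pixels, flipping y so superior is
    up); left-eye exams are mirrored here, at render time.  Returns the
    serialized document and writes it to ``out`` if given.
    """
    half = 22.0  # degrees of field shown around fixation
    size = 2 * half * scale_px_per_deg
    ET.register_namespace("", _SVG_NS)
    svg = ET.Element(
        f"{{{_SVG_NS}}}svg",
        {
            "viewBox": f"0 0 {size:g} {size:g}",
            "width": f"{size:g}",
            "height": f"{size:g}",
            "data-scale-px-per-deg": repr(scale_px_per_deg),
            "data-eye": exam.field_eye,
        },
    )
    mirror = -1.0 if exam.field_eye == "OS" else 1.0
    s = scale_px_per_deg
    root = ET.SubElement(
        svg,
        f"{{{_SVG_NS}}}g",
        {
            "id": "field",
            "transform": f"translate({half * s:g},{half * s:g}) scale({mirror * s:g},{-s:g})",
        },
    )

    def fmt(v: float) -> str:
        return repr(float(v))

    if field is not None:
        gt = ET.SubElement(root, f"{{{_SVG_NS}}}g", {"id": "ground-truth"})
        for region, poly in zip(field.regions(), field.region_polygons()):
            fill = "#202020" if region.depth.kind is DepthKind.ABSOLUTE else "#808080"
            pts = " ".join(f"{fmt(x)},{fmt(y)}" for x, y in poly.exterior.coords)
            ET.SubElement(
                gt,
                f"{{{_SVG_NS}}}polygon",
                {"points": pts, "fill": fill, "fill-opacity": "0.35", "stroke": "none"},
            )

    traj = ET.SubElement(root, f"{{{_SVG_NS}}}g", {"id": "trajectory"})
    for i, p in enumerate(exam.paths):
        mask = exam.frame_path_index == i
        pts = " ".join(
            f"{fmt(x)},{fmt(y)}"
            for x, y in zip(exam.frame_x_deg[mask][::8], exam.frame_y_deg[mask][::8])
        )
        ET.SubElement(
            traj,
            f"{{{_SVG_NS}}}polyline",
            {
                "class": "path",
                "data-label": p.label,
                "points": pts,
                "fill": "none",
                "stroke": "#4060c0",
                "stroke-width": "0.05",
                "stroke-dasharray": "0.4 0.3",
            },
        )

    segs = ET.SubElement(root, f"{{{_SVG_NS}}}g", {"id": "segments"})
    for seg in exam.segments:
        ET.SubElement(
            segs,
            f"{{{_SVG_NS}}}line",
            {
                "class": "segment",
                "x1": fmt(seg.off_point.x_deg),
                "y1": fmt(seg.off_point.y_deg),
                "x2": fmt(seg.on_point.x_deg),
                "y2": fmt(seg.on_point.y_deg),
                "stroke": "#909090",
                "stroke-width": "0.15",
            },
        )

    offs = ET.SubElement(root, f"{{{_SVG_NS}}}g", {"id": "off-events"})
    ons = ET.SubElement(root, f"{{{_SVG_NS}}}g", {"id": "on-events"})
    for e in exam.events:
        parent, fill, cls = (offs, "red", "off") if e.kind == "OFF" else (ons, "green", "on")
        ET.SubElement(
            parent,
            f"{{{_SVG_NS}}}circle",
            {
                "class": cls,
                "cx": fmt(e.point.x_deg),
                "cy": fmt(e.point.y_deg),
                "r": "0.25",
                "fill": fill,
            },
        )

    fix = ET.SubElement(root, f"{{{_SVG_NS}}}g", {"id": "fixation"})
    arm = exam.stimulus.fixation_diameter_deg / 2.0
    for x1, y1, x2, y2 in ((-arm, 0, arm, 0), (0, -arm, 0, arm)):
        ET.SubElement(
            fix,
            f"{{{_SVG_NS}}}line",
            {
                "x1": fmt(x1), "y1": fmt(y1), "x2": fmt(x2), "y2": fmt(y2),
                "stroke": "white", "stroke-width": "0.1",
            },
        )

    if field is not None:
        bs = field.region_polygons()[0]
        pts = " ".join(f"{fmt(x)},{fmt(y)}" for x, y in bs.exterior.coords)
        ET.SubElement(
            root,
            f"{{{_SVG_NS}}}polygon",
            {
                "id": "blind-spot",
                "points": pts,
                "fill": "none",
                "stroke": "#c0c0c0",
                "stroke-width": "0.08",
            },
        )

    data = ET.tostring(svg, xml_declaration=True, encoding="UTF-8")
    if out is not None:
        out = Path(out)
        try:
            out.write_bytes(data)
        except OSError as exc:
            raise OSError(f"cannot write SVG to {out}: {exc}") from exc
    return data


# --------------------------------------------------------------------------
# Analytic segment oracle
# --------------------------------------------------------------------------


def analytic_scotoma_segments(
    field: VisualFieldMap,
    trajectory: list[PathSpec] | tuple[PathSpec, ...],
    geom: ScreenGeometry | None = None,
    spec: StimulusSpec | None = None,
    mode: str = "sampled",
    tol_cm: float = 1e-5,
) -> dict[str, list[tuple[FieldPoint, FieldPoint]]]:
    """Continuous-position containment intervals along each path.

    Independent of the frame/event machinery: positions are refined by
    bisection on the screen-space arc length, so the returned entry/exit
    points are exact to ``tol_cm``.  ``mode="sampled"`` uses the same
    513-point containment rule as the observer (the oracle for frame
    quantization alone); ``mode="geometric"`` tests true disc containment
    via polygon covering (the spoke-free geometric idealization, which
    differs from the sampled rule by at most the inter-spoke sag, well
    under 0.01 degrees for the preset regions).
    """
    geom = geom if geom is not None else ScreenGeometry()
    spec = spec if spec is not None else StimulusSpec()
    union = field.region_union(DepthKind.ABSOLUTE)
    d = geom.viewing_distance_cm
    from .field_model import OUTER_SAMPLE_FRACTION

    def contained(x_cm: float, y_cm: float) -> bool:
        xd = math.degrees(math.atan(x_cm / d))
        yd = math.degrees(math.atan(y_cm / d))
        ecc = math.hypot(xd, yd)
        diam = angular_diameter_deg(spec.diameter_mm(ecc), geom)
        if mode == "sampled":
            pts = np.array([xd, yd]) + (diam / 2.0) * _DISC_SAMPLES
            return bool(
                shapely.contains_xy(union, pts[:, 0], pts[:, 1]).all()
            )
        elif mode == "geometric":
            disc = shapely.Point(xd, yd).buffer(
                OUTER_SAMPLE_FRACTION * diam / 2.0, quad_segs=32
            )
            return bool(union.covers(disc))
        raise DomainError(f"unknown oracle mode {mode!r}")

    out: dict[str, list[tuple[FieldPoint, FieldPoint]]] = {}
    for p in trajectory:
        x0, y0 = deg_to_cm(p.start, geom)
        x1, y1 = deg_to_cm(p.end, geom)
        length = math.hypot(x1 - x0, y1 - y0)

        def pos(s: float) -> tuple[float, float]:
            f = s / length
            return (x0 + (x1 - x0) * f, y0 + (y1 - y0) * f)

        # coarse scan fine enough to catch the narrowest containment window
        n = max(64, int(math.ceil(length / 0.005)))
        ss = np.linspace(0.0, length, n + 1)
        flags = np.array([contained(*pos(s)) for s in ss])

        def refine(lo: float, hi: float, want_inside_hi: bool) -> float:
            # invariant: contained(pos(hi)) == want_inside_hi != contained(pos(lo))
            while hi - lo > tol_cm:
                mid = (lo + hi) / 2.0
                if contained(*pos(mid)) == want_inside_hi:
                    hi = mid
                else:
                    lo = mid
            return hi

        intervals: list[tuple[float, float]] = []
        inside = bool(flags[0])
        start_s = 0.0 if inside else None
        for k in range(1, len(ss)):
            if bool(flags[k]) != inside:
                edge = refine(ss[k - 1], ss[k], bool(flags[k]))
                if flags[k]:
                    start_s = edge
                else:
                    intervals.append((start_s, edge))
                    start_s = None
                inside = bool(flags[k])
        if inside and start_s is not None:
            intervals.append((start_s, length))

        def to_field(s: float) -> FieldPoint:
            x, y = pos(s)
            return FieldPoint(math.degrees(math.atan(x / d)), math.degrees(math.atan(y / d)))

        out[p.label] = [(to_field(a), to_field(b)) for a, b in intervals]
    return out


# --------------------------------------------------------------------------
# Fixture bundles
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    """A synthetic field with its observer and analytic expected segments."""

    name: str
    field: VisualFieldMap
    observer: ObserverParams
    trajectory: tuple[PathSpec, ...]
    expected_segments: dict


def fixture_suite(seed: int = 0) -> dict[str, Fixture]:
    """Deterministic preset bundle covering clean, narrow-band, wide
    arcuate and quadrant fields; each fixture carries the analytic
    containment intervals of the default trajectory as its oracle."""
    geom = ScreenGeometry()
    spec = StimulusSpec()
    trajectory = tuple(build_screening_trajectory(geom))
    bundle: dict[str, Fixture] = {}
    from .field_model import PRESET_NAMES

    for name in PRESET_NAMES:
        field = make_preset_field(name)
        obs = ObserverParams(rng_seed=seed)
        expected = analytic_scotoma_segments(field, trajectory, geom, spec)
        bundle[name] = Fixture(name, field, obs, trajectory, expected)
    return bundle
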