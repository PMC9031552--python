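"""Execution of screening runs and scotoma delineation.

The engine advances the dot centre frame by frame along each straight
screen-space path (constant linear speed: speed/frame_rate centimetres
per frame), re-evaluates the eccentricity-dependent dot diameter every
frame, asks the simulated observer for visibility, and turns the
resulting timeline into OFF/ON events and paired scotoma segments — the
grey lines of the screening printout.

Delineation reruns vertical sweeps at a reduced speed (divisor 4 or 8)
across a window around a detected segment; each sweep contributes a pair
of boundary crossings (the event positions corrected by the effective
dot radius), from which a closed outline of the defect is reconstructed.
Slowing the dot shrinks the positional error contributed by response
latency (error = latency x speed), which is the entire point of the
reduced-speed mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import shapely

from .errors import ConfigurationError, DomainError, MalformedStreamError
from .field_model import (
    DepthKind,
    OUTER_SAMPLE_FRACTION,
    VisualFieldMap,
    disc_coverage_fractions,
)
from .geometry import (
    FieldPoint,
    PathSpec,
    ScreenGeometry,
    StimulusSpec,
    angular_diameter_deg,
    build_screening_trajectory,
    deg_to_cm,
)
from .observer import OFF, ON, ObserverParams, respond

__all__ = [
    "ExamEvent",
    "ScotomaSegment",
    "ExamRecord",
    "BoundaryCrossing",
    "DelineationResult",
    "run_screening",
    "run_delineation",
    "pair_events",
    "DEFAULT_MIN_INVISIBLE_FRAMES",
]

#: Minimum number of consecutive invisible frames for a disappearance to be
#: recorded.  At the screening speed a narrow (~0.35 deg) band conceals the
#: dot for only about one frame, so the default keeps single-frame events;
#: raise to 2 to debounce flicker at region edges when simulating noisy
#: rendering.
DEFAULT_MIN_INVISIBLE_FRAMES = 1


@dataclass(frozen=True)
class ExamEvent:
    """An observer event placed on its path in field coordinates."""

    path_index: int
    path_label: str
    frame: int  # global frame index of the perceptual transition
    time_s: float  # report time (includes latency)
    point: FieldPoint  # dot centre at the report time, clamped to the path
    kind: str  # OFF | ON


@dataclass(frozen=True)
class ScotomaSegment:
    """A paired OFF/ON: the grey line connecting scotoma entry and exit."""

    path_index: int
    path_label: str
    off_point: FieldPoint
    on_point: FieldPoint
    off_time_s: float
    on_time_s: float
    opened_at_path_start: bool = False
    closed_at_path_end: bool = False


@dataclass
class ExamRecord:
    """Complete result of a screening (or sweep) run.

    Frame arrays are parallel: time, position (degrees), dot diameter
    (mm and angular degrees) and the index of the path being swept.
    """

    geometry: ScreenGeometry
    stimulus: StimulusSpec
    observer: ObserverParams
    paths: tuple[PathSpec, ...]
    field_fingerprint: str
    field_eye: str
    frame_time_s: np.ndarray
    frame_x_deg: np.ndarray
    frame_y_deg: np.ndarray
    frame_diameter_mm: np.ndarray
    frame_diameter_deg: np.ndarray
    frame_path_index: np.ndarray
    events: tuple[ExamEvent, ...]
    segments: tuple[ScotomaSegment, ...]
    path_durations_s: tuple[float, ...]
    total_duration_s: float

    def duration_excluding_blind_spot_s(self) -> float:
        return sum(
            d
            for p, d in zip(self.paths, self.path_durations_s)
            if p.label != "blind_spot_line"
        )

    def segments_on(self, label: str) -> list[ScotomaSegment]:
        return [s for s in self.segments if s.path_label == label]


# --------------------------------------------------------------------------
# Frame-level machinery (shared by screening and delineation)
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class _PathFrames:
    t0_s: float
    duration_s: float
    speed_cm_s: float
    start_cm: tuple[float, float]
    end_cm: tuple[float, float]
    length_cm: float
    n_frames: int


def _sample_paths(paths, geom: ScreenGeometry, spec: StimulusSpec):
    """Frame positions/diameters for a path sequence, continuous in time."""
    d = geom.viewing_distance_cm
    metas: list[_PathFrames] = []
    xs, ys, ts, idx = [], [], [], []
    t_cursor = 0.0
    for i, p in enumerate(paths):
        x0, y0 = deg_to_cm(p.start, geom)
        x1, y1 = deg_to_cm(p.end, geom)
        if not (geom.contains_cm(x0, y0) and geom.contains_cm(x1, y1)):
            raise ConfigurationError(f"path {p.label!r} leaves the screen")
        length = math.hypot(x1 - x0, y1 - y0)
        v = spec.speed_cm_s / p.speed_divisor
        step = v / geom.frame_rate_hz
        n = int(math.floor(length / step + 1e-9)) + 1
        s = np.arange(n) * step
        xs.append(x0 + (x1 - x0) * s / length)
        ys.append(y0 + (y1 - y0) * s / length)
        ts.append(t_cursor + s / v)
        idx.append(np.full(n, i, dtype=int))
        metas.append(_PathFrames(t_cursor, length / v, v, (x0, y0), (x1, y1), length, n))
        t_cursor += length / v
    x_cm = np.concatenate(xs)
    y_cm = np.concatenate(ys)
    x_deg = np.degrees(np.arctan(x_cm / d))
    y_deg = np.degrees(np.arctan(y_cm / d))
    ecc = np.hypot(x_deg, y_deg)
    diam_mm = np.clip(
        spec.d0_mm + spec.slope_mm_per_deg * ecc, spec.d0_mm, spec.d15_mm
    )
    diam_deg = angular_diameter_deg(diam_mm, geom)
    return (
        metas,
        np.concatenate(ts),
        x_deg,
        y_deg,
        diam_mm,
        np.asarray(diam_deg),
        np.concatenate(idx),
        t_cursor,
    )


def _debounce(invisible: np.ndarray, min_frames: int) -> np.ndarray:
    """Suppress invisible runs shorter than ``min_frames``."""
    if min_frames <= 1 or not invisible.any():
        return invisible
    out = invisible.copy()
    n = out.size
    i = 0
    while i < n:
        if out[i]:
            j = i
            while j < n and out[j]:
                j += 1
            if j - i < min_frames:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


def _point_on_path(meta: _PathFrames, t_s: float, geom: ScreenGeometry) -> FieldPoint:
    """Dot centre at absolute time ``t_s``, clamped to the path extent."""
    s = min(max((t_s - meta.t0_s) * meta.speed_cm_s, 0.0), meta.length_cm)
    frac = s / meta.length_cm
    x = meta.start_cm[0] + (meta.end_cm[0] - meta.start_cm[0]) * frac
    y = meta.start_cm[1] + (meta.end_cm[1] - meta.start_cm[1]) * frac
    d = geom.viewing_distance_cm
    return FieldPoint(math.degrees(math.atan(x / d)), math.degrees(math.atan(y / d)))


def _run_paths(
    field: VisualFieldMap,
    obs: ObserverParams,
    paths: Sequence[PathSpec],
    geom: ScreenGeometry,
    spec: StimulusSpec,
    min_invisible_frames: int,
    rng: np.random.Generator,
):
    metas, t, x_deg, y_deg, diam_mm, diam_deg, path_idx, total = _sample_paths(
        paths, geom, spec
    )
    centers = np.column_stack([x_deg, y_deg])
    fractions = disc_coverage_fractions(
        field, centers, diam_deg / 2.0, DepthKind.ABSOLUTE
    )
    invisible = fractions >= obs.containment_threshold - 1e-12

    events: list[ExamEvent] = []
    offset = 0
    for i, (p, meta) in enumerate(zip(paths, metas)):
        inv = _debounce(invisible[offset : offset + meta.n_frames], min_invisible_frames)
        vis = ~inv
        for ev in respond(vis, obs, geom.frame_rate_hz, t0_s=meta.t0_s, rng=rng):
            events.append(
                ExamEvent(
                    path_index=i,
                    path_label=p.label,
                    frame=offset + ev.frame,
                    time_s=ev.time_s,
                    point=_point_on_path(meta, ev.time_s, geom),
                    kind=ev.kind,
                )
            )
        offset += meta.n_frames
    segments = pair_events(
        events, paths, path_spans=[(m.t0_s, m.t0_s + m.duration_s) for m in metas]
    )
    frames = (t, x_deg, y_deg, diam_mm, np.asarray(diam_deg), path_idx)
    durations = tuple(m.duration_s for m in metas)
    return frames, tuple(events), segments, durations, total


# --------------------------------------------------------------------------
# Event pairing
# --------------------------------------------------------------------------


def pair_events(
    events: Sequence[ExamEvent],
    trajectory: Sequence[PathSpec],
    path_spans: Sequence[tuple[float, float]] | None = None,
) -> tuple[ScotomaSegment, ...]:
    """Pair OFF/ON events into scotoma segments, per path.

    An unmatched OFF at the end of a path closes at the path endpoint; an
    unmatched ON at the start of a path opens at the path's start.  Two
    consecutive OFFs on one path violate the alternation grammar and raise
    :class:`MalformedStreamError`.
    """
    segments: list[ScotomaSegment] = []
    for i, path in enumerate(trajectory):
        path_events = sorted(
            (e for e in events if e.path_index == i), key=lambda e: e.time_s
        )
        open_off: ExamEvent | None = None
        for e in path_events:
            if e.kind == OFF:
                if open_off is not None:
                    raise MalformedStreamError(
                        f"two consecutive OFF events on path {path.label!r}"
                    )
                open_off = e
            elif e.kind == ON:
                if open_off is None:
                    # reappearance without disappearance: segment opens at
                    # the path start
                    t0 = path_spans[i][0] if path_spans else math.nan
                    segments.append(
                        ScotomaSegment(
                            i,
                            path.label,
                            off_point=path.start,
                            on_point=e.point,
                            off_time_s=t0,
                            on_time_s=e.time_s,
                            opened_at_path_start=True,
                        )
                    )
                else:
                    segments.append(
                        ScotomaSegment(
                            i,
                            path.label,
                            off_point=open_off.point,
                            on_point=e.point,
                            off_time_s=open_off.time_s,
                            on_time_s=e.time_s,
                        )
                    )
                    open_off = None
            else:
                raise MalformedStreamError(f"unknown event kind {e.kind!r}")
        if open_off is not None:
            t1 = path_spans[i][1] if path_spans else math.nan
            segments.append(
                ScotomaSegment(
                    i,
                    path.label,
                    off_point=open_off.point,
                    on_point=path.end,
                    off_time_s=open_off.time_s,
                    on_time_s=t1,
                    closed_at_path_end=True,
                )
            )
    return tuple(segments)


# --------------------------------------------------------------------------
# Screening
# --------------------------------------------------------------------------


def run_screening(
    field: VisualFieldMap,
    obs: ObserverParams | None = None,
    trajectory: Sequence[PathSpec] | None = None,
    geom: ScreenGeometry | None = None,
    spec: StimulusSpec | None = None,
    min_invisible_frames: int = DEFAULT_MIN_INVISIBLE_FRAMES,
) -> ExamRecord:
    """Run the full screening trajectory against a field and observer.

    Frames are sampled at the geometry's frame rate; the dot diameter is
    re-evaluated every frame from the current eccentricity.  On a clean
    field the only segment is the blind-spot crossing.
    """
    geom = geom if geom is not None else ScreenGeometry()
    spec = spec if spec is not None else StimulusSpec()
    obs = obs if obs is not None else ObserverParams()
    paths = (
        tuple(trajectory)
        if trajectory is not None
        else tuple(build_screening_trajectory(geom))
    )
    rng = np.random.default_rng(obs.rng_seed)
    frames, events, segments, durations, total = _run_paths(
        field, obs, paths, geom, spec, min_invisible_frames, rng
    )
    t, x_deg, y_deg, diam_mm, diam_deg, path_idx = frames
    return ExamRecord(
        geometry=geom,
        stimulus=spec,
        observer=obs,
        paths=paths,
        field_fingerprint=field.fingerprint(),
        field_eye=field.eye,
        frame_time_s=t,
        frame_x_deg=x_deg,
        frame_y_deg=y_deg,
        frame_diameter_mm=diam_mm,
        frame_diameter_deg=diam_deg,
        frame_path_index=path_idx,
        events=events,
        segments=segments,
        path_durations_s=durations,
        total_duration_s=total,
    )


# --------------------------------------------------------------------------
# Delineation
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BoundaryCrossing:
    """One slow sweep's crossing of a defect: the sweep abscissa and the
    radius-corrected lower/upper boundary estimates (degrees)."""

    x_deg: float
    y_lower_deg: float
    y_upper_deg: float

    @property
    def width_deg(self) -> float:
        return self.y_upper_deg - self.y_lower_deg


@dataclass
class DelineationResult:
    """Reconstructed defect outline from reduced-speed vertical sweeps."""

    segment: ScotomaSegment
    divisor: int
    sweep_step_deg: float
    sweep_window: tuple[float, float, float, float]  # xmin, xmax, ymin, ymax
    crossings: tuple[BoundaryCrossing, ...]
    outline_deg: np.ndarray  # closed polyline, shape (n, 2); empty if no crossings
    sweeps: tuple[PathSpec, ...]

    def width_estimates_deg(self) -> np.ndarray:
        return np.array([c.width_deg for c in self.crossings])

    def boundary_points(self) -> np.ndarray:
        pts = [(c.x_deg, c.y_lower_deg) for c in self.crossings]
        pts += [(c.x_deg, c.y_upper_deg) for c in self.crossings]
        return np.array(pts) if pts else np.empty((0, 2))

    def mean_boundary_distance_deg(self, boundary) -> float:
        """Mean distance of the recovered crossing points to a ground-truth
        boundary (any shapely geometry, e.g. ``polygon.boundary``)."""
        pts = self.boundary_points()
        if pts.size == 0:
            raise DomainError("no crossings recovered")
        return float(
            np.mean([boundary.distance(shapely.Point(p)) for p in pts])
        )


def run_delineation(
    field: VisualFieldMap,
    obs: ObserverParams | None = None,
    segment: ScotomaSegment | None = None,
    geom: ScreenGeometry | None = None,
    spec: StimulusSpec | None = None,
    divisor: int = 8,
    sweep_step_deg: float = 0.5,
    pad_deg: float = 2.0,
    min_invisible_frames: int = DEFAULT_MIN_INVISIBLE_FRAMES,
    exam: ExamRecord | None = None,
) -> DelineationResult:
    """Delineate the defect around a screening segment with slow vertical
    sweeps (kinetic-perimetry style).

    Sweeps run bottom-to-top at ``speed/divisor``, spaced ``sweep_step_deg``
    across the segment's bounding box padded by ``pad_deg`` on each side.
    Each OFF/ON pair on a sweep yields a :class:`BoundaryCrossing` whose
    lower/upper estimates are the event centres pushed outward by the
    effective sampled dot radius (the rim the examiner marks).  If ``exam``
    is given, ``segment`` must be one of its segments.
    """
    if segment is None:
        raise DomainError("a screening segment to delineate is required")
    if divisor < 1:
        raise DomainError("divisor must be >= 1")
    if sweep_step_deg <= 0:
        raise DomainError("sweep_step_deg must be > 0")
    if exam is not None and segment not in exam.segments:
        raise DomainError("segment does not belong to the supplied exam")
    geom = geom if geom is not None else ScreenGeometry()
    spec = spec if spec is not None else StimulusSpec()
    obs = obs if obs is not None else ObserverParams()

    xs = (segment.off_point.x_deg, segment.on_point.x_deg)
    ys = (segment.off_point.y_deg, segment.on_point.y_deg)
    xmin, xmax = min(xs) - pad_deg, max(xs) + pad_deg
    ymin, ymax = min(ys) - pad_deg, max(ys) + pad_deg
    n_sweeps = int(math.floor((xmax - xmin) / sweep_step_deg + 1e-9)) + 1
    sweeps = tuple(
        PathSpec(
            f"sweep_{k}",
            FieldPoint(xmin + k * sweep_step_deg, ymin),
            FieldPoint(xmin + k * sweep_step_deg, ymax),
            speed_divisor=divisor,
        )
        for k in range(n_sweeps)
    )
    rng = np.random.default_rng(obs.rng_seed)
    _, _, sweep_segments, _, _ = _run_paths(
        field, obs, sweeps, geom, spec, min_invisible_frames, rng
    )

    crossings: list[BoundaryCrossing] = []
    for s in sweep_segments:
        if s.opened_at_path_start or s.closed_at_path_end:
            continue  # partial crossing: no reliable boundary on that side
        r_off = _effective_radius_deg(s.off_point, geom, spec)
        r_on = _effective_radius_deg(s.on_point, geom, spec)
        crossings.append(
            BoundaryCrossing(
                x_deg=s.off_point.x_deg,
                y_lower_deg=s.off_point.y_deg - r_off,
                y_upper_deg=s.on_point.y_deg + r_on,
            )
        )
    crossings.sort(key=lambda c: c.x_deg)
    if crossings:
        lower = [(c.x_deg, c.y_lower_deg) for c in crossings]
        upper = [(c.x_deg, c.y_upper_deg) for c in reversed(crossings)]
        outline = np.array(lower + upper + [lower[0]])
    else:
        outline = np.empty((0, 2))
    return DelineationResult(
        segment=segment,
        divisor=divisor,
        sweep_step_deg=sweep_step_deg,
        sweep_window=(xmin, xmax, ymin, ymax),
        crossings=tuple(crossings),
        outline_deg=outline,
        sweeps=sweeps,
    )


def _effective_radius_deg(
    p: FieldPoint, geom: ScreenGeometry, spec: StimulusSpec
) -> float:
    """Angular radius of the outermost containment sample at a position —
    the offset between the dot centre at an OFF/ON event and the scotoma
    rim it marks."""
    diam = angular_diameter_deg(spec.diameter_mm(p.eccentricity_deg()), geom)
    return OUTER_SAMPLE_FRACTION * diam / 2.0
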