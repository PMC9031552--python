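"""Simulated patient: visibility judgements and timed button events.

The response rule is deliberately simple and geometric: the moving dot is
invisible exactly while it is wholly contained in an absolute scotoma
(relative scotomas dim it — "a brightness difference is perceived" — but
never extinguish it, so they produce no OFF event; perceived dimming is
metadata, not part of the event grammar).  On top of that hard rule sit
optional human imperfections: a truncated-Gaussian response latency,
lapses (a disappearance missed entirely, which elides the OFF *and* its
ON), and false alarms.  With all of these at their zero defaults the
observer is an exact change-point detector and the whole pipeline is
deterministic without seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DomainError
from .field_model import DepthKind, VisualFieldMap, disc_coverage_fraction
from .geometry import FieldPoint

__all__ = ["ObserverParams", "ObserverEvent", "visible", "respond", "OFF", "ON"]

OFF = "OFF"
ON = "ON"


@dataclass(frozen=True)
class ObserverParams:
    """Simulated-observer parameters.

    containment_threshold is the disc-coverage fraction (of absolute
    regions) at which the dot disappears; the default 1.0 means the dot is
    invisible only when fully inside an absolute region.  Latency is drawn
    per event from a Gaussian truncated at zero.  ``lapse_rate`` is the
    per-disappearance probability of missing it entirely;
    ``false_alarm_rate`` a per-frame probability of a spurious one-frame
    blink report while the dot is visible.
    """

    containment_threshold: float = 1.0
    latency_mean_s: float = 0.0
    latency_sd_s: float = 0.0
    lapse_rate: float = 0.0
    false_alarm_rate: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.containment_threshold <= 1.0:
            raise ConfigurationError("containment_threshold must lie in (0, 1]")
        for name in ("lapse_rate", "false_alarm_rate"):
            if not 0.0 <= getattr(self, name) < 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1)")
        if self.latency_sd_s < 0 or self.latency_mean_s < 0:
            raise ConfigurationError("latency parameters must be >= 0")

    @property
    def is_deterministic(self) -> bool:
        return (
            self.latency_sd_s == 0.0
            and self.lapse_rate == 0.0
            and self.false_alarm_rate == 0.0
        )


@dataclass(frozen=True)
class ObserverEvent:
    """A button event: the perceptual transition frame and the (possibly
    latency-delayed) report time."""

    frame: int
    time_s: float
    kind: str  # OFF | ON


def visible(
    field: VisualFieldMap,
    obs: ObserverParams,
    center: FieldPoint,
    diameter_deg: float,
) -> bool:
    """Whether the dot at ``center`` is seen.

    Invisible iff the fraction of the disc inside absolute regions reaches
    the containment threshold; deterministic (lapses/false alarms only act
    on the event stream, not on single judgements).
    """
    frac = disc_coverage_fraction(field, center, diameter_deg, DepthKind.ABSOLUTE)
    return frac < obs.containment_threshold - 1e-12


def respond(
    visibility_timeline: Sequence[bool] | np.ndarray,
    obs: ObserverParams,
    frame_rate_hz: float = 60.0,
    t0_s: float = 0.0,
    rng: np.random.Generator | None = None,
) -> list[ObserverEvent]:
    """Convert a frame-sampled visibility timeline into OFF/ON events.

    OFF is emitted at each visible->invisible transition, ON at each
    invisible->visible transition; a timeline that starts invisible emits
    no initial OFF (the downstream pairing rule opens such a segment at
    the path start) and one that ends invisible leaves its OFF unmatched.
    Each event time is the transition frame time plus a latency draw.
    Lapses delete a disappearance pairwise (an elided OFF elides its ON).
    Random draws occur in a fixed order so a fixed seed yields a
    bit-identical stream.
    """
    if frame_rate_hz <= 0:
        raise DomainError("frame rate must be > 0")
    vis = np.asarray(visibility_timeline, dtype=bool)
    if vis.size == 0:
        return []
    if rng is None:
        rng = np.random.default_rng(obs.rng_seed)
    dt = 1.0 / frame_rate_hz

    def latency() -> float:
        if obs.latency_mean_s == 0.0 and obs.latency_sd_s == 0.0:
            return 0.0
        return max(0.0, float(rng.normal(obs.latency_mean_s, obs.latency_sd_s)))

    events: list[ObserverEvent] = []
    # invisible runs: (start_frame, end_frame_exclusive or None if unclosed)
    flips = np.flatnonzero(np.diff(vis.astype(np.int8)))
    starts = [int(i) + 1 for i in flips if vis[i] and not vis[i + 1]]
    ends = [int(i) + 1 for i in flips if not vis[i] and vis[i + 1]]
    if not vis[0]:
        # timeline opens invisible: the first reappearance is an unmatched ON
        pass
    for start in starts:
        end = next((e for e in ends if e > start), None)
        if obs.lapse_rate > 0.0 and rng.random() < obs.lapse_rate:
            continue  # disappearance missed: OFF and its ON both elided
        t_off = t0_s + start * dt + latency()
        events.append(ObserverEvent(start, t_off, OFF))
        if end is not None:
            t_on = max(t_off, t0_s + end * dt + latency())
            events.append(ObserverEvent(end, t_on, ON))
    if not vis[0] and ends:
        first_on = ends[0]
        events.insert(0, ObserverEvent(first_on, t0_s + first_on * dt + latency(), ON))
    if obs.false_alarm_rate > 0.0:
        u = rng.random(vis.size)
        for i in np.flatnonzero((u < obs.false_alarm_rate) & vis)[:]:
            i = int(i)
            if i + 1 < vis.size and vis[i + 1]:
                t = t0_s + i * dt + latency()
                events.append(ObserverEvent(i, t, OFF))
                events.append(ObserverEvent(i + 1, max(t, t0_s + (i + 1) * dt), ON))
    events.sort(key=lambda e: (e.time_s, e.frame, 0 if e.kind == OFF else 1))
    return events
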