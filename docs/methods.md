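# Methods

This note records the model behind `rapidcamp`, the defaults and why they
were chosen, and what the simulation does and does not establish about
real exams.

## Screen geometry

All field positions are degrees of visual angle in a right-eye frame
(+x temporal, +y superior); left eyes are mirrored only when rendering or
exporting. The screen mapping is the separable per-axis tangent
projection, x_cm = D·tan(x°) (and likewise y), with the fixation point at
the screen origin. A radial gnomonic projection differs from this choice
only off-axis; the separable form is what makes the ±10° square have edge
2·D·tan(10°) ≈ 14.1 cm at the default D = 40 cm, consistent with every
other printed dimension the defaults reproduce. Conversions are exact
inverses of each other (round-trip error below 1e-9°).

Angular stimulus size uses the small-angle conversion d/D rather than an
eccentricity-corrected (cos²-foreshortened) subtense: it is the
convention under which the reference size ladder's angle column is
reproduced (2.72 mm → 0.39°, 2.17 mm → 0.31°). The single exception is
the ladder's 0° row, which prints 0.16° where d/D gives 0.150°; we treat
that as a rounding anomaly of the source table and exclude the 0° angle
entry from exact checks.

The flat screen slows the dot's *angular* speed off-axis by cos²(ecc) —
about 3% at 10° — which is small enough to ignore, and
`angular_speed_ratio` exposes the number behind that judgement.

## Stimulus

The dot diameter is linear in eccentricity, d(e) = d0 + (d15−d0)/15 · e,
clamped to [d0, d15], with the exact achieved endpoints d0 = 1.05 mm and
d15 = 2.72 mm (slope ≈ 0.1113 mm/°, not the rounded 0.11). Luminances
(140 / 0.8 cd/m²) and the 1.39° fixation cross are carried as metadata
only; nothing is physically rendered. The default speed is 3 cm/s at
40 cm, constant *linear* speed along straight screen-space lines, with a
legal range of 0.18–24 cm/s (the extremes at which detection degrades).
Frames advance the dot by speed/frame_rate = 0.05 cm at the default
60 Hz.

## Screening trajectory

The line placement is configurable (`TrajectoryLayout`); the default is
back-solved from the reference coverage table and total length: verticals
spanning ±10° at x = 10°, 6.5°, 2.5° temporal (labelled outermost-first so
their thickness extremes line up with the table's rows), two 7.44 cm
diagonals at ±45° in the nasal half starting near 3.1° eccentricity, two
5.6 cm horizontals at y = ±3.2°, and a blind-spot pass at 15° temporal
spanning ±7° (enough to cross the blind spot with margin; not a printed
value). The seven central paths total 68.4 cm → 22.8 s at 3 cm/s,
within the specified <30 s; including the blind-spot pass the run is
26.1 s.

`path_pixel_count` rasterizes the continuous centre path by quarter-pixel
arc-length sampling (a supercover: every cell the centre passes through is
counted once, with a half-open convention at each path end). A full-width
21.4 cm sweep at 442 px yields exactly 442 cells; the default seven-path
trajectory yields 1324 distinct cells. Note that lines at exactly ±45°
through the grid origin cross pixel corners, where the supercover
degenerates to one cell per step — the count is therefore closer to the
path length × linear density (~1413) than twice it.

## Coverage model

The strip swept by the growing dot along a path is approximated by two
congruent trapezoids, i.e. a rectangle of width (thickest + thinnest
diameter) and length half the run: area = (a+b)·h. On the reference
per-path inputs this totals 13.43 cm² of the 198.81 cm² (14.1 cm)²
square — 6.75% of the paracentral field. The same accounting for static
perimetry is n·(4 mm²)/area: 68 points over the 87.58 cm² central disc
(radius 5.28 cm at 30 cm) cover 3.1%, and 17 points cover <1%. The
reference table's printed rows are shipped as constants *and* re-derivable
from any layout via `path_coverage_rows`, so coverage is reproducible
independent of line placement (the printed rows are rounded to 2 dp;
derived values agree to ~0.01 cm).

## Ground-truth fields

Regions are shapely polygons in degree space. The blind spot is an
ellipse at (15°, −1.5°) with semi-axes (2.75°, 3.75°). Arcuate defects
are constant-width bands along circular arcs; the nerve-fibre constructor
places the arc centre on the vertical meridian's extension and forces the
arc through the blind-spot centre, crossing the vertical meridian at a
chosen eccentricity (default 8°, the Bjerrum region) and ending at the
nasal horizontal raphe. This is a deliberate geometric simplification of
retinal fibre anatomy — no axon-map model is attempted. Depth classes are
ordered NORMAL < RELATIVE < ABSOLUTE and classification is total and
deterministic, deepest class winning on overlap (ties toward larger
attenuation), so region order never matters.

Disc containment — the primitive behind every visibility question — is
evaluated on a fixed polar grid: 16 equal-area (midpoint-radius) rings ×
32 spokes + centre = 513 samples. Determinism was chosen over Monte
Carlo so containment tests need no seeds and tolerances can be stated:
the sampler's outermost ring sits at √(15.5/16) ≈ 0.984 of the disc
radius, so "fully contained" on the sampler equals geometric containment
of a disc shrunk by that factor (to within the inter-spoke sag, <0.005 of
the radius). The delineation rim correction uses exactly this effective
radius.

## Observer

Visibility is a hard containment rule: invisible iff the covered fraction
of the disc inside absolute regions reaches `containment_threshold`
(default 1.0). Relative regions never extinguish the dot. Latency is
Gaussian truncated at zero (no reaction-time model is prescribed by the
method; Gaussian is the conventional default), applied per event; lapses
remove a disappearance pairwise (an unreported OFF removes its ON);
false alarms inject one-frame blinks. All default to zero.

## Exam engine

Events are emitted at visibility transition frames; event *positions* are
the dot centre at the (latency-shifted) report time, clamped to the path.
An optional debounce suppresses invisible runs shorter than
`min_invisible_frames`. The default is 1 (no suppression): at 3 cm/s and
60 Hz the full-containment window of the ~0.3° dot inside a 0.35° band is
about one frame step (0.05 cm), so a single dark frame *is* the narrow-
scotoma signal, and suppressing it would blind the method to precisely
the defect it exists to find. A 17 ms gap in an otherwise continuous
motion trace is treated as perceptible, consistent with the high-contrast
design of the test; set `min_invisible_frames=2` to model an observer who
misses single-frame blinks.

Unpaired events are resolved conservatively: an OFF still open at a
path's end closes at the path endpoint; an ON without a preceding OFF
opens at the path start. Two consecutive OFFs on one path are a grammar
violation and raise an error.

Delineation re-sweeps vertically at speed/divisor (4 or 8) across the
segment's bounding box padded by 2° on each side, at 0.5° sweep spacing
(the sweep window and spacing are artifact choices — the procedure's
source does not state them). Each complete OFF/ON pair on a sweep gives a
boundary crossing; the recorded rim positions are the event centres
pushed outward along the sweep by the effective sampled dot radius, which
removes the dot-size bias from the recovered boundary. With a zero-noise
observer the residual error is frame quantization (~0.009° at divisor 8)
plus obliquity of the crossing; under latency ℓ the boundary shifts by
ℓ·speed/divisor, which is why divisor 8 beats divisor 1 by ~8× at
ℓ = 0.2 s.

## Static-perimetry proxy

The 10-2 grid is the odd lattice x, y ∈ {±1, …, ±9} under x²+y² ≤ 82 —
the unique odd-lattice radius cutoff with exactly 68 points (the grid's
coordinates are not printed in clinical sources; 2° spacing offset 1°
from the meridians is standard). Classification is purely geometric:
ABSOLUTE_DEFECT iff the 0.43° stimulus disc is fully contained in
absolute regions, RELATIVE_DEFECT on partial overlap or a centre inside a
relative region, NORMAL otherwise. No staircases or dB thresholds are
modelled: the kinetic-vs-static comparison this package reproduces is a
containment argument, and adding threshold psychophysics would only
obscure it. The discordance window follows directly: a band of width w
with 0.31 ≲ w < 0.43° swallows the kinetic dot at 10° eccentricity but
never the static stimulus.

## Problem sizes and runtime

The default screening run is ~1 570 frames; a divisor-8 delineation of
one segment is 9 sweeps of ~470 frames. Containment is evaluated in bulk
(short-circuiting frames far from any absolute region), so a screening
run takes ~0.1 s and the full test suite under a minute on one core.

## What passing tests do and do not show

The synthetic generator emulates the *geometry* of clinical defects —
widths, depth classes, arc anchoring — not their physiology. Passing
tests demonstrate that the method's detection claims hold as geometric
facts under an idealized observer: they say nothing about fixation
stability, attention, luminance calibration, media opacity or response
variability in real patients, all of which the observer model only
caricatures (latency/lapse/false-alarm). Eye tracking and threshold
perimetry algorithms are out of scope. Presets are qualitative
emulations of drawn clinical figures, not digitizations.
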