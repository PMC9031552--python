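# rapidcamp

Simulation engine for **rapid campimetry** — a fast, high-contrast kinetic
screening test of the central 10° visual field on an ordinary flat screen.

## The problem

Standard automated perimetry (SAP, e.g. the Humphrey 10-2 program) probes
the central field with 68 briefly flashed static stimuli of fixed size
(Goldmann III, 4 mm² ≈ 0.43°). Two structural limits follow: the stimuli
sample only ~3% of the central field area, and a stimulus can only vanish
*completely* — read out as an absolute defect — if it fits wholly inside
the scotoma. Narrow arcuate (Bjerrum) defects of early glaucoma can be
thinner than 0.43°, so SAP reports them as relative at best, or misses
them.

Rapid campimetry replaces the static grid with a single bright dot
(140 cd/m² on a 0.8 cd/m² background) that sweeps the central field at
≈3 cm/s along seven vertical, diagonal and horizontal screen lines (plus
one pass through the blind spot), completing in under 30 s. The dot's
diameter grows linearly with eccentricity from 1.05 mm (0.16°) at fixation
to 2.72 mm (0.39°) at 15° — matching the retina's falling resolution — so
at 10° it subtends only 0.31° and *can* disappear inside a 0.35° band.
The subject reports each disappearance (OFF) and reappearance (ON); the
OFF/ON pair delineates the scotoma along the path, and a slow re-sweep
(speed divided by 4 or 8) traces its boundary.

This package implements that method end to end as a deterministic,
testable simulation:

* `rapidcamp.geometry` — tangent-screen projection (x_cm = D·tan x°),
  eccentricity-dependent stimulus sizing, pixel rasterization, traversal
  timing, and the trapezoid coverage model: each swept strip ≈ a rectangle
  of width (thickest + thinnest dot diameter) × half the run length.
* `rapidcamp.field_model` — synthetic ground-truth fields: blind-spot
  ellipse, circular-arc nerve-fibre bands (absolute or relative, any
  width), quadrant wedges; disc containment on a fixed 513-point polar
  sampler.
* `rapidcamp.observer` — simulated patient: hard containment visibility
  rule, optional response latency, lapses and false alarms (all zero by
  default, making the pipeline seed-free).
* `rapidcamp.exam_engine` — frame-by-frame (60 Hz) screening and
  reduced-speed delineation, OFF/ON event pairing into scotoma segments.
* `rapidcamp.sap_sim` — a geometric 10-2 proxy (68-point grid, 0.43°
  stimulus, containment-based classification) for method comparison.
* `rapidcamp.io_report` — JSON/CSV serialization, SVG exam printouts,
  analytic segment oracles and fixture bundles.

## Worked example

```python
import rapidcamp as rc

field = rc.make_preset_field("narrow_arcuate_035")   # 0.35°-wide absolute band
exam  = rc.run_screening(field, rc.ObserverParams()) # zero-noise observer

print(f"{exam.total_duration_s:.1f} s")
for s in exam.segments:
    print(s.path_label, (s.off_point.x_deg, s.off_point.y_deg),
          (s.on_point.x_deg, s.on_point.y_deg))
```

prints (coordinates in degrees, temporal = +x):

```
screening duration: 26.1 s (22.8 s excluding the blind-spot pass)
  blind_spot_line  OFF (+15.00, +2.02)  ON (+15.00, -5.13)
  vertical_1       OFF (+10.00, +4.64)  ON (+10.00, +4.71)
  vertical_3       OFF (+2.50, +7.82)  ON (+2.50, +7.90)
  diagonal_1       OFF (-6.62, +6.62)  ON (-6.67, +6.67)
```

The dot vanished into the blind spot (as it should) and blinked off/on
where the verticals and a diagonal cross the narrow band. The simulated
10-2 exam on the same field sees it differently:

```python
static = rc.simulate_static_exam(field)
# -> 0 absolute, 2 relative defect points
```

because the 0.43° static stimulus cannot fit inside a 0.35° band — the
defect that kinetic screening proves absolute is at most relative to SAP.
Slow delineation then recovers the band's true width:

```python
seg = next(s for s in exam.segments if s.path_label == "vertical_3")
res = rc.run_delineation(field, rc.ObserverParams(), seg, divisor=8)
# -> 9 boundary crossings, mean recovered width 0.354° (true 0.35°)
```

The same workflow is available from the shell:

```bash
rapidcamp make-field --preset narrow_arcuate_035 --out field.json
rapidcamp screen --field field.json --out exam.json --svg exam.svg
rapidcamp delineate --field field.json --exam exam.json --segment-index 1 --out outline.json
rapidcamp sap --field field.json --out sap.csv
rapidcamp compare --field field.json --exam exam.json --out report.json
rapidcamp coverage-report --out coverage.csv
```

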