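"""Tangent projection, stimulus sizing, rasterization and coverage model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import rapidcamp as rc
from rapidcamp.errors import ConfigurationError, DomainError
from rapidcamp.geometry import (
    REFERENCE_COVERAGE_INPUTS,
    REFERENCE_SQUARE_AREA_CM2,
    TrajectoryLayout,
    path_coverage_rows,
    trajectory_screen_length_cm,
)

# printed size ladder: eccentricity -> (diameter mm, angular diameter deg)
SIZE_LADDER = [
    (0.0, 1.05, None),  # the 0-deg angular entry is a printed rounding anomaly
    (1.0, 1.16, 0.17),
    (2.5, 1.33, 0.19),
    (5.0, 1.61, 0.23),
    (7.5, 1.88, 0.27),
    (10.0, 2.17, 0.31),
    (12.5, 2.45, 0.35),
    (15.0, 2.72, 0.39),
]


class TestProjection:
    def test_ten_degrees_maps_to_half_the_square_edge(self, geom):
        x, y = rc.deg_to_cm(rc.FieldPoint(10.0, 0.0), geom)
        assert x == pytest.approx(7.05, abs=0.01)
        assert y == 0.0
        assert geom.tested_region_edge_cm(10.0) == pytest.approx(14.1, abs=0.01)

    def test_fixation_maps_to_origin(self, geom):
        assert rc.deg_to_cm(rc.FieldPoint(0.0, 0.0), geom) == (0.0, 0.0)

    def test_fifteen_degrees(self, geom):
        x, _ = rc.deg_to_cm(rc.FieldPoint(15.0, 0.0), geom)
        assert x == pytest.approx(40 * math.tan(math.radians(15)), abs=1e-12)
        assert x == pytest.approx(10.72, abs=0.005)

    def test_inverse_of_printed_example(self, geom):
        p = rc.cm_to_deg((7.05, 0.0), geom)
        assert p.x_deg == pytest.approx(9.995, abs=0.005)
        assert p.y_deg == 0.0

    def test_rejects_angles_at_or_beyond_90(self, geom):
        with pytest.raises(DomainError):
            rc.deg_to_cm(rc.FieldPoint(90.0, 0.0), geom)

    @settings(deadline=None, max_examples=100)
    @given(
        x=st.floats(-20, 20, allow_nan=False),
        y=st.floats(-20, 20, allow_nan=False),
    )
    def test_roundtrip_within_nanodegrees(self, x, y):
        geom = rc.ScreenGeometry()
        p = rc.FieldPoint(x, y)
        q = rc.cm_to_deg(rc.deg_to_cm(p, geom), geom)
        assert abs(q.x_deg - x) <= 1e-9
        assert abs(q.y_deg - y) <= 1e-9

    def test_eccentricity(self):
        assert rc.eccentricity_deg(rc.FieldPoint(3, 4)) == 5.0
        assert rc.eccentricity_deg(rc.FieldPoint(0, 0)) == 0.0
        assert rc.eccentricity_deg(rc.FieldPoint(10, 10)) == pytest.approx(
            math.sqrt(200), abs=1e-12
        )


class TestDotSize:
    @pytest.mark.parametrize("ecc,diam,_", SIZE_LADDER)
    def test_size_ladder_diameters(self, ecc, diam, _, stim):
        assert rc.dot_diameter_mm(ecc, stim) == pytest.approx(diam, abs=0.03)

    @pytest.mark.parametrize(
        "ecc,diam,angle", [row for row in SIZE_LADDER if row[2] is not None]
    )
    def test_size_ladder_angles(self, ecc, diam, angle, geom):
        assert rc.angular_diameter_deg(diam, geom) == pytest.approx(angle, abs=0.015)

    def test_exact_endpoints(self, stim):
        assert rc.dot_diameter_mm(0.0, stim) == 1.05
        assert rc.dot_diameter_mm(15.0, stim) == 2.72
        # clamped beyond the blind-spot eccentricity
        assert rc.dot_diameter_mm(25.0, stim) == 2.72

    def test_midpoint_is_linear(self, stim):
        assert rc.dot_diameter_mm(7.5, stim) == pytest.approx(1.885, abs=1e-9)

    def test_monotone_nondecreasing(self, stim):
        ecc = np.linspace(0, 30, 301)
        d = rc.dot_diameter_mm(ecc, stim)
        assert np.all(np.diff(d) >= 0)
        assert d.min() == stim.d0_mm and d.max() == stim.d15_mm

    def test_angular_diameter_examples(self, geom):
        assert round(rc.angular_diameter_deg(2.72, geom), 2) == 0.39
        assert round(rc.angular_diameter_deg(2.17, geom), 2) == 0.31
        assert rc.angular_diameter_deg(0.0, geom) == 0.0

    def test_negative_eccentricity_rejected(self, stim):
        with pytest.raises(DomainError):
            rc.dot_diameter_mm(-1.0, stim)


class TestSpeedAndTiming:
    def test_angular_speed_ratio(self):
        assert rc.angular_speed_ratio(0.0) == 1.0
        assert rc.angular_speed_ratio(10.0) == pytest.approx(0.9698, abs=1e-4)
        # the flat-vs-curved velocity difference at 10 degrees is a few percent
        assert 0.02 <= 1.0 - rc.angular_speed_ratio(10.0) <= 0.05
        ratios = [rc.angular_speed_ratio(e) for e in np.linspace(0, 20, 41)]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))

    def test_traversal_time(self):
        assert rc.traversal_time_s(14.1, 3.0) == pytest.approx(4.7, abs=0.001)
        assert rc.traversal_time_s(0.0, 3.0) == 0.0
        with pytest.raises(DomainError):
            rc.traversal_time_s(1.0, 0.0)

    def test_default_trajectory_under_30_s(self, trajectory, geom):
        length = trajectory_screen_length_cm(trajectory, geom)
        assert 65.0 <= length <= 72.0
        assert rc.traversal_time_s(length, 3.0) < 30.0

    def test_speed_outside_legal_range_rejected(self):
        with pytest.raises(ConfigurationError):
            rc.StimulusSpec(speed_cm_s=30.0)
        with pytest.raises(ConfigurationError):
            rc.StimulusSpec(speed_cm_s=0.1)


class TestRasterization:
    def test_full_width_horizontal_path_hits_every_column(self, geom):
        half = rc.cm_to_deg((10.7, 0.0), geom).x_deg
        path = (rc.FieldPoint(-half, 0.0), rc.FieldPoint(half, 0.0))
        assert rc.path_pixel_count([path], geom) == 442

    def test_zero_length_path_is_one_pixel(self, geom):
        p = rc.FieldPoint(1.0, 1.0)
        assert rc.path_pixel_count([(p, p)], geom) == 1

    def test_default_trajectory_exceeds_1000_pixels(self, trajectory, geom):
        seven = [p for p in trajectory if p.label != "blind_spot_line"]
        n = rc.path_pixel_count(seven, geom)
        assert n >= 1000
        # ballpark of length x linear pixel density (68.4 cm * 20.65 px/cm)
        assert n <= 1600


class TestCoverage:
    def test_trapezoid_model_reproduces_printed_rows(self):
        assert rc.trapezoid_path_area(0.26, 0.22, 7.0) == pytest.approx(3.35, abs=0.03)
        assert rc.trapezoid_path_area(0.19, 0.14, 5.6) == pytest.approx(1.85, abs=0.01)

    def test_rectangle_limit(self):
        assert rc.trapezoid_path_area(0.3, 0.3, 5.0) == pytest.approx(2 * 0.3 * 5.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            rc.trapezoid_path_area(0.1, 0.2, 5.0)
        with pytest.raises(DomainError):
            rc.trapezoid_path_area(0.2, 0.1, -1.0)

    def test_reference_report_totals(self):
        rep = rc.reference_coverage_report()
        assert rep.total_area_cm2 == pytest.approx(13.41, abs=0.03)
        assert round(rep.percent_covered, 2) == 6.75
        assert rep.total_area_cm2 == pytest.approx(
            sum(r.area_cm2 for r in rep.rows), abs=1e-12
        )

    def test_single_row_percent(self):
        rep = rc.coverage_report([("p", 1.0, 1.0, 1.0)], 200.0)
        assert rep.total_area_cm2 == 2.0
        assert rep.percent_covered == pytest.approx(1.0)

    def test_linearity_in_thickness(self):
        base = rc.coverage_report(REFERENCE_COVERAGE_INPUTS, REFERENCE_SQUARE_AREA_CM2)
        doubled = rc.coverage_report(
            [(l, 2 * a, 2 * b, h) for l, a, b, h in REFERENCE_COVERAGE_INPUTS],
            REFERENCE_SQUARE_AREA_CM2,
        )
        assert doubled.total_area_cm2 == pytest.approx(2 * base.total_area_cm2)
        assert doubled.percent_covered == pytest.approx(2 * base.percent_covered)

    def test_percent_scale_invariance(self):
        k = 2.5
        base = rc.coverage_report(REFERENCE_COVERAGE_INPUTS, REFERENCE_SQUARE_AREA_CM2)
        scaled = rc.coverage_report(
            [(l, k * a, k * b, k * h) for l, a, b, h in REFERENCE_COVERAGE_INPUTS],
            k * k * REFERENCE_SQUARE_AREA_CM2,
        )
        assert scaled.percent_covered == pytest.approx(base.percent_covered)

    def test_zero_region_area_rejected(self):
        with pytest.raises(DomainError):
            rc.coverage_report([("p", 1, 1, 1)], 0.0)

    def test_static_grid_coverage(self):
        region = rc.disc_region_area_cm2(5.28)
        assert region == pytest.approx(87.58, abs=0.005)
        assert round(rc.static_grid_coverage_percent(68, 4.0, region), 1) == 3.1
        assert rc.static_grid_coverage_percent(17, 4.0, region) < 1.0
        assert rc.static_grid_coverage_percent(0, 4.0, region) == 0.0

    def test_disc_region_unit_radius(self):
        assert rc.disc_region_area_cm2(1.0 / math.sqrt(math.pi)) == pytest.approx(1.0)

    def test_layout_derived_rows_approximate_reference(self, trajectory, geom, stim):
        """Thickness extremes read off the default layout should land close
        to the reference table (the table itself is rounded to 2 dp)."""
        rows = {r.label: r for r in path_coverage_rows(trajectory, geom, stim)}
        assert rows["vertical_1"].thickest_cm == pytest.approx(0.26, abs=0.01)
        assert rows["vertical_1"].thinnest_cm == pytest.approx(0.22, abs=0.01)
        assert rows["vertical_3"].thinnest_cm == pytest.approx(0.13, abs=0.01)
        assert rows["vertical_1"].half_run_cm == pytest.approx(7.0, abs=0.1)


class TestTrajectory:
    def test_default_has_eight_paths(self, trajectory):
        assert len(trajectory) == 8
        labels = [p.label for p in trajectory]
        assert labels[0] == "blind_spot_line"
        assert sum(l.startswith("vertical") for l in labels) == 3
        assert sum(l.startswith("diagonal") for l in labels) == 2
        assert sum(l.startswith("horizontal") for l in labels) == 2

    def test_vertical_path_length(self, trajectory, geom):
        v1 = next(p for p in trajectory if p.label == "vertical_1")
        assert v1.screen_length_cm(geom) == pytest.approx(14.1, abs=0.01)

    def test_seven_path_total_length(self, trajectory, geom):
        assert trajectory_screen_length_cm(trajectory, geom) == pytest.approx(
            68.4, abs=0.1
        )

    def test_offscreen_layout_rejected(self, geom):
        layout = TrajectoryLayout(blind_spot_x_deg=19.5, blind_spot_half_span_deg=7.0)
        small = rc.ScreenGeometry(screen_width_cm=20.0, screen_height_cm=15.0)
        with pytest.raises(ConfigurationError):
            rc.build_screening_trajectory(small, layout)

    def test_degenerate_path_rejected(self):
        with pytest.raises(ConfigurationError):
            rc.PathSpec("p", rc.FieldPoint(1, 1), rc.FieldPoint(1, 1))
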