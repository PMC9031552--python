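"""Screening runs, event pairing and delineation."""

import math

import numpy as np
import pytest

import rapidcamp as rc
from rapidcamp.errors import ConfigurationError, DomainError, MalformedStreamError
from rapidcamp.exam_engine import ExamEvent, _debounce, pair_events
from rapidcamp.io_report import analytic_scotoma_segments, exam_to_dict


def screen_err_cm(p: rc.FieldPoint, q: rc.FieldPoint, geom: rc.ScreenGeometry) -> float:
    a, b = rc.deg_to_cm(p, geom), rc.deg_to_cm(q, geom)
    return math.hypot(a[0] - b[0], a[1] - b[1])


FRAME_STEP_CM = 3.0 / 60.0  # screening speed over frame rate


class TestScreening:
    def test_clean_field_yields_only_the_blind_spot_segment(
        self, clean_field, zero_noise_observer
    ):
        exam = rc.run_screening(clean_field, zero_noise_observer)
        assert len(exam.segments) == 1
        assert exam.segments[0].path_label == "blind_spot_line"
        assert len(exam.events) == 2

    def test_narrow_band_detected_on_a_vertical_path(self, narrow_screening):
        vertical_segments = [
            s
            for s in narrow_screening.segments
            if s.path_label.startswith("vertical")
        ]
        assert len(vertical_segments) >= 1

    def test_durations(self, narrow_screening):
        # seven central paths complete in under 30 s at 3 cm/s; the whole
        # run including the blind-spot pass stays under a minute
        assert narrow_screening.duration_excluding_blind_spot_s() < 30.0
        assert narrow_screening.total_duration_s < 60.0
        assert narrow_screening.total_duration_s == pytest.approx(
            sum(narrow_screening.path_durations_s)
        )

    def test_dot_diameter_tracks_eccentricity_every_frame(self, narrow_screening):
        ecc = np.hypot(narrow_screening.frame_x_deg, narrow_screening.frame_y_deg)
        expected = np.clip(1.05 + (2.72 - 1.05) / 15.0 * ecc, 1.05, 2.72)
        np.testing.assert_allclose(narrow_screening.frame_diameter_mm, expected)

    def test_frames_sampled_at_frame_rate(self, narrow_screening):
        t = narrow_screening.frame_time_s
        idx = narrow_screening.frame_path_index
        same_path = idx[1:] == idx[:-1]
        dt = np.diff(t)[same_path]
        np.testing.assert_allclose(dt, 1.0 / 60.0, atol=1e-12)

    def test_events_lie_on_their_paths(self, narrow_screening, geom):
        for e in narrow_screening.events:
            path = narrow_screening.paths[e.path_index]
            a = np.array(rc.deg_to_cm(path.start, geom))
            b = np.array(rc.deg_to_cm(path.end, geom))
            p = np.array(rc.deg_to_cm(e.point, geom))
            u, v = b - a, p - a
            cross = u[0] * v[1] - u[1] * v[0]
            assert abs(cross) < 1e-9

    def test_off_precedes_paired_on(self, narrow_screening):
        for s in narrow_screening.segments:
            if not (s.opened_at_path_start or s.closed_at_path_end):
                assert s.off_time_s < s.on_time_s

    def test_determinism_byte_for_byte(self, narrow_field):
        import json

        obs = rc.ObserverParams(latency_mean_s=0.1, latency_sd_s=0.02, rng_seed=11)
        a = json.dumps(exam_to_dict(rc.run_screening(narrow_field, obs)), sort_keys=True)
        b = json.dumps(exam_to_dict(rc.run_screening(narrow_field, obs)), sort_keys=True)
        assert a == b

    def test_offscreen_trajectory_rejected(self, clean_field):
        small = rc.ScreenGeometry(screen_width_cm=10.0, screen_height_cm=10.0)
        with pytest.raises(ConfigurationError):
            rc.run_screening(clean_field, geom=small)

    def test_debounce_suppresses_short_blinks(self):
        inv = np.array([False, True, False, True, True, False, True, True, True])
        out = _debounce(inv, 2)
        assert out.tolist() == [False, False, False, True, True, False, True, True, True]
        assert _debounce(inv, 1).tolist() == inv.tolist()


class TestOracleEquivalence:
    def test_segments_match_analytic_containment_intervals(
        self, narrow_screening, narrow_field, geom
    ):
        """At zero noise every recorded segment endpoint sits within one
        frame step of the analytic containment interval, and every interval
        long enough to guarantee a frame sample is recorded."""
        oracle = analytic_scotoma_segments(narrow_field, narrow_screening.paths, geom)
        for seg in narrow_screening.segments:
            intervals = oracle[seg.path_label]
            errs = [
                max(
                    screen_err_cm(seg.off_point, a, geom),
                    screen_err_cm(seg.on_point, b, geom),
                )
                for a, b in intervals
            ]
            assert min(errs) <= FRAME_STEP_CM
        recorded = {s.path_label for s in narrow_screening.segments}
        for label, intervals in oracle.items():
            for a, b in intervals:
                if screen_err_cm(a, b, geom) >= 2 * FRAME_STEP_CM:
                    assert label in recorded

    def test_geometric_oracle_agrees_with_sampled_oracle(self, narrow_field, geom):
        paths = [p for p in rc.build_screening_trajectory(geom) if p.label == "vertical_3"]
        sampled = analytic_scotoma_segments(narrow_field, paths, geom, mode="sampled")
        geometric = analytic_scotoma_segments(narrow_field, paths, geom, mode="geometric")
        (sa, sb), = sampled["vertical_3"]
        (ga, gb), = geometric["vertical_3"]
        assert abs(sa.y_deg - ga.y_deg) < 0.01
        assert abs(sb.y_deg - gb.y_deg) < 0.01


class TestPairing:
    def path(self):
        return rc.PathSpec("p", rc.FieldPoint(0, -5), rc.FieldPoint(0, 5))

    def ev(self, kind, t, y):
        return ExamEvent(0, "p", int(t * 60), t, rc.FieldPoint(0.0, y), kind)

    def test_single_pair(self):
        segs = pair_events([self.ev("OFF", 1.0, -2.0), self.ev("ON", 2.0, 1.0)], [self.path()])
        assert len(segs) == 1
        assert segs[0].off_point.y_deg == -2.0
        assert segs[0].on_point.y_deg == 1.0

    def test_empty_stream(self):
        assert pair_events([], [self.path()]) == ()

    def test_unmatched_off_closes_at_path_end(self):
        segs = pair_events([self.ev("OFF", 3.0, 4.0)], [self.path()], [(0.0, 3.33)])
        assert len(segs) == 1
        assert segs[0].closed_at_path_end
        assert segs[0].on_point == self.path().end
        assert segs[0].on_time_s == pytest.approx(3.33)

    def test_unmatched_on_opens_at_path_start(self):
        segs = pair_events([self.ev("ON", 0.5, -4.0)], [self.path()], [(0.0, 3.33)])
        assert len(segs) == 1
        assert segs[0].opened_at_path_start
        assert segs[0].off_point == self.path().start

    def test_consecutive_offs_rejected(self):
        with pytest.raises(MalformedStreamError):
            pair_events(
                [self.ev("OFF", 1.0, -2.0), self.ev("OFF", 2.0, 0.0)], [self.path()]
            )


@pytest.fixture(scope="module")
def band_segment(narrow_screening):
    return next(s for s in narrow_screening.segments if s.path_label == "vertical_3")


@pytest.fixture(scope="module")
def band_boundary(narrow_field):
    return narrow_field.region_polygons()[1].boundary


class TestDelineation:
    def test_divisor8_recovers_band_width(
        self, narrow_field, zero_noise_observer, band_segment
    ):
        res = rc.run_delineation(
            narrow_field, zero_noise_observer, band_segment, divisor=8
        )
        widths = res.width_estimates_deg()
        assert len(widths) >= 5
        assert abs(widths.mean() - 0.35) <= 0.07
        assert np.all(np.abs(widths - 0.35) <= 0.07)

    def test_outline_tracks_true_boundary(
        self, narrow_field, zero_noise_observer, band_segment, band_boundary
    ):
        res = rc.run_delineation(
            narrow_field, zero_noise_observer, band_segment, divisor=8
        )
        # zero latency: reconstruction error is bounded by the sweep spacing
        assert res.mean_boundary_distance_deg(band_boundary) <= res.sweep_step_deg
        assert res.outline_deg.shape[0] == 2 * len(res.crossings) + 1

    def test_slowing_down_beats_full_speed_under_latency(
        self, narrow_field, band_segment, band_boundary
    ):
        lat = rc.ObserverParams(latency_mean_s=0.2)
        errs = {}
        for divisor in (1, 4, 8):
            res = rc.run_delineation(narrow_field, lat, band_segment, divisor=divisor)
            errs[divisor] = res.mean_boundary_distance_deg(band_boundary)
        assert errs[8] <= errs[4] <= errs[1]

    def test_error_grows_with_latency(self, narrow_field, band_segment, band_boundary):
        errs = []
        for latency in (0.0, 0.1, 0.2):
            obs = rc.ObserverParams(latency_mean_s=latency)
            res = rc.run_delineation(narrow_field, obs, band_segment, divisor=4)
            errs.append(res.mean_boundary_distance_deg(band_boundary))
        assert errs[0] <= errs[1] <= errs[2]

    def test_clean_field_yields_no_crossings(self, clean_field, zero_noise_observer):
        seg = rc.ScotomaSegment(
            0, "probe", rc.FieldPoint(-4, 3), rc.FieldPoint(-2, 5), 0.0, 1.0
        )
        res = rc.run_delineation(clean_field, zero_noise_observer, seg, divisor=8)
        assert res.crossings == ()
        assert res.outline_deg.size == 0

    def test_foreign_segment_rejected_against_exam(
        self, narrow_field, narrow_screening, zero_noise_observer
    ):
        foreign = rc.ScotomaSegment(
            0, "probe", rc.FieldPoint(0, 0), rc.FieldPoint(1, 1), 0.0, 1.0
        )
        with pytest.raises(DomainError):
            rc.run_delineation(
                narrow_field, zero_noise_observer, foreign, exam=narrow_screening
            )

    def test_delineation_time_budget(self, narrow_field, band_segment):
        """10 sweeps at divisor 8 stay within the minutes-scale window the
        procedure is specified for (1-10 min per eye)."""
        res = rc.run_delineation(
            narrow_field, rc.ObserverParams(), band_segment, divisor=8
        )
        sweep_len = sum(s.screen_length_cm(rc.ScreenGeometry()) for s in res.sweeps)
        t = rc.traversal_time_s(sweep_len, 3.0 / 8)
        assert 60.0 <= t <= 600.0
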