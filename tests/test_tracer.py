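"""The flashlight tracing algorithm on rendered ground-truth stacks."""

import numpy as np
import pytest

from flashtrace.assess import point_to_polyline_distance
from flashtrace.imaging import preprocess
from flashtrace.render import RenderConfig, render_stack
from flashtrace.tracer import (TracerParams, best_in_section,
                               extension_schedule, initialize, scan_arc,
                               select_next, trace_fiber)
from flashtrace.tracer import PeakCandidate


class TestExtensionSchedule:
    def test_native_radius_at_index_two(self):
        p = TracerParams(R=1.0, k=0.07)
        R2, a2 = extension_schedule(2, p)
        assert R2 == 1.0 and np.isclose(a2, p.alpha0)

    def test_zero_attenuation_keeps_angle(self):
        p = TracerParams(R=1.0, k=0.0)
        for i in range(1, 7):
            assert np.isclose(extension_schedule(i, p)[1], p.alpha0)

    def test_printed_attenuation_value(self):
        p = TracerParams(R=1.0, alpha0=np.pi / 2, k=0.1)
        _, a4 = extension_schedule(4, p)
        assert np.isclose(a4, (np.pi / 2) * np.exp(-0.2))

    def test_radius_multiples_and_angle_never_widens(self):
        p = TracerParams(R=0.8, k=0.05)
        radii = [extension_schedule(i, p)[0] for i in range(1, 7)]
        assert np.allclose(radii, [0.4, 0.8, 1.2, 1.6, 2.0, 2.4])
        angles = [extension_schedule(i, p)[1] for i in range(1, 7)]
        assert max(angles) <= p.alpha0 + 1e-12


class TestSelection:
    def c(self, off=0, angle=0.0, brightness=0.5, width=0.5):
        return PeakCandidate(section_offset=off, angle=angle,
                             brightness=brightness, width=width,
                             pos_px=(0.0, 0.0))

    def test_within_section_prefers_smallest_angle(self):
        picked = best_in_section([self.c(angle=-0.35, brightness=0.9),
                                  self.c(angle=0.09, brightness=0.6)])
        assert picked.angle == 0.09

    def test_across_sections_prefers_brightest(self):
        chosen = select_next({0: self.c(off=0, brightness=0.7),
                              2: self.c(off=2, brightness=0.9)})
        assert chosen.section_offset == 2

    def test_brightness_tie_prefers_nearer_section(self):
        chosen = select_next({-2: self.c(off=-2, brightness=0.8),
                              1: self.c(off=1, brightness=0.8)})
        assert chosen.section_offset == 1

    def test_empty_input_signals_no_peak(self):
        assert select_next({}) is None
        assert best_in_section([]) is None


class TestScanArc:
    def test_dark_arc_yields_nothing(self):
        section = np.full((50, 50), 0.05, np.float32)
        p = TracerParams(R=0.75)
        cands = scan_arc(section, (25.0, 25.0), (1.0, 0.0), 0.75, np.pi / 2,
                         p, xy_pixel=0.06)
        assert cands == []

    def test_single_pixel_spike_rejected_by_width(self):
        section = np.full((60, 60), 0.05, np.float32)
        # one bright pixel on the arc straight ahead (R = 0.75 um = 12.5 px)
        section[30, 42] = 1.0
        p = TracerParams(R=0.75, W_min=0.1)
        cands = scan_arc(section, (30.0, 30.0), (1.0, 0.0), 0.75, np.pi / 2,
                         p, xy_pixel=0.06)
        assert cands == []

    def test_rendered_tube_found_at_its_angle(self, straight_fiber_stack):
        pp, pts, _ = straight_fiber_stack
        p = TracerParams(R=0.75)
        center = pp.to_pixel(10.0, 10.0, 3.0)
        sec = int(round(center[2]))
        cands = scan_arc(pp.sections[sec], (center[0], center[1]),
                         (1.0, 0.0), 0.75, np.pi / 2, p, pp.xy_pixel)
        assert len(cands) == 1
        assert abs(cands[0].angle) <= 2 * (np.pi / 2) / p.n
        assert cands[0].brightness > 0.8

    def test_saturated_wide_blob_rejected_by_w_max(self):
        section = np.full((80, 80), 0.9, np.float32)  # bright everywhere
        p = TracerParams(R=0.75, W_max=1.0)
        cands = scan_arc(section, (40.0, 40.0), (1.0, 0.0), 0.75, np.pi / 2,
                         p, xy_pixel=0.06)
        # one run covering the whole arc: width 0.75 * pi > W_max
        assert cands == []


class TestInitialize:
    def test_second_point_on_the_fiber_axis(self, straight_fiber_stack):
        pp, pts, _ = straight_fiber_stack
        seed = pp.to_pixel(10.0, 10.0, 3.0)
        second, direction = initialize(pp, (seed[0], seed[1],
                                            int(round(seed[2]))),
                                       TracerParams(R=0.75))
        ang = np.arctan2(direction[1], direction[0])
        # the brightest circle point lies on the fiber: ahead or behind
        assert min(abs(ang), abs(abs(ang) - np.pi)) < 0.1

    def test_dark_seed_rejected(self, straight_fiber_stack):
        pp, _, _ = straight_fiber_stack
        with pytest.raises(ValueError, match="seed not on a fiber"):
            initialize(pp, (30.0, 30.0, 1), TracerParams(R=0.75))

    def test_brighter_of_two_crossing_fibers_wins(self):
        bright = np.array([[2.0, 5.0, 1.5], [18.0, 5.0, 1.5]])
        dim = np.array([[10.0, 1.0, 1.5], [10.0, 9.0, 1.5]])
        cfg_b = RenderConfig(noise_sd=0.0, peak_intensity=0.9, seed=0)
        cfg_d = RenderConfig(noise_sd=0.0, peak_intensity=0.45, seed=0)
        a = render_stack([bright], (20, 10, 3), (0.1, 0.3), cfg_b)
        b = render_stack([dim], (20, 10, 3), (0.1, 0.3), cfg_d)
        merged = a
        merged.sections = np.maximum(a.sections, b.sections)
        pp = preprocess(merged)
        seed = pp.to_pixel(10.0, 5.0, 1.5)  # the crossing point
        second, direction = initialize(pp, (seed[0], seed[1],
                                            int(round(seed[2]))),
                                       TracerParams(R=0.75))
        # direction along x (the bright fiber), not along y (the dim one)
        assert abs(direction[0]) > abs(direction[1])


class TestTraceFiber:
    def test_straight_fiber_end_to_end_within_tolerance(
            self, straight_fiber_stack):
        pp, pts, _ = straight_fiber_stack
        res = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10),
                          params=TracerParams(R=0.75), do_preprocess=False)
        tp = res.trace.points
        assert tp[:, 0].max() > 36.0  # spans the fiber
        d = point_to_polyline_distance(tp, pts)
        assert d.max() < 0.5
        assert res.termination in ("stack_edge", "no_peaks")

    def test_gap_bridged_with_extensions(self, gap_fiber_stack):
        pp, pts = gap_fiber_stack
        res = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10),
                          params=TracerParams(R=0.75, i_max=4, B_min=0.5),
                          do_preprocess=False)
        assert res.trace.points[:, 0].max() > 30.0
        assert max(e["extension_i"] for e in res.log) > 2

    def test_gap_truncates_without_extensions(self, gap_fiber_stack):
        pp, pts = gap_fiber_stack
        res = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10),
                          params=TracerParams(R=0.75, i_max=0, B_min=0.5),
                          do_preprocess=False)
        assert res.termination == "no_peaks"
        assert res.trace.points[:, 0].max() < 24.0

    def test_angular_contract_of_logged_steps(self, straight_fiber_stack):
        pp, _, _ = straight_fiber_stack
        params = TracerParams(R=0.75)
        res = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10), params=params,
                          do_preprocess=False)
        for e in res.log:
            if e["origin"] != "auto" or e["step"] < 2:
                continue
            _, alpha_i = extension_schedule(e["extension_i"], params)
            assert abs(e["angle"]) <= alpha_i + 1e-9

    def test_brightness_contract_of_logged_steps(self, straight_fiber_stack):
        pp, _, _ = straight_fiber_stack
        params = TracerParams(R=0.75)
        res = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10), params=params,
                          do_preprocess=False)
        for e in res.log:
            if e["origin"] == "auto" and e["step"] >= 2:
                assert e["brightness"] >= params.B_min

    def test_determinism(self, straight_fiber_stack):
        pp, _, _ = straight_fiber_stack
        a = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10),
                        params=TracerParams(R=0.75), do_preprocess=False)
        b = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10),
                        params=TracerParams(R=0.75), do_preprocess=False)
        assert np.array_equal(a.trace.points, b.trace.points)
        assert a.log == b.log

    def test_max_steps_termination(self, straight_fiber_stack):
        pp, _, _ = straight_fiber_stack
        res = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10),
                          params=TracerParams(R=0.75), max_steps=5,
                          do_preprocess=False)
        assert res.termination == "max_steps"
        assert res.trace.n_points <= 7

    def test_manual_override_bridges_and_is_flagged(self, gap_fiber_stack):
        pp, pts = gap_fiber_stack
        res = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10),
                          params=TracerParams(R=0.75, i_max=0, B_min=0.5),
                          overrides=[(24.5, 10.0, 3.0)],
                          do_preprocess=False)
        origins = [e["origin"] for e in res.log]
        assert "manual" in origins
        assert res.trace.points[:, 0].max() > 30.0

    def test_override_outside_stack_rejected(self, gap_fiber_stack):
        pp, _ = gap_fiber_stack
        with pytest.raises(ValueError, match="outside"):
            trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10),
                        params=TracerParams(R=0.75),
                        overrides=[(99.0, 99.0, 1.0)],
                        do_preprocess=False)

    def test_xy_steps_match_logged_radius(self, straight_fiber_stack):
        # before nudging, consecutive XY displacements equal the logged R_i
        # within a pixel plus the sub-pixel refinement window
        pp, _, _ = straight_fiber_stack
        params = TracerParams(R=0.75, z_refine=False, xy_refine=False)
        res = trace_fiber(pp, (2.0 / 0.06, 10.0 / 0.06, 10), params=params,
                          do_preprocess=False)
        tp = res.trace.points
        for i in range(2, tp.shape[0]):
            e = res.log[i]
            if e["origin"] != "auto":
                continue
            R_i, _ = extension_schedule(e["extension_i"], params)
            dxy = np.linalg.norm(tp[i, :2] - tp[i - 1, :2])
            assert abs(dxy - R_i) <= pp.xy_pixel + 1e-9
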