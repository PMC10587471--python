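"""Directional-statistics kernel: rotations, sampling, standardization,
concentration-parameter estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flashtrace.simulate import WalkConfig, simulate_fiber
from flashtrace.trajectory import FiberTrace
from flashtrace.vmf import (DirectionSample, KappaEstimate, estimate_kappa,
                            rotation_to, sample_vmf, standardize_steps,
                            vmf_mean_resultant_length)


def unit(v):
    v = np.asarray(v, float)
    return v / np.linalg.norm(v)


class TestRotation:
    def test_pole_maps_to_identity(self):
        assert np.allclose(rotation_to(np.array([0.0, 0.0, 1.0])), np.eye(3))

    def test_printed_form_at_x_axis(self):
        # hand evaluation of the closed form at mu = (1, 0, 0)
        expected = np.array([[0.0, 0.0, 1.0],
                             [0.0, 1.0, 0.0],
                             [-1.0, 0.0, 0.0]])
        assert np.allclose(rotation_to(np.array([1.0, 0.0, 0.0])), expected)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_proper_rotation_taking_pole_to_mu(self, seed):
        v = unit(np.random.default_rng(seed).normal(size=3))
        if v[2] <= -0.999:
            v = -v
        M = rotation_to(v)
        assert np.allclose(M @ np.array([0.0, 0.0, 1.0]), v, atol=1e-12)
        assert np.allclose(M.T @ M, np.eye(3), atol=1e-9)
        assert np.isclose(np.linalg.det(M), 1.0, atol=1e-9)
        # inverse standardizes mu back to the pole
        assert np.allclose(M.T @ v, [0.0, 0.0, 1.0], atol=1e-9)

    def test_antipodal_fallback_is_a_proper_rotation(self):
        M = rotation_to(np.array([0.0, 0.0, -1.0]))
        assert np.allclose(M @ np.array([0.0, 0.0, 1.0]), [0.0, 0.0, -1.0])
        assert np.isclose(np.linalg.det(M), 1.0)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            rotation_to(np.array([1.0, 1.0, 0.0]))


class TestSampler:
    def test_concentration_limit_collapses_to_mean(self):
        mu = unit([1.0, 2.0, 2.0])
        s = sample_vmf(mu, 1e9, 100, seed=0)
        angles = np.arccos(np.clip(s.directions @ mu, -1, 1))
        assert angles.max() < 1e-3

    @pytest.mark.parametrize("kappa", [5.0, 20.0])
    def test_mean_resultant_length_matches_closed_form(self, kappa):
        # A(kappa) = coth(kappa) - 1/kappa is an independent oracle
        s = sample_vmf(np.array([0.0, 0.0, 1.0]), kappa, 100_000, seed=42)
        assert abs(s.L - vmf_mean_resultant_length(kappa)) < 0.005

    def test_near_uniform_limit(self):
        s = sample_vmf(np.array([0.0, 0.0, 1.0]), 1e-6, 100_000, seed=7)
        assert np.linalg.norm(s.directions.mean(axis=0)) < 0.02

    def test_rotational_symmetry_about_mean(self):
        mu = unit([3.0, -1.0, 0.5])
        s = sample_vmf(mu, 10.0, 50_000, seed=3)
        # the mean vector must align with mu
        m = s.directions.mean(axis=0)
        assert np.dot(unit(m), mu) > 0.9999

    def test_seed_determinism(self):
        a = sample_vmf(np.array([0.0, 0.0, 1.0]), 8.0, 100, seed=5)
        b = sample_vmf(np.array([0.0, 0.0, 1.0]), 8.0, 100, seed=5)
        assert np.array_equal(a.directions, b.directions)

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ValueError, match="kappa"):
            sample_vmf(np.array([0.0, 0.0, 1.0]), 0.0, 10, seed=0)


class TestStandardize:
    def test_collinear_trace_gives_pole_directions_and_L_one(self):
        tr = FiberTrace(np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2],
                                  [0, 0, 3.0]]))
        s = standardize_steps(tr)
        assert s.directions.shape == (2, 3)
        assert np.allclose(s.directions, [0.0, 0.0, 1.0])
        assert np.isclose(s.L, 1.0)

    def test_right_angle_turn_maps_to_equator(self):
        tr = FiberTrace(np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0.0]]))
        s = standardize_steps(tr)
        assert s.directions.shape == (1, 3)
        assert abs(s.directions[0, 2]) < 1e-12  # 90 degrees from the pole

    def test_invariant_under_global_rigid_motion(self, rng):
        # Standardization removes the global orientation: the polar angle of
        # every standardized direction (its angle to the previous step) is
        # exactly invariant under rigid motions of the trace.  The azimuth
        # depends on the rotation convention used to carry the previous
        # step to the pole, so the transverse components are only
        # statistically stable; the resultant length, dominated by the
        # polar components, moves very little.
        from scipy.spatial.transform import Rotation

        tr = simulate_fiber(WalkConfig(kappa=20.0, n_steps=100,
                                       step_len=1.0, seed=6))
        pts = tr.points
        R = Rotation.random(random_state=4).as_matrix()
        moved = FiberTrace(pts @ R.T + np.array([5.0, -3.0, 2.0]))
        a = standardize_steps(tr)
        b = standardize_steps(moved)
        assert np.allclose(a.directions[:, 2], b.directions[:, 2],
                           atol=1e-9)
        assert abs(a.L - b.L) < 0.05

    def test_too_short_and_zero_step_errors(self):
        with pytest.raises(ValueError, match="insufficient"):
            standardize_steps(FiberTrace(np.array([[0, 0, 0], [1, 0, 0.0]])))
        bad = FiberTrace.__new__(FiberTrace)  # bypass validation
        bad.points = np.array([[0, 0, 0], [1, 0, 0], [1, 0, 0], [2, 0, 0.0]])
        with pytest.raises(ValueError, match="index 1"):
            standardize_steps(bad)


def sample_with_L(L):
    """Two symmetric directions whose mean resultant length is exactly L."""
    a = np.arccos(L)
    return DirectionSample(np.array([[np.sin(a), 0, np.cos(a)],
                                     [-np.sin(a), 0, np.cos(a)]]))


class TestEstimators:
    def test_simple_estimator_at_validity_threshold(self):
        est = estimate_kappa(sample_with_L(0.9), "simple", step_len=1.0)
        assert np.isclose(est.kappa, 10.0)

    def test_approx3d_hand_value(self):
        est = estimate_kappa(sample_with_L(0.9), "approx3d", step_len=1.0)
        assert np.isclose(est.kappa, 0.9 * (3 - 0.81) / (1 - 0.81))

    def test_fixed_point_solves_defining_equation(self):
        est = estimate_kappa(sample_with_L(0.95), "fixed_point", step_len=1.0)
        # bisection oracle on A(kappa) = 0.95
        lo, hi = 1e-6, 1e6
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if vmf_mean_resultant_length(mid) < 0.95:
                lo = mid
            else:
                hi = mid
        assert abs(est.kappa - lo) < 1e-5
        assert abs(est.kappa - 20.0) < 1e-5

    def test_simple_requires_large_L(self):
        with pytest.raises(ValueError, match="0.9"):
            estimate_kappa(sample_with_L(0.5), "simple", step_len=1.0)

    def test_degenerate_rigid_fiber(self):
        with pytest.raises(ValueError, match="rigid"):
            estimate_kappa(DirectionSample(np.tile([0.0, 0, 1], (3, 1))),
                           "approx3d", step_len=1.0)

    def test_methods_agree_for_stiff_fibers(self):
        for L in np.linspace(0.9, 0.999, 25):
            s = sample_with_L(L)
            k_a = estimate_kappa(s, "approx3d", 1.0).kappa
            k_f = estimate_kappa(s, "fixed_point", 1.0).kappa
            k_s = estimate_kappa(s, "simple", 1.0).kappa
            assert abs(k_a - k_f) / k_f < 0.05
            assert abs(k_s - k_f) / k_f < 0.10

    def test_strictly_increasing_in_L(self):
        grid = np.linspace(0.05, 0.995, 60)
        for method in ("approx3d", "fixed_point"):
            ks = [estimate_kappa(sample_with_L(L), method, 1.0).kappa
                  for L in grid]
            assert np.all(np.diff(ks) > 0)
        ks = [estimate_kappa(sample_with_L(L), "simple", 1.0).kappa
              for L in grid[grid >= 0.9]]
        assert np.all(np.diff(ks) > 0)

    @pytest.mark.parametrize("kappa", [5.0, 20.0, 64.0])
    def test_round_trip_sampling_and_estimation(self, kappa):
        s = sample_vmf(np.array([0.0, 0.0, 1.0]), kappa, 100_000, seed=11)
        est = estimate_kappa(s, "fixed_point", step_len=1.0)
        assert abs(est.kappa - kappa) / kappa < 0.03


class TestSerialization:
    def test_direction_sample_csv_round_trip(self, tmp_path):
        s = sample_vmf(np.array([0.0, 0.0, 1.0]), 5.0, 50, seed=2)
        p = tmp_path / "dirs.csv"
        s.to_csv(p)
        assert p.read_text().splitlines()[0] == "ux,uy,uz"
        back = DirectionSample.from_csv(p)
        assert np.allclose(back.directions, s.directions, atol=1e-9)

    def test_kappa_estimate_json_round_trip(self):
        est = KappaEstimate(kappa=20.0, method="fixed_point", step_len=1.5,
                            n_directions=100, L=0.95)
        back = KappaEstimate.from_json(est.to_json())
        assert back == est

    def test_kappa_estimate_carries_its_step(self):
        est = estimate_kappa(sample_with_L(0.95), "approx3d", step_len=1.5)
        assert est.step_len == 1.5
        assert '"step_len_um": 1.5' in est.to_json()
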