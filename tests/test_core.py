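"""Closed-form sedimentation model: terminal velocity, effective
areas, boundary concentration curves, half-life bounds and fits."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import syrsed as sy
from syrsed.specs import InvalidParameterError


class TestTerminalVelocity:
    @pytest.mark.parametrize(
        "r, rho_p, rho_b, eta, expected",
        [
            (5e-6, 1070.0, 997.0, 1e-3, -3.9785e-6),     # PS bead in water
            (10.3e-6, 1062.0, 1000.0, 1e-3, -1.43391e-5),  # stromal cell in PBS
        ],
    )
    def test_known_values(self, r, rho_p, rho_b, eta, expected):
        v = sy.terminal_velocity(sy.ParticleSpec(r, rho_p), sy.BufferSpec(rho_b, eta))
        assert v == pytest.approx(expected, rel=1e-4)

    def test_density_matched_is_zero(self):
        v = sy.terminal_velocity(sy.ParticleSpec(5e-6, 1000.0), sy.BufferSpec(1000.0, 1e-3))
        assert v == 0.0

    def test_light_particle_floats(self):
        v = sy.terminal_velocity(sy.ParticleSpec(5e-6, 950.0), sy.BufferSpec(1000.0, 1e-3))
        assert v > 0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(InvalidParameterError):
            sy.ParticleSpec(-1e-6, 1000.0)
        with pytest.raises(InvalidParameterError):
            sy.BufferSpec(1000.0, 0.0)


class TestRelaxationTime:
    @pytest.mark.parametrize(
        "r, rho_p, expected",
        [(5e-6, 1070.0, 5.944e-6), (10.3e-6, 1062.0, 2.504e-5)],
    )
    def test_microsecond_scale(self, r, rho_p, expected):
        tau = sy.stokes_relaxation_time(sy.ParticleSpec(r, rho_p), sy.BufferSpec(997.0, 1e-3))
        assert tau == pytest.approx(expected, rel=1e-3)

    def test_vanishes_with_radius(self):
        tau = sy.stokes_relaxation_time(sy.ParticleSpec(1e-12, 1070.0), sy.BufferSpec(997.0, 1e-3))
        assert tau < 1e-15


class TestEffectiveAreas:
    def test_lens_endpoints(self):
        R = 1.7e-3
        assert sy.effective_area_lens(R, 0.0) == pytest.approx(math.pi * R**2)
        assert sy.effective_area_lens(R, 2 * R) == 0.0
        assert sy.effective_area_lens(R, 5 * R) == 0.0

    def test_segment_endpoints(self):
        R = 1.7e-3
        assert sy.effective_area_segment(R, 0.0) == pytest.approx(math.pi * R**2 / 2)
        assert sy.effective_area_segment(R, R) == 0.0

    def test_lens_half_offset_value(self):
        # frozen Monte-Carlo oracle value for R=1, d=1 (4e6 samples)
        assert sy.effective_area_lens(1.0, 1.0) == pytest.approx(1.22837, abs=2e-3)

    def test_segment_half_height_value(self):
        assert sy.effective_area_segment(1.0, 0.5) == pytest.approx(0.61418, abs=2e-3)

    def test_monte_carlo_oracle(self, rng):
        """Both areas agree with point-in-region sampling within 3 SE."""
        R, d, n = 1.3, 0.7, 1_000_000
        pts = rng.uniform(-R, R, (n, 2))
        box = 4 * R**2
        in_lens = ((pts**2).sum(1) < R**2) & ((pts[:, 0]**2 + (pts[:, 1] + d)**2) < R**2)
        in_seg = ((pts**2).sum(1) < R**2) & (pts[:, 1] > d)
        for mask, area in [(in_lens, sy.effective_area_lens(R, d)),
                           (in_seg, sy.effective_area_segment(R, d))]:
            p = mask.mean()
            se = box * math.sqrt(p * (1 - p) / n)
            assert abs(mask.mean() * box - area) < 3 * se

    def test_negative_inputs_rejected(self):
        with pytest.raises(InvalidParameterError):
            sy.effective_area_lens(1.0, -0.1)
        with pytest.raises(InvalidParameterError):
            sy.effective_area_segment(-1.0, 0.1)


class TestConcentrationRatios:
    def test_upper_endpoints(self):
        v, R = 4e-6, 2.3e-3
        assert sy.concentration_ratio_upper(v, R, 0.0) == 1.0
        assert sy.concentration_ratio_upper(v, R, 2 * R / v) == 0.0

    def test_lower_endpoints(self):
        v, R = 4e-6, 2.3e-3
        assert sy.concentration_ratio_lower(v, R, 0.0) == 1.0
        assert sy.concentration_ratio_lower(v, R, R / v) == 0.0

    def test_half_path_value(self):
        # both boundaries pass 0.3910 when the scaled path is one half
        v, R = 4e-6, 2.3e-3
        assert sy.concentration_ratio_upper(v, R, R / v) == pytest.approx(0.39100, abs=1e-4)
        assert sy.concentration_ratio_lower(v, R, 0.5 * R / v) == pytest.approx(0.39100, abs=1e-4)

    def test_zero_velocity_sentinel(self):
        assert sy.concentration_ratio_upper(0.0, 1e-3, 1e6) == 1.0
        assert sy.concentration_ratio_lower(0.0, 1e-3, 1e6) == 1.0

    def test_ratio_equals_area_fraction(self):
        """Algebraic identity: ratio = effective area / initial area."""
        v, R = 3.98e-6, 2.3e-3
        t = np.linspace(0.0, 2 * R / v, 97)
        upper = sy.concentration_ratio_upper(v, R, t)
        lower = sy.concentration_ratio_lower(v, R, t)
        np.testing.assert_allclose(
            upper, sy.effective_area_lens(R, v * t) / (math.pi * R**2), atol=1e-12)
        np.testing.assert_allclose(
            lower, sy.effective_area_segment(R, v * t) / (math.pi * R**2 / 2), atol=1e-12)

    @given(
        v=st.floats(1e-7, 1e-4), R=st.floats(5e-4, 5e-3),
        t1=st.floats(0, 2000), t2=st.floats(0, 2000),
    )
    @settings(max_examples=60, deadline=None)
    def test_monotone_bounded_ordered(self, v, R, t1, t2):
        """Ratios live in [0,1], decrease in time, and upper >= lower."""
        lo, hi = sorted([t1, t2])
        for fn in (sy.concentration_ratio_upper, sy.concentration_ratio_lower):
            a, b = fn(v, R, lo), fn(v, R, hi)
            assert 0.0 <= b <= a <= 1.0
        assert sy.concentration_ratio_upper(v, R, lo) >= sy.concentration_ratio_lower(v, R, lo)


class TestBoundaryCoefficients:
    def test_values_and_exact_doubling(self):
        lo, hi = sy.half_life_boundary_coefficients()
        assert round(lo, 1) == 0.4
        assert round(hi, 1) == 0.8
        assert hi == 2 * lo  # exact: same root, rescaled argument
        assert lo == pytest.approx(0.40397, abs=1e-5)

    def test_solves_half_concentration(self):
        lo, hi = sy.half_life_boundary_coefficients()
        v, R = 1e-5, 1e-3
        assert abs(sy.concentration_ratio_lower(v, R, lo * R / v) - 0.5) < 1e-10
        assert abs(sy.concentration_ratio_upper(v, R, hi * R / v) - 0.5) < 1e-10

    def test_against_independent_root_finder(self):
        f = lambda x: math.acos(x) - x * math.sqrt(1 - x * x) - math.pi / 4
        root = brentq(f, 0.0, 1.0, xtol=1e-14)
        lo, _ = sy.half_life_boundary_coefficients()
        assert lo == pytest.approx(root, abs=1e-11)


class TestHalfLife:
    def test_bounds_ps_bead(self, ps_bead, water, syringe_1ml):
        est = sy.half_life_bounds(ps_bead, water, syringe_1ml)
        assert est.lower_bound == pytest.approx(233.5, rel=1e-3)
        assert est.upper_bound == pytest.approx(467.1, rel=1e-3)

    def test_linearity_in_radius_and_density(self, ps_bead, water, syringe_1ml):
        est = sy.half_life_bounds(ps_bead, water, syringe_1ml)
        bigger = sy.SyringeSpec(2 * syringe_1ml.barrel_radius, 40e-3, 0.5e-3)
        est2 = sy.half_life_bounds(ps_bead, water, bigger)
        assert est2.lower_bound == pytest.approx(2 * est.lower_bound)
        half_mismatch = sy.ParticleSpec(ps_bead.radius, water.density + (ps_bead.density - water.density) / 2)
        est3 = sy.half_life_bounds(half_mismatch, water, syringe_1ml)
        assert est3.lower_bound == pytest.approx(2 * est.lower_bound)

    def test_density_matched_sentinel(self, syringe_1ml):
        est = sy.half_life_bounds(
            sy.ParticleSpec(5e-6, 1000.0), sy.BufferSpec(1000.0, 1e-3), syringe_1ml)
        assert math.isinf(est.lower_bound) and math.isinf(est.upper_bound)

    def test_estimate_is_linear_in_ks(self, ps_bead, water, syringe_1ml):
        t4 = sy.half_life_estimate(ps_bead, water, syringe_1ml, K_S=0.4)
        t8 = sy.half_life_estimate(ps_bead, water, syringe_1ml, K_S=0.8)
        assert t8 == pytest.approx(2 * t4)

    def test_stromal_cell_estimate(self, syringe_1ml):
        """Literature-parameter mammalian-cell prediction, ~64 s."""
        cell = sy.ParticleSpec(10.3e-6, 1062.0)
        t = sy.half_life_estimate(cell, sy.BufferSpec(1000.0, 1e-3), syringe_1ml, K_S=0.4)
        assert t == pytest.approx(64.2, abs=0.5)

    def test_out_of_range_ks_warns(self, ps_bead, water, syringe_1ml):
        with pytest.warns(UserWarning):
            sy.half_life_estimate(ps_bead, water, syringe_1ml, K_S=1.5)

    def test_sedimentation_constant_round_trip(self, ps_bead, water, syringe_1ml):
        v = abs(sy.terminal_velocity(ps_bead, water))
        for k in (0.4, 0.52, 0.8):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t = sy.half_life_estimate(ps_bead, water, syringe_1ml, K_S=k)
            assert sy.sedimentation_constant(t, v, syringe_1ml.barrel_radius) == pytest.approx(k)

    def test_sedimentation_constant_basics(self):
        assert sy.sedimentation_constant(100.0, 1e-5, 2e-3) == pytest.approx(0.5)
        assert sy.sedimentation_constant(0.0, 1e-5, 2e-3) == 0.0
        with pytest.raises(InvalidParameterError):
            sy.sedimentation_constant(10.0, 0.0, 2e-3)


class TestFitSedimentationConstant:
    def test_noiseless_fit_exact(self, rng):
        x = rng.uniform(50.0, 500.0, 12)  # R_S/v_T predictor values
        pts = [(0.5 * xi, xi * 1e-5, 1e-5) for xi in x]
        K, r2 = sy.fit_sedimentation_constant(pts)
        assert K == pytest.approx(0.5, rel=1e-12)
        assert r2 == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_noise_closed_form(self):
        # single predictor duplicated with +/- eps: K = mean/predictor
        x, eps = 200.0, 7.0
        pts = [(0.6 * x + eps, x * 1e-5, 1e-5), (0.6 * x - eps, x * 1e-5, 1e-5)]
        K, _ = sy.fit_sedimentation_constant(pts)
        assert K == pytest.approx(0.6)

    def test_insufficient_data(self):
        with pytest.raises(InvalidParameterError):
            sy.fit_sedimentation_constant([(100.0, 2e-3, 1e-5)])


class TestScalingLaws:
    """Half-life scalings on exact model grids: t ∝ r^-2, Δρ^-1, η, R_S."""

    @staticmethod
    def _power_fit_r2(x, y):
        # fit y = a*x^b in log space, return (b, R^2 in log space)
        b, loga = np.polyfit(np.log(x), np.log(y), 1)
        resid = np.log(y) - (b * np.log(x) + loga)
        ss_tot = np.sum((np.log(y) - np.log(y).mean()) ** 2)
        return b, 1.0 - np.sum(resid**2) / ss_tot

    def test_all_four_scalings(self, syringe_1ml):
        grids = {
            "radius": (np.array([2, 3, 4, 5, 6, 7.5]) * 1e-6, -2.0),
            "density": (np.array([1010, 1015, 1035, 1070, 1100, 1130, 1190.0]), -1.0),
            "viscosity": (np.array([0.7, 1.0, 1.3, 1.6, 2.0]) * 1e-3, 1.0),
            "barrel_radius": (np.array([1.15, 1.625, 2.3, 3.6]) * 1e-3, 1.0),
        }
        for name, (vals, expected_exp) in grids.items():
            ts, xs = [], []
            for v in vals:
                p = sy.ParticleSpec(v if name == "radius" else 5e-6,
                                    v if name == "density" else 1070.0)
                b = sy.BufferSpec(997.0, v if name == "viscosity" else 1e-3)
                s = syringe_1ml if name != "barrel_radius" else sy.SyringeSpec(
                    v, 40e-3, 0.5e-3)
                ts.append(sy.half_life_bounds(p, b, s).lower_bound)
                xs.append(v - 997.0 if name == "density" else v)
            exp, r2 = self._power_fit_r2(np.array(xs), np.array(ts))
            assert exp == pytest.approx(expected_exp, abs=1e-9), name
            assert r2 > 1 - 1e-12, name


class TestEinsteinViscosity:
    def test_dilute_sample_negligible(self):
        """10^6 3 µm particles per ml thicken water by far below 1e-3 mPa·s."""
        p = sy.ParticleSpec(3e-6, 1050.0)
        b = sy.BufferSpec(997.0, 1e-3)
        inc = sy.einstein_viscosity_increment(p, 1e12, b)  # 1e6 /ml in SI
        assert inc == pytest.approx(2.83e-7, rel=1e-2)
        assert inc < 1e-6  # the 1e-3 mPa·s negligibility bound

    def test_linear_in_concentration(self):
        p = sy.ParticleSpec(3e-6, 1050.0)
        b = sy.BufferSpec(997.0, 1e-3)
        assert sy.einstein_viscosity_increment(p, 0.0, b) == 0.0
        assert sy.einstein_viscosity_increment(p, 2e12, b) == pytest.approx(
            2 * sy.einstein_viscosity_increment(p, 1e12, b))


class TestAnalyticCurve:
    def test_sources_and_shape(self, ps_bead, water, syringe_1ml):
        up = sy.analytic_curve(ps_bead, water, syringe_1ml, boundary="upper")
        lo = sy.analytic_curve(ps_bead, water, syringe_1ml, boundary="lower")
        assert up.source == "analytic_upper" and lo.source == "analytic_lower"
        for c in (up, lo):
            assert c.ratio[0] == 1.0 and c.ratio[-1] == pytest.approx(0.0, abs=1e-12)
            assert np.all(np.diff(c.ratio) <= 1e-12)
            assert c.effective_area is not None
        assert up.times[-1] == pytest.approx(2 * lo.times[-1])
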