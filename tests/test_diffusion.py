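"""Diffusion solver, linearity scoring and effective-D inversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hepazone import diffusion as dif
from hepazone.errors import BracketError, InvalidParameterError, UndefinedMetricError

from conftest import theta_closed_form


class TestDiffusionCoefficientScaling:
    def test_chir_from_rhodamine_matches_published_estimate(self):
        d = dif.estimate_diffusion_coefficient(dif.CHIR99021, dif.RHODAMINE_B_AGAROSE)
        assert d == pytest.approx(2.98e-6, rel=0.01)
        # full-precision value of the cube-root scaling itself
        assert d == pytest.approx(2.96e-6 * (479.0 / 465.34) ** (1 / 3), rel=1e-12)

    def test_identity_and_exact_cube(self):
        ref = dif.ReferenceDiffusion(dif.SoluteDescriptor("ref", 800.0), 1.0e-6)
        same = dif.estimate_diffusion_coefficient(dif.SoluteDescriptor("x", 800.0), ref)
        assert same == pytest.approx(1.0e-6, rel=1e-12)
        light = dif.estimate_diffusion_coefficient(dif.SoluteDescriptor("y", 100.0), ref)
        assert light == pytest.approx(2.0e-6, rel=1e-12)

    def test_scale_equivariance_in_reference_D(self):
        sol = dif.SoluteDescriptor("s", 300.0)
        ref1 = dif.ReferenceDiffusion(dif.SoluteDescriptor("r", 500.0), 1e-6)
        ref3 = dif.ReferenceDiffusion(dif.SoluteDescriptor("r", 500.0), 3e-6)
        assert dif.estimate_diffusion_coefficient(sol, ref3) == pytest.approx(
            3.0 * dif.estimate_diffusion_coefficient(sol, ref1), rel=1e-12
        )

    def test_invalid_parameters_raise(self):
        with pytest.raises(InvalidParameterError):
            dif.SoluteDescriptor("bad", 0.0)
        with pytest.raises(InvalidParameterError):
            dif.ReferenceDiffusion(dif.RHODAMINE_B, -1e-6)


class TestSolver:
    def test_initial_condition_interior_zero(self, geom, bc):
        for method in ("analytic_series", "finite_difference"):
            p = dif.solve_profile(geom, bc, 1e-5, 0.0, method=method)
            assert p.concentrations[0] == bc.c_inlet1
            assert p.concentrations[-1] == bc.c_inlet2
            assert np.all(p.concentrations[1:-1] == 0.0)

    def test_boundaries_exact_at_all_times(self, geom, bc):
        for t_days in (0.5, 7.0, 40.0):
            p = dif.solve_profile(geom, bc, 1e-5, t_days * dif.DAY_S)
            assert p.concentrations[0] == bc.c_inlet1
            assert p.concentrations[-1] == bc.c_inlet2

    def test_steady_state_is_linear(self, geom, bc):
        t = 2.0 * geom.length**2 / 1e-5  # tau = 2
        p = dif.solve_profile(geom, bc, 1e-5, t)
        line = bc.c_inlet1 + (bc.c_inlet2 - bc.c_inlet1) * p.positions / geom.length
        assert np.abs(p.concentrations - line).max() < 1e-6

    @pytest.mark.parametrize("tau", [1e-3, 0.05])
    def test_methods_agree(self, geom, bc, tau):
        """Fourier series and explicit FD cross-validate below 1e-3 uM."""
        t = tau * geom.length**2 / 1e-5
        pa = dif.solve_profile(geom, bc, 1e-5, t)
        pf = dif.solve_profile(geom, bc, 1e-5, t, method="finite_difference")
        assert np.abs(pa.concentrations - pf.concentrations).max() < 1e-3

    def test_negative_time_rejected(self, geom, bc):
        with pytest.raises(InvalidParameterError):
            dif.solve_profile(geom, bc, 1e-5, -1.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(log_tau=st.floats(min_value=-4.0, max_value=math.log10(2.0)))
    def test_profile_monotone_and_bounded(self, geom, bc, log_tau):
        """With c1 < c2 the profile never decreases in x nor leaves [c1, c2]."""
        t = 10.0**log_tau * geom.length**2 / 1e-5
        p = dif.solve_profile(geom, bc, 1e-5, t)
        assert np.all(np.diff(p.concentrations) >= -1e-9)
        assert p.concentrations.min() >= -1e-12
        assert p.concentrations.max() <= bc.c_inlet2 * (1 + 1e-12)


def _brute_force_windowed_theta(x, c, window_frac=0.05):
    """Independent re-implementation of the windowed tangent estimator."""
    n = x.size
    size = max(1, round(window_frac * (n - 1)))
    half = size // 2
    padded = np.concatenate([np.full(half, c[0]), c, np.full(size - 1 - half, c[-1])])
    kernel = np.full(size, 1.0 / size)
    smooth = np.convolve(padded, kernel, mode="valid")
    span = x[-1] - x[0]
    mid = x[0] + 0.5 * span
    h = window_frac * span
    i_lo = int(np.argmin(np.abs(x - (mid - h))))
    i_hi = int(np.argmin(np.abs(x - (mid + h))))
    local = (smooth[i_hi] - smooth[i_lo]) / (x[i_hi] - x[i_lo])
    return local / ((c[-1] - c[0]) / span)


def _series_profile(x, L, tau, n_terms=500):
    """Naive term-by-term Fourier evaluation, independent of the solver."""
    f = x / L
    for n in range(1, n_terms + 1):
        f = f + (2.0 / math.pi) * ((-1.0) ** n / n) * np.sin(
            n * math.pi * x / L
        ) * math.exp(-(n**2) * math.pi**2 * tau)
    return f


class TestLinearityMetric:
    def test_exactly_linear_profile_scores_one(self):
        x = np.linspace(0.0, 9.0, 901)
        p = dif.ConcentrationProfile(x, x, 0.0)
        assert dif.linearity_metric(p) == pytest.approx(1.0, abs=1e-12)

    def test_step_at_midpoint_scores_far_above_one(self):
        x = np.linspace(0.0, 9.0, 901)
        c = np.where(x < 4.5, 0.0, 9.0)
        assert dif.linearity_metric(dif.ConcentrationProfile(x, c, 0.0)) > 5.0

    def test_jump_outside_mid_window_scores_near_zero(self):
        x = np.linspace(0.0, 9.0, 901)
        c = np.where(x < 8.0, 0.0, 9.0)
        assert dif.linearity_metric(dif.ConcentrationProfile(x, c, 0.0)) < 0.05

    def test_flat_profile_is_undefined(self):
        x = np.linspace(0.0, 9.0, 101)
        with pytest.raises(UndefinedMetricError):
            dif.linearity_metric(dif.ConcentrationProfile(x, np.full(101, 3.0), 0.0))

    def test_windowed_series_oracle_at_tau_005(self, geom, bc):
        """Solver theta equals an independent windowed series evaluation."""
        tau = 0.05
        t = tau * geom.length**2 / 1e-5
        theta_impl = dif.linearity_metric(dif.solve_profile(geom, bc, 1e-5, t))
        x = np.linspace(0.0, geom.length, geom.n_grid)
        c = bc.c_inlet2 * _series_profile(x, geom.length, tau)
        theta_oracle = _brute_force_windowed_theta(x, c)
        assert theta_impl == pytest.approx(theta_oracle, abs=1e-3)
        # the pure mid-channel tangent differs only by the O(window^2) bias
        assert theta_impl == pytest.approx(theta_closed_form(tau), abs=0.01)

    def test_theta_monotone_in_time_and_saturates(self, geom, bc):
        taus = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.5, 2.0])
        times = taus * geom.length**2 / 1e-5
        thetas = dif.linearity_vs_time(geom, bc, 1e-5, times)
        assert np.all(np.diff(thetas) > 0)
        assert np.all((thetas > 0) & (thetas <= 1.0))
        assert thetas[-1] == pytest.approx(1.0, abs=1e-6)


class TestOptimalLinearTime:
    def test_matches_bisection_on_closed_form(self, geom, bc):
        """Grid search crosses theta_min within one grid step of the root."""
        from scipy.optimize import brentq

        d = 1.2444e-5
        tau_star = brentq(lambda u: theta_closed_form(u) - 0.95, 0.01, 0.5)
        t_star_cf = tau_star * geom.length**2 / d
        step = 0.1 * dif.DAY_S
        times = np.arange(1.0, 15.0, 0.1) * dif.DAY_S
        res = dif.optimal_linear_time(geom, bc, d, times, theta_min=0.95)
        assert res.reached
        assert abs(res.time - t_star_cf) <= step + 1e-9

    def test_diffusive_time_scaling(self, geom, bc):
        d = 4e-6
        times = np.linspace(0.5, 30.0, 60) * dif.DAY_S
        res1 = dif.optimal_linear_time(geom, bc, d, times, theta_min=0.9)
        res4 = dif.optimal_linear_time(geom, bc, 4 * d, times / 4.0, theta_min=0.9)
        assert res1.reached and res4.reached
        assert res4.time == pytest.approx(res1.time / 4.0, rel=1e-9)

    def test_not_reached_flag_returns_closest(self, geom, bc):
        times = np.array([0.5, 1.0]) * dif.DAY_S  # far from linear with small D
        res = dif.optimal_linear_time(geom, bc, 2.98e-6, times, theta_min=0.95)
        assert not res.reached
        assert res.time == times[-1]  # theta increases with t, so latest is closest


class TestInvertEffectiveD:
    def test_round_trip_recovers_known_D(self, geom, bc):
        d_true = 8e-6
        t = 7 * dif.DAY_S
        theta = dif.linearity_metric(dif.solve_profile(geom, bc, d_true, t))
        d_eff = dif.invert_effective_D(geom, bc, t, theta)
        assert d_eff == pytest.approx(d_true, rel=0.01)

    def test_day7_linearity_needs_more_than_molecular_estimate(self, geom, bc):
        """A theta=0.95 day-7 gradient implies a larger effective D than the
        Mw-scaled molecular estimate 2.98e-6 cm^2/s."""
        d_eff = dif.invert_effective_D(geom, bc, 7 * dif.DAY_S, 0.95)
        assert d_eff > 2.98e-6

    def test_Dt_invariance_doubling_time_halves_D(self, geom, bc):
        d1 = dif.invert_effective_D(geom, bc, 7 * dif.DAY_S, 0.9)
        d2 = dif.invert_effective_D(geom, bc, 14 * dif.DAY_S, 0.9)
        assert d2 == pytest.approx(d1 / 2.0, rel=0.01)

    def test_unreachable_target_raises_bracket_error(self, geom, bc):
        with pytest.raises(BracketError):
            dif.invert_effective_D(geom, bc, 60.0, 0.99, bracket=(1e-9, 1e-8))

    def test_invalid_target_rejected(self, geom, bc):
        with pytest.raises(InvalidParameterError):
            dif.invert_effective_D(geom, bc, 60.0, 1.5)


class TestProfileIO:
    def test_csv_round_trip(self, tmp_path, geom, bc):
        profiles = dif.solve_profiles(
            geom, bc, 1e-5, np.array([1.0, 7.0]) * dif.DAY_S
        )
        path = tmp_path / "profiles.csv"
        dif.write_profiles_csv(profiles, path)
        back = dif.read_profiles_csv(path)
        assert len(back) == 2
        for orig, rt in zip(profiles, back):
            assert rt.time_days == pytest.approx(orig.time_days)
            np.testing.assert_allclose(rt.concentrations, orig.concentrations)
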