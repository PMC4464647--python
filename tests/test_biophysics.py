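"""GHK current equation, permeability fits, Boltzmann activation, QC, inhibition."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.optimize import least_squares

from wholecell.biophysics import (
    GHKContext,
    InconsistentPointError,
    PermeabilityCurve,
    boltzmann,
    fit_boltzmann,
    fit_ghk_permeability,
    ghk_current,
    ghk_shape,
    invert_permeability,
    percent_inhibition,
    qc_reversal_filter,
    reversal_potential,
    summarize_inhibition,
)
from wholecell.solutions import FARADAY, GAS_CONSTANT

P0 = 2.0e-17  # typical whole-cell permeability scale, m^3/s


class TestGhkCurrent:
    def test_symmetric_concentrations_are_ohmic(self):
        """With Co = Ci the constant-field equation collapses to a line in V."""
        ctx = GHKContext(co_mm=150.0, ci_mm=150.0)
        v = np.array([-80.0, -20.0, 5.0, 60.0])
        expected = 1e12 * P0 * ctx.z**2 * FARADAY**2 * (v * 1e-3) * 150.0 / (
            GAS_CONSTANT * ctx.temperature_k)
        assert ghk_current(P0, v, ctx) == pytest.approx(expected, rel=1e-12)

    def test_zero_current_at_nernst_potential(self, cl_context):
        i = ghk_current(P0, cl_context.vrev_mv, cl_context)
        assert abs(i) < 1e-9 * abs(ghk_current(P0, 100.0, cl_context))

    def test_continuity_across_zero_voltage(self, cl_context):
        """Series branch agrees with direct expm1 evaluation to 1e-9 relative."""
        for v_mv in (-0.005, 0.005):
            # independent direct evaluation of the constant-field expression
            u = cl_context.z * FARADAY * v_mv * 1e-3 / (
                GAS_CONSTANT * cl_context.temperature_k)
            direct = 1e12 * P0 * cl_context.z * FARADAY * u * (
                cl_context.ci_mm - (cl_context.co_mm - cl_context.ci_mm)
                / np.expm1(u))
            assert ghk_current(P0, v_mv, cl_context) == \
                pytest.approx(direct, rel=1e-9)
        # the genuine curvature of I(V) near 0 is ~3e-9 relative at +-5 uV,
        # so the midpoint check is held at 1e-8
        below = ghk_current(P0, -0.005, cl_context)
        above = ghk_current(P0, 0.005, cl_context)
        assert ghk_current(P0, 0.0, cl_context) == \
            pytest.approx((below + above) / 2.0, rel=1e-8)

    def test_strictly_increasing_in_voltage(self, cl_context):
        v = np.linspace(-120.0, 120.0, 241)
        i = ghk_current(P0, v, cl_context)
        assert np.all(np.diff(i) > 0)

    def test_negative_permeability_rejected(self, cl_context):
        with pytest.raises(ValueError):
            ghk_current(-1e-18, 10.0, cl_context)


class TestPermeabilityFit:
    def test_noiseless_data_recovers_p_exactly(self, cl_context):
        v = np.arange(-100.0, 121.0, 20.0)
        fit = fit_ghk_permeability(v, ghk_current(P0, v, cl_context), cl_context)
        assert fit.p_hat == pytest.approx(P0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_closed_form_equals_generic_least_squares(self, cl_context, rng):
        """The one-parameter GHK fit must match an independent optimizer to 1e-10."""
        v = np.arange(-100.0, 121.0, 20.0)
        for _ in range(5):
            i = ghk_current(P0, v, cl_context) + rng.normal(0, 20.0, v.size)
            closed = fit_ghk_permeability(v, i, cl_context).p_hat
            res = least_squares(
                lambda p: ghk_current(abs(p[0]) * 1e-17, v, cl_context) - i,
                x0=[1.0], method="lm")
            assert closed == pytest.approx(abs(res.x[0]) * 1e-17, rel=1e-10)

    def test_estimator_is_unbiased_with_matching_variance(self, cl_context, rng):
        """Monte Carlo: mean(P_hat) -> P0 and sd -> sigma/sqrt(sum g^2)."""
        v = np.arange(-100.0, 121.0, 20.0)
        g = ghk_shape(v, cl_context)
        sigma = 25.0
        i0 = ghk_current(P0, v, cl_context)
        sims = i0 + rng.normal(0.0, sigma, size=(1000, v.size))
        p_hats = sims @ g / (g @ g)
        sd_expected = sigma / np.sqrt(g @ g)
        assert p_hats.mean() == pytest.approx(P0, abs=4 * sd_expected / np.sqrt(1000))
        assert p_hats.std(ddof=1) == pytest.approx(sd_expected, rel=0.15)

    def test_too_few_points_rejected(self, cl_context):
        with pytest.raises(ValueError):
            fit_ghk_permeability([0.0, 10.0], [0.0, 1.0], cl_context)


class TestInversion:
    def test_round_trip_identity_on_voltage_grid(self, cl_context):
        v = np.arange(-100.0, 121.0, 10.0)
        v = v[np.abs(v - cl_context.vrev_mv) > 2.0]
        for vi in v:
            i = ghk_current(P0, vi, cl_context)
            assert invert_permeability(vi, i, cl_context) == \
                pytest.approx(P0, rel=1e-12)

    def test_zero_current_off_reversal_means_zero_permeability(self, cl_context):
        assert invert_permeability(50.0, 0.0, cl_context) == 0.0

    def test_v_zero_limit_form(self, cl_context):
        """At V = 0 the inversion uses the finite limit I = zF(Ci - Co)P."""
        i = ghk_current(P0, 0.0, cl_context)
        assert invert_permeability(0.0, i, cl_context) == pytest.approx(P0, rel=1e-9)

    def test_nonzero_current_at_reversal_is_flagged(self, cl_context):
        with pytest.raises(InconsistentPointError):
            invert_permeability(cl_context.vrev_mv, 25.0, cl_context)


class TestBoltzmann:
    def test_exact_samples_recover_parameters(self):
        v = np.arange(-100.0, 121.0, 20.0)
        p = boltzmann(v, 0.1 * P0, P0, 61.0, 12.0)
        fit, norm = fit_boltzmann(PermeabilityCurve(v, p))
        assert fit.v_half_mv == pytest.approx(61.0, rel=1e-6)
        assert fit.dv_mv == pytest.approx(12.0, rel=1e-6)
        assert fit.p_max == pytest.approx(P0, rel=1e-6)
        assert fit.p_min == pytest.approx(0.1 * P0, rel=1e-6)

    def test_normalized_curve_is_half_at_v_half(self):
        v = np.arange(-100.0, 121.0, 5.0)
        p = boltzmann(v, 0.2 * P0, P0, 35.0, 10.0)
        fit, norm = fit_boltzmann(PermeabilityCurve(v, p))
        assert norm.normalized
        mid = np.interp(fit.v_half_mv, norm.v_mv, norm.p)
        assert mid == pytest.approx(0.5, abs=1e-6)

    def test_recovery_under_relative_noise(self):
        """Median |V_half error| < 3 mV over 100 cohorts of 10 noisy curves."""
        rng = np.random.default_rng(7)
        v = np.arange(-100.0, 121.0, 20.0)
        errors = []
        for _ in range(100):
            cohort = []
            for _ in range(10):
                true_vh = rng.normal(61.0, 3.0)
                p = boltzmann(v, 0.0, P0, true_vh, 12.0)
                p_noisy = p * (1 + 0.05 * rng.standard_normal(v.size))
                fit, _ = fit_boltzmann(PermeabilityCurve(v, p_noisy))
                cohort.append(fit.v_half_mv - true_vh)
            errors.append(abs(np.mean(cohort)))
        assert np.median(errors) < 3.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_boltzmann(PermeabilityCurve(np.array([0.0, 20, 40, 60]),
                                            np.array([0.0, 0.2, 0.8, 1.0])))


class TestReversalAndQc:
    def test_linear_interpolation_between_brackets(self):
        assert reversal_potential([-10.0, 10.0], [-1.0, 1.0]) == pytest.approx(0.0)

    def test_ghk_iv_reverses_at_nernst_within_grid_error(self, cl_context):
        v = np.arange(-100.0, 121.0, 20.0)
        i = ghk_current(P0, v, cl_context)
        assert reversal_potential(v, i) == pytest.approx(cl_context.vrev_mv,
                                                         abs=0.5)

    def test_monotone_positive_current_has_no_reversal(self):
        with pytest.raises(ValueError):
            reversal_potential([0.0, 20.0, 40.0], [1.0, 2.0, 3.0])

    def test_qc_keeps_cells_at_e_cl_and_drops_shifted_ones(self):
        included, excluded = qc_reversal_filter(
            {"a": -28.4, "b": -28.4 + 30.0, "c": -40.0}, e_cl_mv=-28.4)
        assert included == ["a", "c"]
        assert [e[0] for e in excluded] == ["b"]
        assert "30.0 mV positive" in excluded[0][1]


class TestInhibition:
    @pytest.mark.parametrize("control, treated, expected",
                             [(100.0, 100.0, 0.0), (100.0, 0.0, 100.0),
                              (200.0, 114.0, 43.0)])
    def test_percent_inhibition(self, control, treated, expected):
        assert percent_inhibition(control, treated) == pytest.approx(expected)

    def test_zero_control_rejected(self):
        with pytest.raises(ValueError):
            percent_inhibition(0.0, 10.0)

    @given(scale=st.floats(0.01, 100.0))
    def test_invariant_under_common_rescaling(self, scale):
        assert percent_inhibition(120.0 * scale, 70.0 * scale) == \
            pytest.approx(percent_inhibition(120.0, 70.0), rel=1e-9)

    def test_cohort_summary_mean_and_sem(self):
        mean, sem = summarize_inhibition([(100, 50), (100, 60), (100, 40)])
        assert mean == pytest.approx(50.0)
        assert sem == pytest.approx(10.0 / np.sqrt(3))
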