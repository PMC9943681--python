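"""Protection-kinetics model evaluation, fitting, diagnostics and rate
conversion, checked against independent oracles (exhaustive grid search,
golden-section, closed forms)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colocseq.io import ColocError
from colocseq.kinetics import (MODEL1, MODEL2, confidence_intervals,
                               convert_rate, fit_model1, fit_model2,
                               k_to_k_prime, model1_eval, model2_eval,
                               parameter_dependency, select_model)

from conftest import GRID, grid_oracle, profile


class TestModelEval:
    def test_untreated_is_one(self):
        for p0, k in [(0.0, 0.5), (0.3, 2.0), (1.0, 7.0)]:
            assert model1_eval(0.0, p0, k) == 1.0

    def test_fully_protected_is_one(self):
        """P0 = 1 is the fully protected limit: f = 1 at any concentration."""
        assert model1_eval(5.0, 1.0, 3.0) == 1.0
        np.testing.assert_allclose(model1_eval(GRID, 1.0, 0.7), 1.0)

    def test_half_decay_closed_form(self):
        """Pure decay reaches 1/2 exactly when k'A = ln 2."""
        assert model1_eval(np.log(2) / 1.7, 0.0, 1.7) == pytest.approx(0.5, abs=1e-15)

    @given(p0=st.floats(0, 1), k=st.floats(0, 50), a=st.floats(0, 10))
    @settings(max_examples=100, deadline=None)
    def test_range_and_monotonicity(self, p0, k, a):
        v = model1_eval(a, p0, k)
        assert p0 - 1e-12 <= v <= 1.0 + 1e-12
        assert model1_eval(a + 0.5, p0, k) <= v + 1e-12

    def test_domain_violations_fatal(self):
        with pytest.raises(ColocError):
            model1_eval(-1.0, 0.5, 1.0)
        with pytest.raises(ColocError):
            model1_eval(1.0, 1.5, 1.0)
        with pytest.raises(ColocError):
            model1_eval(1.0, 0.5, -1.0)


class TestFitModel1:
    def test_noiseless_recovery(self):
        """Exact parameter recovery from noiseless data on the experimental
        concentration grid, cross-checked against the grid-search oracle."""
        A = np.array([0, 0.2, 0.6, 1.2, 2.0, 2.6, 3.2, 4.0, 6.0])
        f = model1_eval(A, 0.4, 1.5)
        fit = fit_model1(profile(f, conc=A))
        assert fit.P0 == pytest.approx(0.4, abs=1e-6)
        assert fit.k_prime == pytest.approx(1.5, abs=1e-6)
        ss_o, p_o, k_o = grid_oracle(A, f)
        assert fit.residual_ss <= ss_o + 1e-6

    def test_flat_data_hits_protected_limit(self):
        fit = fit_model1(profile(np.ones(9)))
        assert fit.P0 == pytest.approx(1.0, abs=1e-9)
        assert fit.r_squared <= 0.0

    def test_pure_decay_p0_at_zero(self):
        A = GRID
        fit = fit_model1(profile(model1_eval(A, 0.0, 2.0), conc=A))
        assert fit.P0 <= 1e-3
        assert fit.k_prime == pytest.approx(2.0, abs=1e-3)

    def test_too_few_points_fatal(self):
        with pytest.raises(ColocError, match="points"):
            fit_model1(profile([1.0, 0.5, 0.3], conc=[0.0, 1.0, 2.0]))

    def test_nonfinite_fatal(self):
        with pytest.raises(ColocError):
            fit_model1(profile([1.0, np.nan, 0.3, 0.2], conc=[0, 1, 2, 3]))

    @pytest.mark.parametrize("p0,k", [(0.0, 0.8), (0.2, 3.0), (0.5, 2.0),
                                      (0.8, 1.0), (0.95, 4.0)])
    def test_recovery_across_parameter_space(self, p0, k):
        """Noiseless recovery <= 1e-6 whenever the decay is observable
        (k' A_max >= 1) and the plateau is below 0.95."""
        f = model1_eval(GRID, p0, k)
        fit = fit_model1(profile(f, conc=GRID))
        assert abs(fit.P0 - p0) <= 1e-6
        assert abs(fit.k_prime - k) <= 1e-5

    def test_units_invariance(self):
        """Rescaling concentrations by c and k' by 1/c leaves P0 and the
        predicted curve unchanged."""
        rng = np.random.default_rng(0)
        f = model1_eval(GRID, 0.35, 1.2) + rng.normal(0, 0.03, len(GRID))
        f[0] = 1.0
        f = np.clip(f, 0, None)
        fit1 = fit_model1(profile(f, conc=GRID))
        fit2 = fit_model1(profile(f, conc=GRID * 4.0))
        assert fit2.P0 == pytest.approx(fit1.P0, abs=1e-6)
        assert fit2.k_prime == pytest.approx(fit1.k_prime / 4.0, abs=1e-6)


class TestFitModel2:
    def test_noiseless_recovery_vs_golden_section(self):
        from scipy.optimize import minimize_scalar
        A = GRID
        f = model2_eval(A, 1.0)
        fit = fit_model2(profile(f, conc=A))
        assert fit.k_prime == pytest.approx(1.0, abs=1e-6)
        oracle = minimize_scalar(lambda k: np.sum((np.exp(-k * A) - f) ** 2),
                                 bracket=(0.01, 5.0), method="golden")
        assert fit.residual_ss <= oracle.fun + 1e-9

    def test_flat_data_zero_rate(self):
        fit = fit_model2(profile(np.ones(9)))
        assert fit.k_prime == pytest.approx(0.0, abs=1e-6)
        assert fit.P0 == 0.0 and fit.P0_ci == (0.0, 0.0)

    def test_fast_decay_near_zero_tail(self):
        A = GRID
        f = model2_eval(A, 10.0 / A.max())
        fit = fit_model2(profile(f, conc=A))
        assert fit.r_squared > 0.999

    def test_model_nesting(self):
        """Model 1 with P0 pinned at 0 reproduces Model 2's SS."""
        rng = np.random.default_rng(7)
        for _ in range(50):
            p0 = rng.uniform(0, 1)
            k = rng.uniform(0.1, 5)
            f = np.clip(model1_eval(GRID, p0, k) + rng.normal(0, 0.05, len(GRID)), 0, None)
            f[0] = 1.0
            prof = profile(f, conc=GRID)
            pinned = fit_model1(prof, fix_p0=0.0)
            free2 = fit_model2(prof)
            assert abs(pinned.residual_ss - free2.residual_ss) <= 1e-9


class TestSelectModel:
    def test_well_behaved_keeps_model1(self):
        rng = np.random.default_rng(21)
        f = np.clip(model1_eval(GRID, 0.5, 2.0) * rng.normal(1, 0.05, len(GRID)), 0, None)
        f[0] = 1.0
        fit = select_model(profile(f, conc=GRID))
        assert fit.model == MODEL1
        assert fit.dependency < 0.3
        assert fit.P0 == pytest.approx(0.5, abs=0.1)

    def test_noisy_flat_profile_falls_back(self):
        """A profile that is flat within noise leaves plateau and rate
        entangled; the one-parameter decay is reported instead (the pattern
        of membrane-protected organellar transcripts)."""
        rng = np.random.default_rng(3)
        f = np.clip(np.ones(len(GRID)) * rng.normal(1, 0.06, len(GRID)), 0, None)
        f[0] = 1.0
        fit1 = fit_model1(profile(f, conc=GRID))
        fit = select_model(profile(f, conc=GRID))
        assert fit1.dependency > 0.3
        assert fit.model == MODEL2

    def test_pure_decay_keeps_model1_when_clean(self):
        f = model1_eval(GRID, 0.0, 2.0)
        fit = select_model(profile(f, conc=GRID))
        assert fit.converged
        if fit.model == MODEL1:
            assert fit.dependency <= 0.3


class TestParameterDependency:
    def test_bound_pinned_parameter_zero(self):
        f = model1_eval(GRID, 0.0, 2.0)
        fit = fit_model1(profile(f, conc=GRID))
        assert fit.P0 <= 1e-6
        assert fit.dependency == 0.0

    def test_nearly_flat_high_dependency(self):
        """Finite-difference curvature oracle agrees that a near-flat profile
        entangles the parameters almost completely."""
        f = model1_eval(GRID, 0.5, 0.05)
        fit = fit_model1(profile(f, conc=GRID))
        dep = parameter_dependency(fit, profile(f, conc=GRID))
        assert dep >= 0.9
        # oracle: numerical Jacobian via central differences
        h = 1e-6

        def model(p0, k):
            return (1 - p0) * np.exp(-k * GRID) + p0

        J = np.column_stack([
            (model(fit.P0 + h, fit.k_prime) - model(fit.P0 - h, fit.k_prime)) / (2 * h),
            (model(fit.P0, fit.k_prime + h) - model(fit.P0, fit.k_prime - h)) / (2 * h),
        ])
        C = np.linalg.inv(J.T @ J)
        rho2 = C[0, 1] ** 2 / (C[0, 0] * C[1, 1])
        assert dep == pytest.approx(rho2, abs=1e-4)

    def test_well_separated_plateau_low_dependency(self):
        f = model1_eval(GRID, 0.5, 4.0)
        fit = fit_model1(profile(f, conc=GRID))
        assert fit.dependency < 0.3


class TestConfidenceIntervals:
    def test_noiseless_degenerate_point(self):
        f = model1_eval(GRID, 0.4, 1.5)
        prof = profile(f, conc=GRID)
        fit = confidence_intervals(fit_model1(prof), prof)
        assert fit.P0_ci == pytest.approx((0.4, 0.4), abs=1e-6)

    def test_decay_lower_bound_clipped_at_zero(self):
        rng = np.random.default_rng(11)
        f = np.clip(model1_eval(GRID, 0.0, 2.0) + rng.normal(0, 0.04, len(GRID)), 0, None)
        f[0] = 1.0
        prof = profile(f, conc=GRID)
        fit = confidence_intervals(fit_model1(prof), prof)
        assert fit.P0_ci[0] == 0.0

    def test_interval_contains_estimate(self):
        rng = np.random.default_rng(13)
        for _ in range(10):
            f = np.clip(model1_eval(GRID, 0.5, 3.0) * rng.normal(1, 0.08, len(GRID)), 0, None)
            f[0] = 1.0
            prof = profile(f, conc=GRID)
            fit = confidence_intervals(select_model(prof), prof)
            assert fit.P0_ci[0] - 1e-9 <= fit.P0 <= fit.P0_ci[1] + 1e-9
            assert fit.k_ci[0] - 1e-9 <= fit.k_prime <= fit.k_ci[1] + 1e-9

    def test_iid_noise_coverage_near_nominal(self):
        """With independent Gaussian noise on f the 95% profile-likelihood
        interval covers the true P0 at close to nominal rate (200 fixed-seed
        simulations; tolerance 95% +/- 5%)."""
        rng = np.random.default_rng(5)
        A = np.tile(GRID, 2)
        rep = np.repeat(["r1", "r2"], len(GRID))
        cover = 0
        for _ in range(200):
            f = model1_eval(A, 0.5, 4.38) + rng.normal(0, 0.05, len(A))
            f[A == 0] = 1.0
            prof = profile(np.clip(f, 0, None), conc=A, replicate=rep)
            fit = confidence_intervals(select_model(prof), prof)
            cover += (fit.P0_ci[0] - 1e-12 <= 0.5 <= fit.P0_ci[1] + 1e-12)
        assert 0.90 <= cover / 200 <= 1.0


class TestConvertRate:
    def test_dimensional_analysis(self):
        """k' = 1 per (μg/ml) at MW 13,700 and t = 600 s converts to
        1 / (1e-3/13700 * 600) ≈ 2.28e4 M^-1 s^-1 (hand computation)."""
        rc = convert_rate(1.0, enzyme_mw=13_700.0, t=600.0)
        assert rc.k == pytest.approx(13_700.0 / (1e-3 * 600.0), rel=1e-12)
        assert rc.k == pytest.approx(2.28e4, rel=0.01)

    def test_zero_rate(self):
        assert convert_rate(0.0).k == 0.0

    def test_time_proportionality(self):
        assert convert_rate(1.0, t=1200.0).k == pytest.approx(convert_rate(1.0, t=600.0).k / 2)

    def test_round_trip(self):
        assert k_to_k_prime(convert_rate(2.5).k) == pytest.approx(2.5, rel=1e-12)

    def test_invalid_inputs_fatal(self):
        with pytest.raises(ColocError):
            convert_rate(-1.0)
        with pytest.raises(ColocError):
            convert_rate(1.0, enzyme_mw=0.0)


class TestOracleEquivalence:
    def test_fitter_at_least_as_good_as_grid_search(self):
        """On 50 random small profiles the bounded least-squares fit never
        loses to the exhaustive grid-search oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            n = rng.integers(5, 11)
            A = np.sort(np.concatenate([[0.0], rng.uniform(0.05, 6.0, n - 1)]))
            p0, k = rng.uniform(0, 1), rng.uniform(0, 5)
            f = np.clip(model1_eval(A, p0, k) + rng.normal(0, 0.1, n), 0, None)
            f[0] = 1.0
            fit = fit_model1(profile(f, conc=A))
            ss_o, _, _ = grid_oracle(A, f)
            assert fit.residual_ss <= ss_o + 1e-6
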