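"""Recinormal density/CDF, closed-form MLE, reciprobit transform, early mixture."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from laterkit import (
    DegenerateDataError,
    InsufficientDataError,
    RaceParams,
    RecinormalParams,
    fit_early_mixture,
    fit_recinormal,
    recinormal_cdf,
    recinormal_loglik,
    recinormal_pdf,
    recinormal_ppf,
    reciprobit_transform,
    simulate_later,
    theoretical_reciprobit,
)

PARAMS = RecinormalParams(2.0, 0.5)


class TestDensityAndCdf:
    def test_pdf_at_promptness_mean(self):
        # mode of the promptness normal maps to z = 0
        t = 1.0 / PARAMS.mu_p
        expected = PARAMS.mu_p**2 / PARAMS.sigma_p * stats.norm.pdf(0.0)
        assert recinormal_pdf(t, PARAMS) == pytest.approx(expected, rel=1e-12)

    def test_pdf_is_derivative_of_cdf(self):
        t = 0.5
        h = 1e-6
        numeric = (recinormal_cdf(t + h, PARAMS) - recinormal_cdf(t - h, PARAMS)) / (2 * h)
        assert recinormal_pdf(t, PARAMS) == pytest.approx(numeric, rel=1e-6)

    def test_pdf_total_mass_equals_positive_promptness_mass(self):
        params = RecinormalParams(3.0, 0.3)
        total, _ = integrate.quad(
            lambda t: recinormal_pdf(t, params), 1e-9, 1000,
            points=[0.2, 1 / 3, 0.5, 1.0], limit=300,
        )
        assert total == pytest.approx(stats.norm.cdf(10.0), abs=1e-6)

    def test_cdf_half_at_promptness_mean(self):
        assert recinormal_cdf(1.0 / PARAMS.mu_p, PARAMS) == pytest.approx(0.5, abs=1e-12)

    def test_cdf_closed_form_value(self):
        # P(T <= 1) = P(promptness >= 1) = 1 - Phi((1-2)/0.5) = Phi(2)
        assert recinormal_cdf(1.0, PARAMS) == pytest.approx(stats.norm.cdf(2.0), rel=1e-12)

    def test_cdf_vanishes_at_short_times(self):
        assert recinormal_cdf(1e-6, PARAMS) == pytest.approx(0.0, abs=1e-300)

    @pytest.mark.parametrize("mu,sigma", [(2.0, 0.5), (3.0, 0.3), (1.0, 0.4)])
    def test_cdf_matches_quadrature_of_pdf(self, mu, sigma):
        params = RecinormalParams(mu, sigma)
        for t in (0.2, 0.5, 1.0, 3.0):
            quad, _ = integrate.quad(lambda u: recinormal_pdf(u, params), 1e-12, t, limit=200)
            assert quad == pytest.approx(recinormal_cdf(t, params), abs=1e-8)

    @pytest.mark.parametrize("bad_t", [0.0, -1.0])
    def test_nonpositive_time_rejected(self, bad_t):
        with pytest.raises(ValueError):
            recinormal_pdf(bad_t, PARAMS)
        with pytest.raises(ValueError):
            recinormal_cdf(bad_t, PARAMS)

    def test_ppf_inverts_cdf(self):
        q = np.array([0.1, 0.5, 0.9])
        t = recinormal_ppf(q, PARAMS)
        assert recinormal_cdf(t, PARAMS) == pytest.approx(q, rel=1e-10)


class TestParams:
    def test_reliability_flag_not_an_error(self):
        assert not RecinormalParams(1.0, 0.9).reliable
        assert RecinormalParams(3.0, 0.3).reliable

    @pytest.mark.parametrize("mu,sigma", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0), (1.0, -0.5)])
    def test_invalid_params_rejected(self, mu, sigma):
        with pytest.raises(ValueError):
            RecinormalParams(mu, sigma)

    def test_race_params_map_exactly_to_promptness_scale(self):
        race = RaceParams(theta=2.0, mu_r=6.0, sigma_r=1.0)
        rn = race.to_recinormal()
        assert rn.mu_p == pytest.approx(3.0)
        assert rn.sigma_p == pytest.approx(0.5)
        back = RaceParams.from_recinormal(rn)
        assert back.theta == 1.0
        assert back.to_recinormal() == rn


class TestMLE:
    def test_closed_form_on_hand_data(self):
        fit = fit_recinormal([0.5, 0.5, 0.25, 0.25])  # promptness 2,2,4,4
        assert fit.params.mu_p == pytest.approx(3.0)
        assert fit.params.sigma_p == pytest.approx(1.0)

    def test_recovers_generating_parameters_at_large_n(self):
        truth = RecinormalParams(2.96, 0.4)
        fit = fit_recinormal(simulate_later(truth, 10_000, seed=7))
        assert fit.params.mu_p == pytest.approx(truth.mu_p, abs=0.02)
        assert fit.params.sigma_p == pytest.approx(truth.sigma_p, abs=0.02)

    def test_mle_beats_perturbed_parameters(self, rng):
        t = simulate_later(RecinormalParams(3.0, 0.5), 200, seed=5)
        fit = fit_recinormal(t)
        for dmu in (-0.1, 0.0, 0.1):
            for dsig in (-0.1, 0.0, 0.1):
                if dmu == dsig == 0:
                    continue
                perturbed = RecinormalParams(fit.params.mu_p + dmu, fit.params.sigma_p + dsig)
                assert fit.loglik >= recinormal_loglik(t, perturbed)

    def test_mle_matches_grid_search(self):
        t = simulate_later(RecinormalParams(2.5, 0.4), 40, seed=3)
        fit = fit_recinormal(t)
        grid_mu = fit.params.mu_p + np.arange(-20, 21) * 1e-3
        grid_sig = fit.params.sigma_p + np.arange(-20, 21) * 1e-3
        best = max(
            recinormal_loglik(t, RecinormalParams(m, s)) for m in grid_mu for s in grid_sig
        )
        assert fit.loglik >= best - 1e-9

    def test_insufficient_and_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            fit_recinormal([0.4, 0.5])
        with pytest.raises(DegenerateDataError):
            fit_recinormal([0.4, 0.4, 0.4])

    @given(c=st.floats(0.1, 10.0))
    @settings(deadline=None, max_examples=30, derandomize=True)
    def test_scale_equivariance(self, c):
        t = simulate_later(RecinormalParams(3.0, 0.5), 50, seed=9)
        base = fit_recinormal(t).params
        scaled = fit_recinormal(c * t).params
        assert scaled.mu_p == pytest.approx(base.mu_p / c, rel=1e-9)
        assert scaled.sigma_p == pytest.approx(base.sigma_p / c, rel=1e-9)
        assert scaled.intercept == pytest.approx(base.intercept, rel=1e-9)


class TestReciprobit:
    def test_hand_worked_three_point_transform(self):
        pts = reciprobit_transform([1.0, 0.5, 1.0 / 3.0])
        assert pts.abscissa == pytest.approx([-3.0, -2.0, -1.0])
        expected = stats.norm.ppf([1 / 6, 1 / 2, 5 / 6])
        assert pts.ordinate == pytest.approx(expected, abs=1e-4)
        assert pts.ordinate[1] == pytest.approx(0.0, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(InsufficientDataError):
            reciprobit_transform([1.0])

    def test_theoretical_quantiles_are_exactly_linear(self):
        params = RecinormalParams(3.0, 0.5)
        pts = theoretical_reciprobit(params, 200)
        slope, intercept, _ = pts.line_fit()
        resid = pts.ordinate - (slope * pts.abscissa + intercept)
        assert np.max(np.abs(resid)) < 1e-10
        assert slope == pytest.approx(1.0 / params.sigma_p, rel=1e-9)
        assert intercept == pytest.approx(params.intercept, rel=1e-9)

    def test_sampled_data_fall_near_a_line(self):
        t = simulate_later(RecinormalParams(3.0, 0.4), 500, seed=21)
        _, _, r2 = reciprobit_transform(t).line_fit()
        assert r2 > 0.98

    def test_ties_collapse_to_mean_plotting_position(self):
        pts = reciprobit_transform([0.5, 0.5, 0.25, 1.0])  # two tied at -2
        assert pts.abscissa.size == 3
        # tied pair occupies ranks 2,3 of 4 -> mean position (1.5+2.5)/2/4 = 0.5
        i = np.argmin(np.abs(pts.abscissa + 2.0))
        assert pts.ordinate[i] == pytest.approx(0.0, abs=1e-12)

    def test_ordinate_strictly_increasing(self):
        t = simulate_later(RecinormalParams(2.0, 0.3), 100, seed=2)
        pts = reciprobit_transform(t)
        assert np.all(np.diff(pts.abscissa) > 0)
        assert np.all(np.diff(pts.ordinate) > 0)


class TestEarlyMixture:
    def test_recovers_planted_minor_fast_component(self, rng):
        n = 1000
        comp = rng.random(n) < 0.15
        p = np.where(comp, rng.normal(5.0, 0.5, n), rng.normal(2.5, 0.3, n))
        p = np.clip(p, 0.05, None)
        fit = fit_early_mixture(1.0 / p)
        assert fit.weight_early == pytest.approx(0.15, abs=0.05)
        assert fit.early.mu_p > fit.main.mu_p
        assert fit.early_is_minor
        assert fit.main.mu_p == pytest.approx(2.5, abs=0.1)

    def test_single_population_yields_no_spurious_component(self):
        t = simulate_later(RecinormalParams(3.0, 0.4), 500, seed=17)
        fit = fit_early_mixture(t)
        single = fit_recinormal(t)
        assert fit.single_component or fit.loglik - single.loglik < 2.0

    def test_loglik_never_decreases_across_em_iterations(self, rng):
        p = np.concatenate([rng.normal(2.5, 0.3, 850), rng.normal(5.0, 0.5, 150)])
        fit = fit_early_mixture(1.0 / np.clip(p, 0.05, None))
        assert np.all(np.diff(fit.loglik_path) >= -1e-7)

    def test_mixture_beats_or_matches_single_fit(self):
        t = simulate_later(RecinormalParams(3.0, 0.4), 300, seed=23)
        assert fit_early_mixture(t).loglik >= fit_recinormal(t).loglik - 1e-9

    def test_empty_and_tiny_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            fit_early_mixture([])
        with pytest.raises(InsufficientDataError):
            fit_early_mixture(np.full(10, 0.3))
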