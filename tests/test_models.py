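"""GLM fitting against likelihood oracles, AIC ranking, phase fits, smoother."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from plankmap.models import (fit_glm, fit_line_by_phase, rank_predictors,
                             spline_smooth)


def _binom_logl(beta, x, succ, m):
    eta = beta[0] + (beta[1] * x if len(beta) > 1 else 0.0)
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    return float(np.sum(gammaln(m + 1) - gammaln(succ + 1) - gammaln(m - succ + 1)
                        + succ * np.log(mu) + (m - succ) * np.log(1 - mu)))


class TestBinomial:
    def test_intercept_only_three_quarters(self):
        """3 successes of 4 trials: p = 0.75, logL = ln C(4,3)+3 ln .75+ln .25."""
        succ = np.array([1.0, 1.0, 1.0, 0.0])
        m = np.ones(4)
        fit = fit_glm(None, succ, "binomial", trials=m)
        p_hat = expit(fit.intercept)
        assert p_hat == pytest.approx(0.75, abs=1e-8)
        # same likelihood as the single (3, 4) observation up to the constant:
        # with unit trials every combinatorial term is ln 1 = 0, so add ln C(4,3)
        assert fit.log_likelihood + np.log(4) == pytest.approx(-0.8630, abs=1e-4)
        single_style = _binom_logl([fit.intercept], np.zeros(1),
                                   np.array([3.0]), np.array([4.0]))
        assert single_style == pytest.approx(-0.8630, abs=1e-4)
        aic_single = -2 * single_style + 2 * 1
        assert aic_single == pytest.approx(3.726, abs=1e-3)
        # grid-search oracle over p confirms the MLE
        grid = np.linspace(1e-4, 1 - 1e-4, 20001)
        ll = 3 * np.log(grid) + np.log1p(-grid)
        assert grid[np.argmax(ll)] == pytest.approx(0.75, abs=1e-3)

    def test_matches_nelder_mead_oracle(self):
        """IRLS equals direct likelihood maximization on 20 random instances."""
        rng = np.random.default_rng(0)
        for i in range(20):
            n = int(rng.integers(5, 15))
            x = rng.normal(0, 1, n)
            m = rng.integers(3, 30, n).astype(float)
            p = expit(0.4 + 1.1 * x)
            succ = rng.binomial(m.astype(int), p).astype(float)
            succ = np.clip(succ, 0.0, m)
            fit = fit_glm(x, succ, "binomial", trials=m)
            if not fit.converged:
                continue
            res = minimize(lambda b: -_binom_logl(b, x, succ, m),
                           fit.coefficients + 0.05,
                           method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12,
                                    "maxiter": 5000})
            assert np.allclose(fit.coefficients, res.x, atol=1e-4), i
            assert fit.log_likelihood == pytest.approx(-res.fun, abs=1e-6)

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 12)
        m = rng.integers(5, 20, 12).astype(float)
        succ = rng.binomial(m.astype(int), expit(0.3 - 0.8 * x)).astype(float)
        fit = fit_glm(x, succ, "binomial", trials=m)
        ref = sm.GLM(np.column_stack([succ, m - succ]),
                     sm.add_constant(x), family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(fit.coefficients, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.standard_errors, ref.bse, atol=1e-5)
        assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)

    def test_separation_flags_non_converged(self):
        x = np.array([-2.0, -1.0, 1.0, 2.0])
        succ = np.array([0.0, 0.0, 10.0, 10.0])
        m = np.full(4, 10.0)
        fit = fit_glm(x, succ, "binomial", trials=m)
        assert not fit.converged

    def test_fitted_probabilities_in_unit_interval(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 2, 20)
        m = np.full(20, 8.0)
        succ = rng.binomial(8, expit(0.5 * x)).astype(float)
        fit = fit_glm(x, succ, "binomial", trials=m)
        mu = expit(fit.intercept + fit.slope * x)
        assert np.all((mu > 0) & (mu < 1))


class TestGaussian:
    def test_exact_line_and_variance_floor(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = 2.5 * x - 1.0
        fit = fit_glm(x, y, "gaussian")
        assert fit.slope == pytest.approx(2.5, abs=1e-10)
        assert fit.intercept == pytest.approx(-1.0, abs=1e-10)
        assert np.isfinite(fit.aic)

    def test_constant_response_null_slope(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = np.full(5, 3.3)
        fit = fit_glm(x, y, "gaussian")
        assert fit.slope == pytest.approx(0.0, abs=1e-10)
        assert fit.p_value_slope > 0.9 or np.isnan(fit.p_value_slope)

    def test_equals_closed_form_ols(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 10, 15)
        y = rng.normal(1 + 0.5 * x, 2)
        fit = fit_glm(x, y, "gaussian")
        X = np.column_stack([np.ones(15), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit.coefficients, beta, atol=1e-10)
        # AIC convention: k counts both coefficients and the variance
        n = 15
        rss = float(np.sum((y - X @ beta) ** 2))
        logl = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        assert fit.aic == pytest.approx(-2 * logl + 2 * 3, abs=1e-8)

    def test_matches_nelder_mead_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(5, 20))
            x = rng.uniform(-2, 2, n)
            y = rng.normal(0.7 - 1.2 * x, 1.0)
            fit = fit_glm(x, y, "gaussian")

            def nll(b):
                r = y - b[0] - b[1] * x
                s2 = max(np.mean(r ** 2), 1e-12)
                return 0.5 * n * (np.log(2 * np.pi * s2) + 1)

            res = minimize(nll, fit.coefficients + 0.1, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12})
            assert np.allclose(fit.coefficients, res.x, atol=1e-4)


class TestRanking:
    @staticmethod
    def _fits():
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        rng = np.random.default_rng(0)
        y_strong = 2 * x + rng.normal(0, 0.1, 6)
        y_weak = rng.normal(0, 1, 6)
        return {"strong": fit_glm(x, y_strong, "gaussian"),
                "weak": fit_glm(x, y_weak, "gaussian")}

    def test_ascending_aic_ranks(self):
        fits = self._fits()
        out = rank_predictors(fits, response="demo").set_index("predictor")
        assert out.loc["strong", "aic_rank"] == 1
        assert out.loc["weak", "aic_rank"] == 2
        assert out.loc["strong", "significant"]

    def test_rank_invariant_to_loglik_shift(self):
        """Adding a constant to every log-likelihood leaves ranks unchanged."""
        fits = self._fits()
        shifted = {}
        for k, f in fits.items():
            g = fit_glm(None, np.array([1.0, 2.0, 3.0]), "gaussian")
            g.log_likelihood = f.log_likelihood + 10.0
            g.aic = f.aic - 20.0
            g.coefficients = f.coefficients
            g.standard_errors = f.standard_errors
            g.p_value_slope = f.p_value_slope
            shifted[k] = g
        a = rank_predictors(fits, "a").set_index("predictor")["aic_rank"]
        b = rank_predictors(shifted, "b").set_index("predictor")["aic_rank"]
        pd.testing.assert_series_equal(a, b)

    def test_non_converged_excluded_from_ranking(self):
        fits = self._fits()
        bad = fit_glm(np.array([-2.0, -1.0, 1.0, 2.0]),
                      np.array([0.0, 0.0, 5.0, 5.0]), "binomial",
                      trials=np.full(4, 5.0))
        fits["separated"] = bad
        out = rank_predictors(fits, "demo").set_index("predictor")
        assert np.isnan(out.loc["separated", "aic_rank"])
        assert sorted(out["aic_rank"].dropna()) == [1.0, 2.0]

    def test_too_few_converged_errors(self):
        fits = {"only": self._fits()["strong"]}
        with pytest.raises(ValueError, match="converged"):
            rank_predictors(fits, "demo")


class TestPhaseFits:
    def test_flat_series_ci_covers_zero(self):
        x = np.linspace(0, 1, 8)
        y = np.full(8, 0.4)
        y[::2] += 0.01  # tiny jitter so the variance is not degenerate
        out, skipped = fit_line_by_phase(x, y, np.array(["warm"] * 8))
        assert skipped == []
        assert out.loc[0, "slope_ci_low"] <= 0 <= out.loc[0, "slope_ci_high"]

    def test_small_phase_skipped(self):
        x = np.arange(5.0)
        y = x * 0.1
        phases = np.array(["warm", "warm", "warm", "cool", "cool"])
        out, skipped = fit_line_by_phase(x, y, phases)
        assert skipped == ["cool"]
        assert list(out["phase"]) == ["warm"]

    def test_shared_parameters_match_pooled_fit(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 40)
        y = 1.0 + 2.0 * x  # same exact line in both phases
        phases = np.array(["warm"] * 20 + ["cool"] * 20)
        out, _ = fit_line_by_phase(x, y, phases)
        pooled = fit_glm(x, y, "gaussian")
        for _, row in out.iterrows():
            assert row["slope"] == pytest.approx(pooled.slope, abs=1e-9)
            assert row["intercept"] == pytest.approx(pooled.intercept, abs=1e-9)


class TestSpline:
    def test_linear_data_gives_linear_curve(self):
        x = np.linspace(0, 10, 25)
        y = 3.0 * x + 1.0
        fit = spline_smooth(x, y, n_boot=20, seed=0)
        assert np.allclose(fit.fitted, 3.0 * fit.grid + 1.0, atol=1e-6)

    def test_band_contains_smooth_truth(self):
        rng = np.random.default_rng(6)
        x = np.sort(rng.uniform(0, 10, 80))
        truth = 1 / (1 + np.exp(-(x - 5)))
        y = truth + rng.normal(0, 0.05, 80)
        fit = spline_smooth(x, y, n_boot=200, seed=1)
        truth_on_grid = 1 / (1 + np.exp(-(fit.grid - 5)))
        coverage = np.mean((fit.lower <= truth_on_grid) & (truth_on_grid <= fit.upper))
        assert coverage >= 0.9

    def test_few_unique_x_falls_back_linear(self):
        x = np.array([0.0, 0.0, 1.0, 1.0, 2.0] * 2)
        y = 2 * x + 1
        with pytest.warns(UserWarning, match="linear"):
            fit = spline_smooth(x, y, n_boot=10, seed=0)
        assert fit.linear_fallback
        assert np.allclose(fit.fitted, 2 * fit.grid + 1, atol=1e-8)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(7)
        x = np.sort(rng.uniform(0, 5, 30))
        y = np.sin(x) + rng.normal(0, 0.1, 30)
        a = spline_smooth(x, y, n_boot=50, seed=3)
        b = spline_smooth(x, y, n_boot=50, seed=3)
        np.testing.assert_array_equal(a.lower, b.lower)
        np.testing.assert_array_equal(a.upper, b.upper)

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError, match="10 points"):
            spline_smooth(np.arange(5.0), np.arange(5.0))
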