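"""Survival analysis, contingency tests and the negative-binomial GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ubistrat.errors import DataValidationError
from ubistrat.clinical import (
    chi_square_independence,
    fit_negbin_glm,
    km_estimate,
    logrank_test,
)
from ubistrat.simulate import sample_negbin


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self, rng):
        times = rng.exponential(size=200)
        curve = km_estimate(times, np.ones(200, int))
        for t, s in zip(curve.event_times, curve.survival):
            assert s == pytest.approx(np.mean(times > t))

    def test_uncensored_quartiles(self):
        curve = km_estimate([1, 2, 3, 4], [1, 1, 1, 1])
        assert curve.at(2) == pytest.approx(0.5)

    def test_hand_example_with_censoring(self):
        curve = km_estimate([1, 2, 3], [1, 0, 1])
        assert curve.at(1) == pytest.approx(2 / 3)
        assert curve.at(3) == pytest.approx(0.0)

    def test_all_censored_flat(self):
        curve = km_estimate([1, 2, 3], [0, 0, 0])
        assert curve.at(5) == 1.0

    def test_empty_errors(self):
        with pytest.raises(DataValidationError):
            km_estimate([], [])

    def test_matches_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        t = rng.exponential(size=80)
        e = rng.integers(0, 2, size=80)
        if e.sum() == 0:
            e[0] = 1
        kmf = lifelines.KaplanMeierFitter().fit(t, e)
        curve = km_estimate(t, e)
        for tt in curve.event_times:
            assert curve.at(tt) == pytest.approx(
                float(kmf.survival_function_at_times(tt).iloc[0])
            )


class TestLogRank:
    def test_identical_groups_chi2_zero(self):
        res = logrank_test([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1],
                           ["A"] * 3 + ["B"] * 3)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_hand_computed_four_patients(self):
        # A dies at 1, 2; B dies at 3, 4: O_A = 2, E_A = 5/6, V = 17/36
        res = logrank_test([1, 2, 3, 4], [1, 1, 1, 1], ["A", "A", "B", "B"])
        assert res.chi2 == pytest.approx((2 - 5 / 6) ** 2 / (17 / 36))
        assert res.chi2 == pytest.approx(2.882, abs=1e-3)
        assert res.p == pytest.approx(0.0896, abs=1e-3)

    def test_observed_and_expected_balance(self, rng):
        t = rng.exponential(size=60)
        e = rng.integers(0, 2, size=60)
        e[:5] = 1
        g = rng.choice(["A", "B", "C"], size=60)
        res = logrank_test(t, e, g)
        assert sum(res.observed.values()) == pytest.approx(sum(res.expected.values()))
        assert res.df == 2

    def test_no_events_errors(self):
        with pytest.raises(DataValidationError, match="no events"):
            logrank_test([1, 2], [0, 0], ["A", "B"])

    def test_matches_lifelines_two_groups(self, rng):
        sl = pytest.importorskip("lifelines.statistics")
        t = rng.exponential(size=100)
        e = rng.integers(0, 2, size=100)
        e[:10] = 1
        g = rng.choice(["A", "B"], size=100)
        res = logrank_test(t, e, g)
        ref = sl.logrank_test(t[g == "A"], t[g == "B"], e[g == "A"], e[g == "B"])
        assert res.chi2 == pytest.approx(ref.test_statistic)
        assert res.p == pytest.approx(ref.p_value)

    def test_matches_lifelines_three_groups(self, rng):
        sl = pytest.importorskip("lifelines.statistics")
        t = rng.exponential(size=120)
        e = np.ones(120, int)
        g = rng.choice(["A", "B", "C"], size=120)
        res = logrank_test(t, e, g)
        ref = sl.multivariate_logrank_test(t, g, e)
        assert res.chi2 == pytest.approx(ref.test_statistic)

    def test_relabel_invariance(self, rng):
        t = rng.exponential(size=60)
        e = np.ones(60, int)
        g = rng.choice(["A", "B"], size=60)
        res1 = logrank_test(t, e, g)
        relabeled = np.where(g == "A", "X", "Y")
        res2 = logrank_test(t, e, relabeled)
        assert res1.chi2 == pytest.approx(res2.chi2)


class TestChiSquare:
    def test_uniform_table(self):
        res = chi_square_independence([[10, 10], [10, 10]])
        assert res.chi2 == 0.0 and res.p == pytest.approx(1.0)

    def test_hand_example(self):
        res = chi_square_independence([[20, 10], [10, 20]])
        assert res.chi2 == pytest.approx(20 / 3)
        assert res.df == 1
        assert res.p == pytest.approx(0.0098, abs=2e-4)

    def test_zero_marginal_errors(self):
        with pytest.raises(DataValidationError):
            chi_square_independence([[1, 0], [0, 0]])

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(20):
            table = rng.integers(1, 40, size=(3, 4))
            res = chi_square_independence(table)
            ref = stats.chi2_contingency(table, correction=False)
            assert res.chi2 == pytest.approx(ref.statistic, abs=1e-12)
            assert res.p == pytest.approx(ref.pvalue)
            assert np.allclose(res.expected, ref.expected_freq)

    def test_low_expected_flag(self):
        assert chi_square_independence([[2, 3], [3, 2]]).low_expected


class TestNegbinGLM:
    def test_intercept_only_log_mean(self):
        fit = fit_negbin_glm([1, 2, 3])
        assert fit.coefficients["intercept"] == pytest.approx(np.log(2.0), abs=1e-8)
        assert fit.theta_capped  # underdispersed → Poisson limit

    def test_all_zero_counts_error(self):
        with pytest.raises(DataValidationError):
            fit_negbin_glm([0, 0, 0, 0])

    def test_poisson_limit_matches_poisson_glm(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        g = rng.choice(["high", "mid", "low"], size=400)
        mu = np.exp(0.5 + 0.4 * (g == "mid") + 0.8 * (g == "low"))
        y = rng.poisson(mu)
        fit = fit_negbin_glm(y, g, baseline="high")
        X = np.column_stack([np.ones(400), g == "mid", g == "low"]).astype(float)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        ours = [fit.coefficients["intercept"], fit.coefficients["mid"],
                fit.coefficients["low"]]
        assert np.allclose(ours, ref.params, atol=1e-4)

    def test_matches_statsmodels_negbin(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        import statsmodels.discrete.discrete_model as smd

        g = rng.choice(["high", "low"], size=800)
        mu = np.exp(0.4 + 0.6 * (g == "low"))
        y = sample_negbin(rng, mu, 0.5)
        fit = fit_negbin_glm(y, g, baseline="high")
        X = np.column_stack([np.ones(800), g == "low"]).astype(float)
        ref = smd.NegativeBinomial(y, X).fit(disp=0)
        # statsmodels parameterizes alpha = 1/theta
        assert fit.coefficients["intercept"] == pytest.approx(ref.params[0], abs=5e-3)
        assert fit.coefficients["low"] == pytest.approx(ref.params[1], abs=5e-3)
        assert fit.theta == pytest.approx(1.0 / ref.params[2], rel=0.05)

    def test_loglik_nondecreasing(self, rng):
        g = rng.choice(["high", "mid", "low"], size=500)
        mu = np.exp(0.43 + 0.29 * (g == "mid") + 0.58 * (g == "low"))
        y = sample_negbin(rng, mu, 0.25)
        fit = fit_negbin_glm(y, g, baseline="high")
        assert fit.converged
        trace = np.array(fit.loglik_trace)
        assert np.all(np.diff(trace) >= -1e-6)

    def test_wald_outputs_consistent(self, rng):
        g = rng.choice(["high", "low"], size=300)
        y = sample_negbin(rng, np.exp(0.5 + 0.5 * (g == "low")), 0.4)
        fit = fit_negbin_glm(y, g, baseline="high")
        for k in fit.coefficients:
            z = fit.coefficients[k] / fit.std_errors[k]
            assert fit.z_values[k] == pytest.approx(z)
            assert fit.p_values[k] == pytest.approx(2 * stats.norm.sf(abs(z)))
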