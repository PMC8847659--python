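"""p27 comparisons, moderated-t differential expression, LFC concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ubistrat.errors import DataValidationError
from ubistrat.proxy import (
    benjamini_hochberg,
    estimate_prior,
    fit_gene_lfc,
    lfc_concordance,
    moderated_t,
    one_way_anova,
    pooled_t_test,
    spearman,
    welch_t_test,
)
from ubistrat.simulate import SimConfig, simulate_cohort, simulate_expression
from ubistrat.stratify import stratify_cohort


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res.F == 0.0 and res.p == 1.0

    def test_hand_decomposition(self):
        res = one_way_anova([1, 2, 3, 4, 5, 6], ["a", "a", "b", "b", "c", "c"])
        assert res.F == pytest.approx(16.0)
        assert (res.df_between, res.df_within) == (2, 3)
        assert res.p == pytest.approx(0.025, abs=2e-3)

    def test_single_observation_group_errors(self):
        with pytest.raises(DataValidationError):
            one_way_anova([1, 2, 3], ["a", "a", "b"])

    def test_matches_scipy(self, rng):
        x = rng.normal(size=30)
        g = rng.choice(["a", "b", "c"], size=30)
        res = one_way_anova(x, g)
        ref = stats.f_oneway(*(x[g == lv] for lv in "abc"))
        assert res.F == pytest.approx(ref.statistic)
        assert res.p == pytest.approx(ref.pvalue)

    def test_two_groups_f_equals_pooled_t_squared(self, rng):
        x, y = rng.normal(size=12), rng.normal(size=9)
        res = one_way_anova(np.r_[x, y], ["a"] * 12 + ["b"] * 9)
        t, _, _ = pooled_t_test(x, y)
        assert res.F == pytest.approx(t * t)


class TestTTests:
    def test_equal_samples(self):
        assert welch_t_test([1, 2, 3], [1, 2, 3]) == (0.0, 4.0, 1.0)

    def test_closed_form_shifted(self):
        t, df, p = welch_t_test([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-np.sqrt(1.5))
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.288, abs=2e-3)

    def test_degenerate_variance(self):
        with pytest.raises(DataValidationError, match="degenerate"):
            welch_t_test([0, 0], [1, 1])

    def test_matches_scipy(self, rng):
        x, y = rng.normal(size=10), rng.normal(1, 2, size=14)
        t, df, p = welch_t_test(x, y)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert (t, p) == (pytest.approx(ref.statistic), pytest.approx(ref.pvalue))
        tp, _, pp = pooled_t_test(x, y)
        refp = stats.ttest_ind(x, y)
        assert (tp, pp) == (pytest.approx(refp.statistic), pytest.approx(refp.pvalue))


class TestSpearman:
    def test_perfect_monotone(self):
        assert spearman([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
        assert spearman([1, 2, 3, 4], [5, 4, 3, 2])[0] == -1.0

    def test_hand_example(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_constant_vector_errors(self):
        with pytest.raises(DataValidationError, match="rank variance"):
            spearman([1, 1, 1], [1, 2, 3])

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 5, size=50).astype(float)
        y = x + rng.normal(size=50)
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(stats.spearmanr(x, y).statistic)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_monotone_transform(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=20), r.normal(size=20)
        rho, _ = spearman(x, y)
        rho2, _ = spearman(np.exp(x), y**3)
        assert rho == pytest.approx(rho2)


class TestBenjaminiHochberg:
    def test_step_up_example(self):
        assert np.allclose(benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert benjamini_hochberg([0.05])[0] == pytest.approx(0.05)

    def test_monotone_and_bounded(self, rng):
        p = rng.uniform(size=200)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15) and np.all(adj <= 1.0)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels(self, rng):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        p = rng.uniform(size=100)
        assert np.allclose(benjamini_hochberg(p), sm.multipletests(p, method="fdr_bh")[1])

    def test_out_of_range_rejected(self):
        with pytest.raises(DataValidationError):
            benjamini_hochberg([0.5, 1.5])


class TestFitGeneLfc:
    def test_constant_groups(self):
        expr = pd.DataFrame([[2, 2, 1, 1]], index=["g"], columns=list("abcd"))
        de = fit_gene_lfc(expr, ["A", "A", "B", "B"])
        assert de.loc["g", "lfc"] == 1.0
        assert de.loc["g", "s2"] == 0.0
        assert de.loc["g", "df"] == 2

    def test_hand_residuals(self):
        expr = pd.DataFrame([[3, 1, 2, 0]], index=["g"], columns=list("abcd"))
        de = fit_gene_lfc(expr, ["A", "A", "B", "B"])
        assert de.loc["g", "lfc"] == 1.0
        assert de.loc["g", "s2"] == 2.0

    def test_empty_group_errors(self):
        expr = pd.DataFrame([[1, 2, 3]], index=["g"], columns=list("abc"))
        with pytest.raises(DataValidationError):
            fit_gene_lfc(expr, ["A", "A", "A"])


class TestModeratedT:
    @staticmethod
    def _de(rng, n_genes=500, df=4):
        nA = nB = df // 2 + 1
        a = rng.normal(size=(n_genes, nA))
        b = rng.normal(size=(n_genes, nB))
        expr = pd.DataFrame(np.hstack([a, b]),
                            index=[f"g{i}" for i in range(n_genes)])
        return fit_gene_lfc(expr, ["A"] * nA + ["B"] * nB)

    def test_d0_zero_recovers_ordinary_t(self, rng):
        de = self._de(rng)
        res = moderated_t(de, d0=0.0)
        ordinary = de["lfc"] / np.sqrt(de["s2"] * de.attrs["contrast_var"])
        assert np.allclose(res.table["t_mod"], ordinary)

    def test_d0_infinite_complete_shrinkage(self, rng):
        de = self._de(rng)
        res = moderated_t(de, d0=np.inf, s0_sq=2.0)
        expected = de["lfc"] / np.sqrt(2.0 * de.attrs["contrast_var"])
        assert np.allclose(res.table["t_mod"], expected)

    def test_posterior_variance_plugin(self):
        de = pd.DataFrame({"lfc": [1.0] * 12, "s2": [2.0] * 12, "df": [2] * 12})
        res = moderated_t(de, contrast_var=1.0, d0=2.0, s0_sq=1.0)
        assert res.table["s2_post"].iloc[0] == pytest.approx(1.5)
        assert res.table["t_mod"].iloc[0] == pytest.approx(1 / np.sqrt(1.5))

    def test_null_pvalues_uniform(self):
        # heterogeneous true variances so the prior fit is non-trivial
        rng = np.random.default_rng(1)
        n = 5000
        sd = np.sqrt(stats.invgamma.rvs(3, scale=2, size=n, random_state=rng))
        a = sd[:, None] * rng.normal(size=(n, 4))
        b = sd[:, None] * rng.normal(size=(n, 4))
        expr = pd.DataFrame(np.hstack([a, b]), index=[f"g{i}" for i in range(n)])
        de = fit_gene_lfc(expr, ["A"] * 4 + ["B"] * 4)
        res = moderated_t(de)
        assert 0 < res.d0 < np.inf
        assert stats.kstest(res.table["p"], "uniform").pvalue > 0.01

    def test_prior_estimate_recovers_known_hyperparameters(self, rng):
        # s2 ~ s0^2 * F(df, d0) marginally; MOM should land near the truth
        d0_true, s0_true, df = 8.0, 1.5, 4
        chi_num = stats.chi2.rvs(df, size=20000, random_state=rng) / df
        chi_den = stats.chi2.rvs(d0_true, size=20000, random_state=rng) / d0_true
        s2 = s0_true * chi_num / chi_den
        d0, s0 = estimate_prior(s2, np.full(20000, df))
        assert d0 == pytest.approx(d0_true, rel=0.2)
        assert s0 == pytest.approx(s0_true, rel=0.1)

    def test_identical_variances_full_shrinkage_branch(self):
        de = pd.DataFrame({"lfc": np.ones(20), "s2": np.full(20, 2.0), "df": [4] * 20})
        res = moderated_t(de, contrast_var=0.5)
        assert np.isinf(res.d0)


class TestLfcConcordance:
    def test_identical_contrasts_rho_one(self, small_stratified, small_expression):
        # force contrast B labels equal to contrast A by aligning cn_skp2
        cohort = small_stratified[small_stratified["ubiq_group"].isin(["high", "low"])].copy()
        cohort["cn_skp2"] = np.where(cohort["ubiq_group"] == "low", 1, 0)
        res = lfc_concordance(small_expression, cohort)
        assert res.rho == pytest.approx(1.0)

    def test_null_simulation_small_rho(self):
        cfg = SimConfig(n_patients=400, n_genes=5000, frac_responsive=0.0, seed=21)
        cohort = simulate_cohort(cfg)
        strat, _ = stratify_cohort(cohort)
        expr = simulate_expression(cfg, cohort)
        # decouple the CN contrast from the latent factor entirely
        rng = np.random.default_rng(0)
        strat["cn_skp2"] = rng.choice([0, 1], size=len(strat))
        res = lfc_concordance(expr, strat)
        assert abs(res.rho) < 0.05

    def test_rho_increases_with_planted_signal(self):
        rhos = []
        for sd in (0.05, 0.25, 0.6):
            vals = []
            for seed in (31, 32, 33):
                cfg = SimConfig(n_patients=500, n_genes=1500, frac_responsive=0.2,
                                expr_effect_sd=sd, seed=seed)
                cohort = simulate_cohort(cfg)
                strat, _ = stratify_cohort(cohort)
                vals.append(lfc_concordance(simulate_expression(cfg, cohort), strat).rho)
            rhos.append(np.mean(vals))
        assert rhos[0] < rhos[1] < rhos[2]
        assert rhos[2] > 0.3

    def test_small_arm_errors(self, small_expression, small_stratified):
        cohort = small_stratified.head(3).copy()
        with pytest.raises(DataValidationError):
            lfc_concordance(small_expression, cohort)
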