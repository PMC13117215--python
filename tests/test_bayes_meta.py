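import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import beta as beta_dist

from immunometa import bayes_meta as bm

FAST = bm.McmcSettings(n_iter=4000, n_burnin=1000, n_chains=4, seed=2)


def _simulate_meta(rng, k, mu, tau, n_i):
    theta = rng.normal(mu, tau, k)
    p = 1 / (1 + np.exp(-theta))
    x = rng.binomial(n_i, p).astype(float)
    return bm.MetaInput(tuple(f"s{i}" for i in range(k)), x,
                        np.full(k, float(n_i)))


class TestFitRandomEffects:
    def test_single_study_pooled_proportion(self):
        """tau = 0, flat logit prior: posterior of inv-logit(mu) tracks x/n."""
        mi = bm.MetaInput(("s",), np.array([25.0]), np.array([31.0]))
        res = bm.fit_random_effects(mi, mcmc=FAST, tau_fixed=0.0)
        assert res.summaries["pooled_p"]["median"] == \
            pytest.approx(25 / 31, abs=0.01)
        assert res.converged

    def test_single_study_needs_tau_fixed(self):
        mi = bm.MetaInput(("s",), np.array([5.0]), np.array([10.0]))
        with pytest.raises(ValueError, match="tau_fixed"):
            bm.fit_random_effects(mi, mcmc=FAST)

    def test_symmetric_logits_pool_to_zero(self):
        mi = bm.MetaInput(("a", "b"), np.array([30.0, 70.0]),
                          np.array([100.0, 100.0]))
        res = bm.fit_random_effects(mi, mcmc=FAST)
        assert abs(res.summaries["mu"]["median"]) < 0.05

    def test_zero_cells_need_no_correction(self):
        mi = bm.MetaInput(("a", "b", "c"), np.array([0.0, 2.0, 5.0]),
                          np.array([20.0, 25.0, 30.0]))
        res = bm.fit_random_effects(mi, mcmc=FAST)
        assert np.isfinite(res.summaries["mu"]["median"])

    def test_reproducible_summaries(self):
        mi = bm.MetaInput(("a", "b", "c"), np.array([10.0, 14.0, 9.0]),
                          np.array([40.0, 40.0, 40.0]))
        r1 = bm.fit_random_effects(mi, mcmc=FAST)
        r2 = bm.fit_random_effects(mi, mcmc=FAST)
        assert r1.summaries == r2.summaries

    def test_parameter_recovery_coverage(self):
        """95% CrI covers the generating mu in nearly all replicates."""
        rng = np.random.default_rng(31)
        mcmc = bm.McmcSettings(n_iter=2000, n_burnin=600, n_chains=2, seed=5)
        hits = 0
        reps = 20
        for _ in range(reps):
            mi = _simulate_meta(rng, k=20, mu=1.5, tau=0.3, n_i=200)
            res = bm.fit_random_effects(mi, mcmc=mcmc)
            s = res.summaries["mu"]
            hits += s["lower"] <= 1.5 <= s["upper"]
        assert hits >= 18

    def test_pooled_or_vs_reference(self):
        mi = bm.MetaInput(("a", "b"), np.array([30.0, 35.0]),
                          np.array([100.0, 100.0]), p0=0.15)
        res = bm.fit_random_effects(mi, mcmc=FAST)
        implied = res.summaries["pooled_or"]["median"]
        by_hand = math.exp(res.summaries["mu"]["median"]
                           - math.log(0.15 / 0.85))
        assert implied == pytest.approx(by_hand, rel=0.02)


class TestNormalSamplerOracle:
    def test_conjugate_posterior_within_mc_error(self):
        """Normal-likelihood reduction with fixed tau: mu posterior matches
        the closed-form conjugate answer within 3 Monte-Carlo SEs."""
        y = np.array([0.2, 0.5, 0.1, 0.4, 0.3])
        se = np.array([0.10, 0.20, 0.15, 0.12, 0.18])
        tau = 0.2
        prior = bm.PriorSpec()
        tot = se**2 + tau**2
        w = 1 / tot
        prec = w.sum() + 1 / prior.mu_scale**2
        mean_cf = np.sum(w * y) / prec
        sd_cf = 1 / math.sqrt(prec)
        res = bm.fit_normal_random_effects(
            y, se, prior, bm.McmcSettings(n_iter=12_000, n_burnin=2000,
                                          seed=3), tau_fixed=tau)
        ess = res.diagnostics["ess_mu"]
        mcse = sd_cf / math.sqrt(ess)
        assert abs(res.summaries["mu"]["mean"] - mean_cf) < 3 * mcse
        assert res.summaries["mu"]["sd"] == pytest.approx(sd_cf, rel=0.1)

    def test_fixed_effect_closed_form_path(self):
        y = np.array([0.2, 0.5, 0.1])
        se = np.array([0.1, 0.2, 0.15])
        mean_cf, sd_cf = bm.normal_fixed_effect_posterior(y, se)
        res = bm.fit_normal_random_effects(y, se, mcmc=FAST, tau_fixed=0.0)
        assert res.summaries["mu"]["mean"] == pytest.approx(mean_cf, abs=0.01)
        assert res.summaries["mu"]["sd"] == pytest.approx(sd_cf, rel=0.05)


class TestBayesianI2:
    def test_zero_tau_gives_zero(self):
        mi = bm.MetaInput(("a", "b"), np.array([10.0, 12.0]),
                          np.array([50.0, 50.0]))
        res = bm.fit_random_effects(mi, mcmc=FAST, tau_fixed=0.0)
        out = bm.bayesian_i2(res, mi)
        assert out["median"] == 0.0

    def test_tau_equal_s_gives_half(self):
        mi = bm.MetaInput(("a", "b", "c"), np.array([10.0, 12.0, 15.0]),
                          np.array([50.0, 50.0, 50.0]))
        res = bm.fit_random_effects(mi, mcmc=FAST)
        s2 = bm.bayesian_i2(res, mi)["s2"]
        res.tau = np.full_like(res.tau, math.sqrt(s2))
        assert bm.bayesian_i2(res, mi)["median"] == pytest.approx(0.5)

    def test_large_heterogeneity_detected(self):
        rng = np.random.default_rng(7)
        mi = _simulate_meta(rng, k=6, mu=0.0, tau=1.5, n_i=300)
        res = bm.fit_random_effects(mi, mcmc=FAST)
        assert bm.bayesian_i2(res, mi)["median"] > 0.5

    def test_monotone_in_sample_size_at_fixed_tau(self):
        """Scaling all counts by 4 shrinks s^2, so I^2 rises at fixed tau."""
        mi1 = bm.MetaInput(("a", "b", "c"), np.array([10.0, 14.0, 9.0]),
                           np.array([40.0, 40.0, 40.0]))
        mi4 = bm.MetaInput(("a", "b", "c"), 4 * mi1.events, 4 * mi1.totals)
        res = bm.fit_random_effects(mi1, mcmc=FAST)
        for tau in (0.1, 0.3, 0.6):
            res.tau = np.full_like(res.tau, tau)
            assert bm.bayesian_i2(res, mi4)["median"] > \
                bm.bayesian_i2(res, mi1)["median"]


class TestSubgroupAnalysis:
    def test_identical_groups_difference_near_zero(self):
        x = np.array([20.0, 25.0, 22.0] * 2)
        n = np.full(6, 80.0)
        cov = pd.DataFrame({"g": ["A"] * 3 + ["B"] * 3})
        mi = bm.MetaInput(tuple(f"s{i}" for i in range(6)), x, n,
                          covariates=cov)
        out = bm.subgroup_analysis(mi, "g", mcmc=FAST)
        assert abs(out["differences"]["A-B"]["median"]) < 0.05

    def test_group_or_recovery(self):
        """Groups generated at ORs 5.91 and 2.35 vs p0: recovered group ORs
        within 20% and the difference interval excludes zero."""
        rng = np.random.default_rng(41)
        p0 = 0.15
        rows_x, rows_n, labels = [], [], []
        for label, or_true in (("combo", 5.91), ("mono", 2.35)):
            logit = math.log(or_true * p0 / (1 - p0))
            for _ in range(10):
                theta = rng.normal(logit, 0.1)
                rows_x.append(float(rng.binomial(
                    300, 1 / (1 + math.exp(-theta)))))
                rows_n.append(300.0)
                labels.append(label)
        mi = bm.MetaInput(tuple(f"s{i}" for i in range(20)),
                          np.array(rows_x), np.array(rows_n),
                          covariates=pd.DataFrame({"regimen": labels}),
                          p0=p0)
        out = bm.subgroup_analysis(mi, "regimen", mcmc=FAST)
        for label, or_true in (("combo", 5.91), ("mono", 2.35)):
            got = out["groups"][label].summaries["pooled_or"]["median"]
            assert abs(got - or_true) / or_true < 0.20
        diff = out["differences"]["combo-mono"]
        assert diff["lower"] > 0

    def test_single_level_grouping_errors(self):
        mi = bm.MetaInput(("a", "b"), np.array([5.0, 6.0]),
                          np.array([20.0, 20.0]),
                          covariates=pd.DataFrame({"g": ["A", "A"]}))
        with pytest.raises(ValueError, match="two levels"):
            bm.subgroup_analysis(mi, "g", mcmc=FAST)


class TestMetaRegression:
    def test_coefficient_recovery(self):
        """theta_i = 0.5 + 1.2 x_i with tiny tau: slope recovered."""
        rng = np.random.default_rng(3)
        k = 20
        xcov = rng.normal(0, 1, k)
        theta = 0.5 + 1.2 * xcov + rng.normal(0, 0.01, k)
        n_i = 2000
        x = rng.binomial(n_i, 1 / (1 + np.exp(-theta))).astype(float)
        mi = bm.MetaInput(tuple(f"s{i}" for i in range(k)), x,
                          np.full(k, float(n_i)),
                          covariates=pd.DataFrame({"z": xcov}))
        out = bm.meta_regression(mi, ["z"], mcmc=FAST)
        assert out["coefficients"]["z"]["median"] == \
            pytest.approx(1.2, abs=0.15)

    def test_null_covariate_interval_covers_zero(self):
        """A covariate independent of the simulated effects: its 95%
        interval covers zero in at least 90% of 20 replicates."""
        rng = np.random.default_rng(9)
        covered = 0
        mcmc = bm.McmcSettings(n_iter=3000, n_burnin=900, n_chains=2, seed=4)
        reps = 20
        for _ in range(reps):
            k = 20
            xcov = rng.normal(0, 1, k)
            theta = rng.normal(0.3, 0.2, k)
            x = rng.binomial(500, 1 / (1 + np.exp(-theta))).astype(float)
            mi = bm.MetaInput(tuple(f"s{i}" for i in range(k)), x,
                              np.full(k, 500.0),
                              covariates=pd.DataFrame({"z": xcov}))
            out = bm.meta_regression(mi, ["z"], mcmc=mcmc)
            c = out["coefficients"]["z"]
            covered += c["lower"] <= 0 <= c["upper"]
        assert covered >= 18

    def test_covariate_shift_leaves_slope_unchanged(self):
        rng = np.random.default_rng(5)
        k = 15
        xcov = rng.normal(0, 1, k)
        theta = 0.2 + 0.8 * xcov
        x = rng.binomial(500, 1 / (1 + np.exp(-theta))).astype(float)
        def fit(z):
            mi = bm.MetaInput(tuple(f"s{i}" for i in range(k)), x,
                              np.full(k, 500.0),
                              covariates=pd.DataFrame({"z": z}))
            return bm.meta_regression(mi, ["z"], mcmc=FAST)
        a = fit(xcov)["coefficients"]["z"]
        b = fit(xcov + 10.0)["coefficients"]["z"]
        assert a["median"] == pytest.approx(b["median"], abs=0.1)

    def test_collinear_design_errors(self):
        mi = bm.MetaInput(tuple("abcdef"), np.full(6, 10.0),
                          np.full(6, 40.0),
                          covariates=pd.DataFrame({
                              "u": [1.0, 2, 3, 4, 5, 6],
                              "v": [2.0, 4, 6, 8, 10, 12]}))
        with pytest.raises(ValueError, match="collinear"):
            bm.meta_regression(mi, ["u", "v"], mcmc=FAST)


class TestSensitivitySuite:
    def test_cardinality_and_stability(self):
        rng = np.random.default_rng(13)
        mi = _simulate_meta(rng, k=6, mu=0.4, tau=0.05, n_i=400)
        mcmc = bm.McmcSettings(n_iter=2500, n_burnin=800, n_chains=2, seed=6)
        out = bm.sensitivity_suite(mi, mcmc=mcmc)
        assert len(out["leave_one_out"]) == 6
        assert out["verdict"] == "stable"

    def test_prior_swap_data_dominance(self):
        rng = np.random.default_rng(17)
        mi = _simulate_meta(rng, k=20, mu=0.8, tau=0.1, n_i=300)
        wide = bm.fit_random_effects(mi, bm.PriorSpec(mu_scale=100.0),
                                     mcmc=FAST)
        narrow = bm.fit_random_effects(mi, bm.PriorSpec(mu_scale=10.0),
                                       mcmc=FAST)
        assert abs(wide.summaries["mu"]["median"]
                   - narrow.summaries["mu"]["median"]) < 0.05

    def test_needs_three_studies(self):
        mi = bm.MetaInput(("a", "b"), np.array([5.0, 8.0]),
                          np.array([20.0, 20.0]))
        with pytest.raises(ValueError):
            bm.sensitivity_suite(mi, mcmc=FAST)


class TestTrimAndFill:
    def test_symmetric_funnel_imputes_nothing(self):
        y = np.array([-0.4, -0.2, 0.0, 0.2, 0.4])
        out = bm.trim_and_fill(y, np.full(5, 0.1))
        assert out["k0"] == 0
        assert out["adjusted"] == out["unadjusted"]

    def test_identical_effects_short_circuit(self):
        out = bm.trim_and_fill(np.full(6, 0.3), np.full(6, 0.1))
        assert out["k0"] == 0

    def test_adjusted_moves_toward_null_when_filling_low_side(self):
        rng = np.random.default_rng(19)
        se = 0.05 + 0.35 * rng.random(20)
        y = 0.5 + se * rng.normal(size=20)
        keep = np.argsort(y)[3:]
        out = bm.trim_and_fill(y[keep], se[keep], side="right")
        if out["k0"] > 0:
            assert out["adjusted"] <= out["unadjusted"]
            assert len(out["filled_effects"]) == out["k0"]
            assert np.all(out["filled_effects"] < out["unadjusted"])

    def test_too_few_studies(self):
        with pytest.raises(ValueError):
            bm.trim_and_fill(np.array([0.1, 0.2]), np.array([0.1, 0.1]))


class TestFunnelAsymmetry:
    def test_small_study_drift_detected(self):
        rng = np.random.default_rng(23)
        se = np.linspace(0.05, 0.4, 24)
        y = 0.2 + 1.5 * se + se * rng.normal(size=24) * 0.3
        out = bm.funnel_asymmetry(y, se, n_perm=500, seed=1)
        assert out["slope"] > 0
        assert out["p_value"] < 0.05

    def test_symmetric_data_not_flagged(self):
        rng = np.random.default_rng(29)
        se = np.linspace(0.05, 0.4, 24)
        y = 0.2 + se * rng.normal(size=24)
        out = bm.funnel_asymmetry(y, se, n_perm=500, seed=1)
        assert out["p_value"] > 0.05
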