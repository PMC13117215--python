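import math

import numpy as np
import pandas as pd
import pytest

from immunometa import score_strat as st


class TestComputeScore:
    def _patient(self, **kw):
        base = {"kmt2d_mut": 0, "nlr_change": "stable", "pdl1_cps_pos": 0,
                "eotaxin_high": 0, "regimen": "mono", "nlr_baseline_ge4": 0,
                "vegf_high": 0}
        base.update(kw)
        return base

    def test_all_benefit_factors_give_five(self):
        p = self._patient(kmt2d_mut=1, nlr_change="decrease",
                          pdl1_cps_pos=1, eotaxin_high=1)
        assert st.compute_score(p) == 5

    def test_all_risk_factors_give_minus_four(self):
        p = self._patient(nlr_baseline_ge4=1, regimen="irinotecan",
                          vegf_high=1)
        assert st.compute_score(p) == -4

    def test_no_factors_give_zero(self):
        assert st.compute_score(self._patient()) == 0

    def test_missing_factor_errors(self):
        p = self._patient()
        p["kmt2d_mut"] = None
        with pytest.raises(ValueError, match="imputation"):
            st.compute_score(p)

    def test_thyroid_extension_extends_minimum(self):
        w = st.ScoreWeights(include_thyroid=True)
        p = self._patient(nlr_baseline_ge4=1, regimen="irinotecan",
                          vegf_high=1, thyroid_dysfunction_baseline=1)
        assert st.compute_score(p, w) == -5

    def test_enumeration_spans_full_range(self):
        """All 2^7 factor combinations reach exactly the integers -4..5."""
        scores = st.enumerate_scores()
        assert scores.min() == -4
        assert scores.max() == 5
        assert list(scores) == list(range(-4, 6))


class TestAssignStrata:
    @pytest.mark.parametrize("score,benefit,risk", [
        (5, "high", "low"), (3, "high", "low"), (2, "medium", "low"),
        (1, "medium", "low"), (0, "low", "medium"), (-1, "low", "medium"),
        (-2, "low", "high"), (-4, "low", "high"),
    ])
    def test_published_cutoffs(self, score, benefit, risk):
        out = st.assign_strata(score)
        assert (out.benefit, out.risk) == (benefit, risk)

    def test_total_and_monotone(self):
        order_b = {"low": 0, "medium": 1, "high": 2}
        order_r = {"high": 0, "medium": 1, "low": 2}
        labels = [st.assign_strata(s) for s in range(-4, 6)]
        bs = [order_b[a.benefit] for a in labels]
        rs = [order_r[a.risk] for a in labels]
        assert all(x <= y for x, y in zip(bs, bs[1:]))
        assert all(x <= y for x, y in zip(rs, rs[1:]))


class TestKaplanMeier:
    def test_no_censoring_reduces_to_empirical(self):
        t = [1.0, 2.0, 3.0, 4.0, 5.0]
        km = st.km_estimate(t, [1] * 5)
        emp = {1.0: 0.8, 2.0: 0.6, 3.0: 0.4, 4.0: 0.2, 5.0: 0.0}
        got = dict(zip(km["time"], km["survival"]))
        for tt, s in emp.items():
            assert got[tt] == pytest.approx(s)

    def test_all_censored_curve_stays_at_one(self):
        km = st.km_estimate([1.0, 2.0, 3.0], [0, 0, 0])
        assert np.all(km["survival"] == 1.0)
        assert not km["median_defined"]

    def test_textbook_fixture_hand_computed(self):
        """times 1,2,3+,4,5+,6 -> S = 5/6, 2/3, 2/3, 4/9, 4/9, 0."""
        km = st.km_estimate([1, 2, 3, 4, 5, 6], [1, 1, 0, 1, 0, 1])
        got = dict(zip(km["time"], km["survival"]))
        assert got[1.0] == pytest.approx(5 / 6)
        assert got[2.0] == pytest.approx(2 / 3)
        assert got[4.0] == pytest.approx(4 / 9)
        assert got[6.0] == pytest.approx(0.0)

    def test_curve_shape_properties(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(5, 200)
        e = (rng.random(200) < 0.7).astype(int)
        km = st.km_estimate(t, e)
        s = km["survival"]
        assert s[0] == 1.0  # S(0) = 1
        assert np.all(np.diff(s) <= 1e-12)  # non-increasing
        assert np.all(km["ci_lower"] <= s + 1e-12)
        assert np.all(km["ci_upper"] >= s - 1e-12)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            st.km_estimate([], [])


class TestLogRank:
    def test_group_against_itself(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(4, 80)
        e = np.ones(80, dtype=int)
        out = st.log_rank((t, e), (t, e))
        assert out["statistic"] == pytest.approx(0.0, abs=1e-9)
        assert out["p_value"] == pytest.approx(1.0, abs=1e-9)

    def test_no_events_returns_null(self):
        out = st.log_rank(([1.0, 2.0], [0, 0]), ([1.5, 2.5], [0, 0]))
        assert out == {"statistic": 0.0, "p_value": 1.0}

    def test_power_under_rate_ratio_three(self):
        rng = np.random.default_rng(4)
        hits = 0
        for _ in range(20):
            a = rng.exponential(1.0, 200)
            b = rng.exponential(1 / 3, 200)
            out = st.log_rank((a, np.ones(200)), (b, np.ones(200)))
            hits += out["p_value"] < 0.001
        assert hits >= 19


class TestCoxHr:
    def test_null_simulation_centers_at_one(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(2.0, 500)
        g = (rng.random(500) < 0.5).astype(int)
        out = st.cox_hr(g, t, np.ones(500, dtype=int))
        assert 0.8 <= out["hr"] <= 1.25

    def test_rate_ratio_recovery_cross_checked(self):
        """Exponential groups at rate ratio 3: Cox HR matches the
        closed-form exponential MLE rate ratio."""
        rng = np.random.default_rng(6)
        n = 1000
        a = rng.exponential(1.0, n)
        b = rng.exponential(1 / 3, n)
        t = np.concatenate([a, b])
        g = np.concatenate([np.zeros(n), np.ones(n)]).astype(int)
        out = st.cox_hr(g, t, np.ones(2 * n, dtype=int))
        mle = (n / b.sum()) / (n / a.sum())
        assert 2.7 <= out["hr"] <= 3.3
        assert out["hr"] == pytest.approx(mle, rel=0.05)

    def test_deterministic(self):
        t = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        g = np.array([0, 1, 0, 1, 0, 1])
        e = np.ones(6, dtype=int)
        assert st.cox_hr(g, t, e) == st.cox_hr(g, t, e)

    def test_monotone_likelihood_flagged(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        g = np.array([0, 0, 1, 1])
        e = np.array([1, 1, 0, 0])
        out = st.cox_hr(g, t, e)
        assert out["monotone_likelihood"]


class TestDecisionCurve:
    def test_treat_none_is_zero_everywhere(self):
        rng = np.random.default_rng(7)
        y = (rng.random(300) < 0.3).astype(int)
        p = rng.random(300)
        dca = st.decision_curve(p, y)
        assert np.all(dca.nb_none == 0.0)

    def test_treat_all_vanishes_at_prevalence(self):
        y = np.array([1] * 30 + [0] * 70)
        dca = st.decision_curve(np.full(100, 0.5), y, thresholds=[0.3])
        assert dca.nb_all.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_perfect_predictor_net_benefit_is_prevalence(self):
        rng = np.random.default_rng(8)
        y = (rng.random(400) < 0.35).astype(int)
        dca = st.decision_curve(y.astype(float), y,
                                thresholds=np.arange(0.05, 0.95, 0.05))
        assert np.allclose(dca.nb_model, y.mean())

    def test_model_bounded_by_prevalence(self):
        rng = np.random.default_rng(9)
        y = (rng.random(500) < 0.25).astype(int)
        p = np.clip(0.25 + 0.3 * (y - 0.25) + rng.normal(0, 0.1, 500), 0, 1)
        dca = st.decision_curve(p, y)
        assert np.all(dca.nb_model <= y.mean() + 1e-12)

    def test_threshold_one_excluded_with_warning(self):
        y = np.array([0, 1, 1, 0])
        with pytest.warns(UserWarning):
            dca = st.decision_curve(np.array([0.2, 0.8, 0.9, 0.1]), y,
                                    thresholds=[0.5, 1.0])
        assert list(dca.threshold) == [0.5]

    def test_score_calibration_monotone(self, default_cohort):
        scores = st.score_cohort(default_cohort)
        resp = default_cohort.table.response.isin(
            ["CR", "PR"]).astype(int).to_numpy()
        probs = st.score_to_probability(scores.to_numpy(), resp)
        assert np.all((probs >= 0) & (probs <= 1))
        order = np.argsort(scores.to_numpy())
        assert np.all(np.diff(probs[order]) >= -1e-12)


class TestCohortStratification:
    def test_benefit_orr_and_risk_irae_are_ordered(self, default_cohort):
        """On the default cohort the benefit strata order mean ORR and the
        risk strata order grade >=3 irAE rates."""
        scores = st.score_cohort(default_cohort)
        sf = st.strata_frame(scores)
        df = default_cohort.table
        resp = df.response.isin(["CR", "PR"]).astype(float)
        orr = [float(resp[sf.benefit == b].mean())
               for b in ("low", "medium", "high")]
        irae = [float(df.irae_ge3.astype(float)[sf.risk == r].mean())
                for r in ("low", "medium", "high")]
        assert orr[0] < orr[1] < orr[2]
        assert irae[0] < irae[1] < irae[2]
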