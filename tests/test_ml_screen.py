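import math

import numpy as np
import pandas as pd
import pytest

from immunometa import ml_screen as ms


@pytest.fixture(scope="module")
def logistic_fixture():
    rng = np.random.default_rng(1)
    n, p = 400, 6
    X = rng.normal(size=(n, p))
    beta = np.array([1.2, -0.8, 0.0, 0.5, 0.0, 0.0])
    y = (rng.random(n) < 1 / (1 + np.exp(-(0.2 + X @ beta)))).astype(float)
    return X, y


class TestSplitTrainValidation:
    def test_published_split_sizes(self, default_cohort):
        tr, va = ms.split_train_validation(default_cohort, ratio=0.7,
                                           seed=1, train_size=273)
        assert (len(tr.table), len(va.table)) == (273, 100)
        ids = set(tr.table.patient_id) | set(va.table.patient_id)
        assert len(ids) == 373  # disjoint partition

    def test_stratification_preserves_outcome_rate(self, default_cohort):
        tr, va = ms.split_train_validation(default_cohort, ratio=0.7, seed=2)
        full = default_cohort.table.response.isin(["CR", "PR"]).mean()
        tr_rate = tr.table.response.isin(["CR", "PR"]).mean()
        assert abs(tr_rate - full) < 0.02

    def test_determinism(self, default_cohort):
        a1, _ = ms.split_train_validation(default_cohort, seed=5)
        a2, _ = ms.split_train_validation(default_cohort, seed=5)
        assert list(a1.table.patient_id) == list(a2.table.patient_id)

    def test_boundary_ratio_rejected(self, default_cohort):
        with pytest.raises(ValueError):
            ms.split_train_validation(default_cohort, ratio=1.0)


class TestLassoLogisticFit:
    def test_huge_lambda_reduces_to_intercept(self, logistic_fixture):
        X, y = logistic_fixture
        fit = ms.lasso_logistic_fit(X, y, lam=1e6)
        assert np.all(fit.coef == 0)
        assert fit.intercept == pytest.approx(
            math.log(y.mean() / (1 - y.mean())), abs=1e-6)

    def test_unpenalized_matches_newton_mle_oracle(self, logistic_fixture):
        X, y = logistic_fixture
        import statsmodels.api as sm
        fit = ms.lasso_logistic_fit(X, y, lam=0.0, standardize=False,
                                    max_iter=20_000, tol=1e-10)
        oracle = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        got = np.concatenate([[fit.intercept], fit.coef])
        assert np.max(np.abs(got - oracle.params)) < 1e-4

    def test_objective_non_increasing(self, logistic_fixture):
        X, y = logistic_fixture
        for lam in (0.0, 0.01, 0.1):
            fit = ms.lasso_logistic_fit(X, y, lam=lam)
            diffs = np.diff(fit.objective_path)
            assert np.all(diffs <= 1e-10)

    def test_solution_path_monotone_sparsity(self, logistic_fixture):
        X, y = logistic_fixture
        grid = np.geomspace(1e-4, 1.0, 10)
        nonzeros = [int(np.sum(ms.lasso_logistic_fit(X, y, lam).coef != 0))
                    for lam in grid]
        assert all(a >= b for a, b in zip(nonzeros, nonzeros[1:]))

    def test_non_finite_input_errors(self):
        with pytest.raises(ValueError):
            ms.lasso_logistic_fit(np.array([[1.0, np.nan]]),
                                  np.array([1.0]))


class TestCvSelectLambda:
    def test_pure_noise_prefers_largest_lambda(self):
        rng = np.random.default_rng(3)
        wins = 0
        grid = (0.001, 0.01, 0.1)
        for rep in range(15):
            X = rng.normal(size=(120, 8))
            y = (rng.random(120) < 0.4).astype(float)
            out = ms.cv_select_lambda(X, y, folds=5, lambda_grid=grid,
                                      seed=rep, max_iter=300)
            wins += out["lambda"] == 0.1
        assert wins > 7

    def test_strong_signal_kept(self):
        rng = np.random.default_rng(4)
        kept = 0
        for rep in range(10):
            X = rng.normal(size=(1000, 5))
            y = (rng.random(1000)
                 < 1 / (1 + np.exp(-2.0 * X[:, 0]))).astype(float)
            out = ms.cv_select_lambda(X, y, folds=5,
                                      lambda_grid=(0.001, 0.01, 0.05),
                                      seed=rep, max_iter=300)
            fit = ms.lasso_logistic_fit(X, y, out["lambda"])
            kept += fit.coef[0] != 0
        assert kept >= 9

    def test_deterministic_given_seed(self, logistic_fixture):
        X, y = logistic_fixture
        a = ms.cv_select_lambda(X, y, seed=7)
        b = ms.cv_select_lambda(X, y, seed=7)
        assert a == b

    def test_negative_grid_errors(self, logistic_fixture):
        X, y = logistic_fixture
        with pytest.raises(ValueError):
            ms.cv_select_lambda(X, y, lambda_grid=(-0.1, 0.1))


class TestRocAuc:
    def test_perfect_and_degenerate_scores(self):
        y = np.array([0, 0, 1, 1, 1])
        assert ms.roc_auc([0.1, 0.2, 0.7, 0.8, 0.9], y)["auc"] == 1.0
        assert ms.roc_auc([0.5] * 5, y)["auc"] == 0.5

    def test_matches_exhaustive_pair_count(self):
        rng = np.random.default_rng(5)
        s = rng.normal(size=12)
        s[3] = s[7]  # force a tie
        y = np.array([1, 0, 1, 0, 0, 1, 0, 1, 0, 1, 0, 0])
        pairs = [1.0 if si > sj else 0.5 if si == sj else 0.0
                 for si, yi in zip(s, y) if yi == 1
                 for sj, yj in zip(s, y) if yj == 0]
        assert ms.roc_auc(s, y)["auc"] == pytest.approx(np.mean(pairs))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(6)
        s = rng.normal(size=50)
        y = (rng.random(50) < 0.5).astype(int)
        y[0], y[1] = 1, 0
        a = ms.roc_auc(s, y)["auc"]
        assert ms.roc_auc(np.exp(3 * s), y)["auc"] == pytest.approx(a)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            ms.roc_auc([0.1, 0.2], [1, 1])

    def test_bootstrap_ci_brackets_auc(self, logistic_fixture):
        X, y = logistic_fixture
        fit = ms.lasso_logistic_fit(X, y, 0.01)
        out = ms.roc_auc(fit.predict_proba(X), y, n_boot=200, seed=1)
        assert out["ci"][0] < out["auc"] < out["ci"][1]


class TestVariableImportance:
    def test_vis_sums_to_one(self, logistic_fixture):
        X, y = logistic_fixture
        for method in ("standardized_coef", "permutation"):
            vis = ms.variable_importance(pd.DataFrame(X), y, method=method,
                                         n_perm=5)
            assert vis.vis.sum() == pytest.approx(1.0, abs=1e-9)

    def test_single_informative_feature_ranks_first(self):
        rng = np.random.default_rng(8)
        firsts = 0
        for rep in range(10):
            X = rng.normal(size=(1500, 11))
            y = (rng.random(1500)
                 < 1 / (1 + np.exp(-2.0 * X[:, 0]))).astype(float)
            names = ["signal"] + [f"noise{i}" for i in range(10)]
            vis = ms.variable_importance(pd.DataFrame(X, columns=names), y)
            firsts += vis.iloc[0]["feature"] == "signal"
        assert firsts >= 9

    def test_retained_flag_against_threshold(self):
        """Coefficients shaped like the screening outcome (four importances
        above 10%, the rest well below) retain exactly four features."""
        rng = np.random.default_rng(9)
        n, p = 5000, 8
        X = pd.DataFrame(rng.normal(size=(n, p)),
                         columns=[f"f{i}" for i in range(p)])
        coef = np.array([2.76, 2.23, 1.95, 1.58, 0.37, 0.37, 0.37, 0.37])
        fit = ms.LassoFit(coef=coef, intercept=0.0, converged=True,
                          n_iter=1, objective_path=[],
                          scale=np.ones(p), center=np.zeros(p))
        vis = ms.variable_importance(X, np.zeros(n), model=fit,
                                     threshold=0.10)
        assert int(vis.retained.sum()) == 4
        assert list(vis.feature[:4]) == ["f0", "f1", "f2", "f3"]

    def test_degenerate_model_warns_uniform(self):
        X = pd.DataFrame({"a": np.zeros(50), "b": np.zeros(50)})
        y = (np.arange(50) % 2).astype(float)
        with pytest.warns(UserWarning, match="degenerate"):
            vis = ms.variable_importance(X, y, lam=10.0)
        assert vis.vis.tolist() == pytest.approx([0.5, 0.5])


class TestBootstrapAucStability:
    def test_duplicated_feature_contributes_nothing(self):
        rng = np.random.default_rng(10)
        x0 = rng.normal(size=600)
        y = (rng.random(600) < 1 / (1 + np.exp(-2 * x0))).astype(float)
        X = pd.DataFrame({"a": x0, "a_copy": x0,
                          "noise": rng.normal(size=600)})
        out = ms.bootstrap_auc_stability(X, y, ["a", "a_copy"], B=30, seed=1)
        assert out.mean_contribution.abs().max() < 0.01

    def test_sd_shrinks_with_sample_size(self):
        rng = np.random.default_rng(11)
        def sd_at(n):
            x0 = rng.normal(size=n)
            y = (rng.random(n) < 1 / (1 + np.exp(-1.5 * x0))).astype(float)
            X = pd.DataFrame({"a": x0, "b": rng.normal(size=n)})
            out = ms.bootstrap_auc_stability(X, y, ["a", "b"], B=40, seed=2)
            return float(out.sd_contribution.iloc[0])
        assert sd_at(2000) < sd_at(200)

    def test_seed_reproducibility(self, logistic_fixture):
        X, y = logistic_fixture
        Xd = pd.DataFrame(X, columns=[f"f{i}" for i in range(X.shape[1])])
        a = ms.bootstrap_auc_stability(Xd, y, ["f0", "f1"], B=20, seed=3)
        b = ms.bootstrap_auc_stability(Xd, y, ["f0", "f1"], B=20, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_minimum_b(self, logistic_fixture):
        X, y = logistic_fixture
        with pytest.raises(ValueError):
            ms.bootstrap_auc_stability(pd.DataFrame(X), y, ["0"], B=1)


class TestEncodeFeatures:
    def test_encoding_shapes_and_outcomes(self, default_cohort):
        fm = ms.encode_features(default_cohort, "response_or")
        assert len(fm.X) == 373
        assert "kmt2d_mut" in fm.feature_names
        assert "nlr_change_decrease" in fm.feature_names
        assert set(np.unique(fm.y)) <= {0, 1}
        fm2 = ms.encode_features(default_cohort, "irae_ge3")
        assert fm2.y.mean() == default_cohort.table.irae_ge3.astype(
            float).mean()

    def test_missing_features_rejected(self, default_cohort):
        from immunometa import synthetic_cohort as sc
        masked = sc.inject_missingness(default_cohort,
                                       {"kmt2d_mut": 0.1}, seed=1)
        with pytest.raises(ValueError, match="impute"):
            ms.encode_features(masked, "response_or")
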