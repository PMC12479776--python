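import numpy as np
import pandas as pd
import pytest
import xgboost as xgb
from scipy import stats
from sklearn.linear_model import LinearRegression

from effortmet.metab_predict import (
    FeatureTable,
    HyperparameterSpace,
    curvature_comparison,
    evaluate,
    permutation_test,
    permutation_threshold,
    plasma_brain_correlation,
    run_pipeline,
    shapley_attribution,
    split_train_test,
    stage1_filter,
    stage2_select,
    tune_and_fit,
)


def make_table(n=60, p=10, signal=None, noise=1.0, seed=0, target="y"):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, p))
    y = rng.normal(0, noise, n)
    if signal is not None:
        for j, w in signal.items():
            y = y + w * X[:, j]
    cols = [f"f{j}" for j in range(p)]
    frame = pd.DataFrame(X, columns=cols)
    frame[target] = y
    return FeatureTable(frame=frame, feature_cols=cols, target_col=target)


class TestSplit:
    @pytest.mark.parametrize("n,ratio,n_train,n_test", [(69, 0.80, 55, 14), (71, 0.75, 53, 18)])
    def test_study_split_arithmetic(self, n, ratio, n_train, n_test):
        spec = split_train_test(make_table(n=n), ratio=ratio, seed=0)
        assert len(spec.train_ids) == n_train and len(spec.test_ids) == n_test
        assert set(spec.train_ids).isdisjoint(spec.test_ids)
        assert len(set(spec.train_ids) | set(spec.test_ids)) == n

    def test_deterministic_membership(self):
        t = make_table(n=40)
        a = split_train_test(t, 0.8, seed=5)
        b = split_train_test(t, 0.8, seed=5)
        assert a.train_ids == b.train_ids and a.test_ids == b.test_ids

    def test_bad_ratio_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(make_table(), ratio=1.2, seed=0)


class TestStage1:
    def test_filter_is_exact_absolute_threshold(self):
        t = make_table(n=55, p=18, seed=3)
        kept = stage1_filter(t)
        y = t.frame["y"].to_numpy()
        expected = [
            c for c in t.feature_cols if abs(np.corrcoef(t.frame[c], y)[0, 1]) >= 0.1
        ]
        assert kept == expected

    def test_target_copy_kept_constant_removed(self):
        t = make_table(n=30, p=3, seed=1)
        t.frame["f0"] = t.frame["y"]
        t.frame["f1"] = 2.5
        with pytest.warns(RuntimeWarning):
            kept = stage1_filter(t)
        assert "f0" in kept and "f1" not in kept

    def test_null_kept_count_matches_analytic_rate(self):
        # P(|r| >= 0.1) under the null via the t-transform of sample r
        n, p, reps = 55, 18, 150
        t_crit = 0.1 * np.sqrt((n - 2) / (1 - 0.01))
        p_keep = 2 * stats.t.sf(t_crit, df=n - 2)
        counts = [len(stage1_filter(make_table(n=n, p=p, seed=s))) for s in range(reps)]
        expected = p * p_keep
        se = np.sqrt(p * p_keep * (1 - p_keep) / reps)
        assert abs(np.mean(counts) - expected) < 4 * se


class TestStage2:
    def test_subset_contract_and_trace(self):
        t = make_table(n=40, p=6, signal={0: 1.0}, seed=2)
        s1 = stage1_filter(t)
        res = stage2_select(t, s1, seed=0, n_estimators=15)
        assert set(res.stage2_kept) <= set(res.stage1_kept) <= set(t.feature_cols)
        assert res.selection_trace["cvloo_rmse"].notna().all()

    def test_single_stage1_feature_trivially_selected(self):
        t = make_table(n=30, p=3)
        res = stage2_select(t, ["f1"], seed=0)
        assert res.stage2_kept == ["f1"]

    def test_informative_feature_survives_selection(self):
        hits = 0
        for s in range(12):
            t = make_table(n=45, p=10, signal={0: 1.0}, noise=0.2, seed=s)
            res = stage2_select(t, t.feature_cols, seed=s, n_estimators=15)
            hits += "f0" in res.stage2_kept
        assert hits >= 11  # >= 90% of seeds

    def test_empty_stage1_rejected(self):
        with pytest.raises(ValueError):
            stage2_select(make_table(), [], seed=0)


class TestTuning:
    def test_constant_target_gives_zero_validation_rmse(self):
        t = make_table(n=20, p=3, seed=0)
        t.frame["y"] = 4.2
        model, params, val = tune_and_fit(t, ["f0"], HyperparameterSpace(n_evals=3), seed=0)
        assert val == pytest.approx(0.0, abs=1e-6)
        assert np.allclose(model.predict(t.frame[["f0"]].to_numpy()), 4.2, atol=1e-5)

    def test_noiseless_monotone_target_fits_tightly(self):
        t = make_table(n=40, p=4, seed=1)
        t.frame["y"] = 2.0 * t.frame["f0"]
        _, _, val = tune_and_fit(t, ["f0"], HyperparameterSpace(n_evals=8), seed=0)
        assert val < 0.5 * t.frame["y"].std()

    def test_chosen_hyperparameters_within_bounds(self):
        t = make_table(n=25, p=4, signal={0: 0.8}, seed=2)
        space = HyperparameterSpace(n_evals=6)
        _, params, _ = tune_and_fit(t, ["f0", "f1"], space, seed=0)
        for name in ("eta", "max_depth", "min_child_weight", "gamma", "reg_lambda", "reg_alpha"):
            lo, hi = getattr(space, name)
            assert lo <= params[name] <= hi

    def test_deterministic_under_seed(self):
        t = make_table(n=25, p=4, signal={0: 0.8}, seed=3)
        out1 = tune_and_fit(t, ["f0", "f1"], HyperparameterSpace(n_evals=5), seed=9)
        out2 = tune_and_fit(t, ["f0", "f1"], HyperparameterSpace(n_evals=5), seed=9)
        assert out1[1] == out2[1] and out1[2] == out2[2]

    def test_empty_budget_rejected(self):
        with pytest.raises(ValueError):
            HyperparameterSpace(n_evals=0)


class _Oracle:
    """Stub regressor returning a fixed prediction vector."""

    def __init__(self, pred):
        self.pred = np.asarray(pred, float)

    def predict(self, X):
        return self.pred[: len(X)]


class TestEvaluate:
    def test_perfect_predictions(self):
        t = make_table(n=14, p=2, seed=0)
        rep = evaluate(_Oracle(t.frame["y"].to_numpy()), t, ["f0"])
        assert rep.test_rmse == 0.0 and rep.test_pearson_r == pytest.approx(1.0)

    def test_one_tailed_p_matches_t_transform(self):
        t = make_table(n=14, p=2, seed=4)
        rng = np.random.default_rng(0)
        pred = 0.5 * t.frame["y"].to_numpy() + rng.normal(0, 1, 14)
        rep = evaluate(_Oracle(pred), t, ["f0"])
        r = rep.test_pearson_r
        tt = r * np.sqrt((14 - 2) / (1 - r**2))
        assert rep.test_p == pytest.approx(stats.t.sf(tt, df=12), rel=1e-6)
        assert rep.variance_explained == pytest.approx(r**2)

    def test_shuffled_truth_uncorrelated(self):
        rs = []
        for s in range(30):
            t = make_table(n=20, p=2, seed=s)
            pred = np.random.default_rng(s).permutation(t.frame["y"].to_numpy())
            rs.append(evaluate(_Oracle(pred), t, ["f0"]).test_pearson_r)
        assert abs(np.mean(rs)) < 0.1

    def test_small_test_set_rejected(self):
        t = make_table(n=12, p=2)
        with pytest.raises(ValueError):
            evaluate(_Oracle(np.zeros(2)), t.rows(t.frame.index[:2]), ["f0"])


class TestPermutation:
    def test_threshold_is_250th_order_statistic_at_5000(self):
        rng = np.random.default_rng(0)
        vals = rng.permutation(np.arange(5000, dtype=float))
        assert permutation_threshold(vals) == 249.0  # k = 0.05*5000 = 250th smallest

    def test_exact_copy_feature_is_significant(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0, 1, 40)
        X = y.reshape(-1, 1)
        res = permutation_test(
            lambda: LinearRegression(), X[:30], y[:30], X[30:], y[30:], n_perm=100, seed=0
        )
        assert res.observed_rmse < 1e-10 and res.significant

    def test_type_one_rate_and_p_uniformity_under_null(self):
        reps, n_perm = 100, 100
        sig, pvals = 0, []
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            X = rng.normal(0, 1, (40, 2))
            y = rng.normal(0, 1, 40)
            res = permutation_test(
                lambda: LinearRegression(), X[:30], y[:30], X[30:], y[30:],
                n_perm=n_perm, seed=s,
            )
            sig += res.significant
            pvals.append(
                (1 + np.sum(res.permuted_rmse <= res.observed_rmse)) / (n_perm + 1)
            )
        # nominal 5% level within 3 binomial SE
        assert sig / reps <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_minimum_permutations_enforced(self):
        with pytest.raises(ValueError):
            permutation_test(lambda: LinearRegression(), np.zeros((5, 1)),
                             np.zeros(5), np.zeros((2, 1)), np.zeros(2), n_perm=50)


class TestShapley:
    @staticmethod
    def unit_scale_model(n=60, p=5, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.normal(0, 1, (n, p))
        y = 0.3 * X[:, 0] - 0.2 * X[:, 1] + rng.normal(0, 0.2, n)
        cols = [f"f{j}" for j in range(p)]
        m = xgb.XGBRegressor(n_estimators=60, max_depth=3, n_jobs=1, random_state=seed)
        m.fit(X, y)
        m.feature_names_used_ = cols
        return m, pd.DataFrame(X, columns=cols)

    def test_local_accuracy_within_tolerance(self):
        m, rows = self.unit_scale_model()
        rep = shapley_attribution(m, rows)
        pred = m.predict(rows.to_numpy())
        resid = rep.values.sum(axis=1).to_numpy() + rep.base_value - pred
        assert np.max(np.abs(resid)) < 1e-6

    def test_ranking_invariant_to_column_order(self):
        m, rows = self.unit_scale_model(seed=1)
        rep1 = shapley_attribution(m, rows)
        rep2 = shapley_attribution(m, rows[list(reversed(rows.columns))])
        pd.testing.assert_series_equal(rep1.ranking, rep2.ranking)

    def test_single_stump_matches_bruteforce_lattice(self):
        """Depth-1 single tree: the subset-lattice Shapley value is
        f(x) - cover-weighted mean leaf."""
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (80, 1))
        y = (X[:, 0] > 0).astype(float)
        m = xgb.XGBRegressor(
            n_estimators=1, max_depth=1, learning_rate=1.0, base_score=0.5,
            n_jobs=1, random_state=0, reg_lambda=0.0,
        )
        m.fit(X, y)
        m.feature_names_used_ = ["x"]
        rows = pd.DataFrame(X[:5], columns=["x"])
        rep = shapley_attribution(m, rows)

        tree = m.get_booster().trees_to_dataframe()
        leaves = tree[tree["Feature"] == "Leaf"]
        f_empty = float(np.average(leaves["Gain"], weights=leaves["Cover"]))
        pred = m.predict(rows.to_numpy()) - 0.5  # margin above base_score
        brute = pred - f_empty  # phi = f({x}) - f({})
        assert np.allclose(rep.values["x"].to_numpy(), brute, atol=1e-5)
        assert rep.base_value == pytest.approx(f_empty + 0.5, abs=1e-5)

    def test_duplicated_feature_attributions_sum_to_single_case(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0, 1, 80)
        y = 0.8 * x + rng.normal(0, 0.1, 80)
        kw = dict(n_estimators=20, max_depth=2, n_jobs=1, random_state=0)
        m1 = xgb.XGBRegressor(**kw)
        m1.fit(x.reshape(-1, 1), y)
        m1.feature_names_used_ = ["a"]
        m2 = xgb.XGBRegressor(**kw)
        m2.fit(np.column_stack([x, x]), y)
        m2.feature_names_used_ = ["a", "b"]
        r1 = shapley_attribution(m1, pd.DataFrame({"a": x[:10]}))
        r2 = shapley_attribution(m2, pd.DataFrame({"a": x[:10], "b": x[:10]}))
        total1 = r1.values["a"].to_numpy() + r1.base_value
        total2 = r2.values.sum(axis=1).to_numpy() + r2.base_value
        assert np.allclose(total1, total2, atol=1e-4)

    def test_non_tree_model_rejected(self):
        with pytest.raises(TypeError):
            shapley_attribution(LinearRegression(), pd.DataFrame({"a": [1.0]}))


class TestCurvature:
    def test_inverted_u_wins_both_criteria(self):
        wins = 0
        for s in range(20):
            rng = np.random.default_rng(s)
            x = rng.normal(0, 1, 69)
            q = -((x - x.mean()) ** 2)
            y = q + rng.normal(0, 2.6 * q.std(), 69)  # tuned to |r| ~ 0.36
            cc = curvature_comparison(x, y)
            wins += cc.winner_aic == "quadratic" and cc.winner_bic == "quadratic"
        assert wins >= 18

    def test_linear_relation_prefers_linear(self):
        wins = 0
        for s in range(10):
            rng = np.random.default_rng(100 + s)
            x = rng.normal(0, 1, 69)
            y = 0.8 * x + rng.normal(0, 1, 69)
            cc = curvature_comparison(x, y)
            wins += cc.winner_aic == "linear"
        assert wins >= 8

    def test_pure_noise_gives_weak_preference(self):
        deltas = []
        for s in range(20):
            rng = np.random.default_rng(200 + s)
            cc = curvature_comparison(rng.normal(0, 1, 69), rng.normal(0, 1, 69))
            deltas.append(abs(cc.linear["bic"] - cc.quadratic["bic"]))
            assert abs(cc.linear["r"]) < 0.4 and abs(cc.quadratic["r"]) < 0.4
        assert np.median(deltas) < 6

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            curvature_comparison(np.ones(20), np.arange(20.0))
        with pytest.raises(ValueError):
            curvature_comparison(np.arange(5.0), np.arange(5.0))


class TestPlasmaBrain:
    def test_identical_columns_give_unit_r(self):
        idx = pd.Index([f"S{i}" for i in range(20)])
        vals = np.linspace(1, 2, 20)
        plasma = pd.DataFrame({"Gln": vals}, index=idx)
        brain = pd.DataFrame({"Gln": vals}, index=idx)
        out = plasma_brain_correlation(plasma, brain, ["Gln"])
        assert out.loc[0, "r"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rs = []
        for s in range(20):
            rng = np.random.default_rng(s)
            idx = pd.Index(range(50))
            plasma = pd.DataFrame({"Lac": rng.normal(0, 1, 50)}, index=idx)
            brain = pd.DataFrame({"Lac": rng.normal(0, 1, 50)}, index=idx)
            rs.append(plasma_brain_correlation(plasma, brain, ["Lac"]).loc[0, "r"])
        assert abs(np.mean(rs)) < 0.1

    def test_pairwise_nan_dropping_and_minimum(self):
        idx = pd.Index(range(10))
        plasma = pd.DataFrame({"Glu": [1, 2, 3, np.nan, 5, 6, 7, 8, 9, 10]}, index=idx, dtype=float)
        brain = pd.DataFrame({"Glu": np.arange(10, dtype=float)}, index=idx)
        out = plasma_brain_correlation(plasma, brain, ["Glu"])
        assert out.loc[0, "n"] == 9
        with pytest.raises(ValueError):
            plasma_brain_correlation(plasma.iloc[:3], brain.iloc[:2], ["Glu"])


class TestPipelineHygiene:
    def test_selection_and_tuning_blind_to_test_rows(self):
        space = HyperparameterSpace(n_evals=4, n_estimators=30)
        t1 = make_table(n=40, p=8, signal={0: 0.8}, seed=7)
        rep1 = run_pipeline(t1, ratio=0.8, n_perm=100, seed=3, space=space, stage2_estimators=10)

        t2 = make_table(n=40, p=8, signal={0: 0.8}, seed=7)
        test_ids = list(rep1.split.test_ids)
        t2.frame.loc[test_ids, "y"] = t2.frame.loc[test_ids, "y"] + 100.0
        rep2 = run_pipeline(t2, ratio=0.8, n_perm=100, seed=3, space=space, stage2_estimators=10)

        assert rep1.selection.stage1_kept == rep2.selection.stage1_kept
        assert rep1.selection.stage2_kept == rep2.selection.stage2_kept
        assert rep1.prediction.hyperparameters == rep2.prediction.hyperparameters
        assert rep1.prediction.validation_rmse == rep2.prediction.validation_rmse
        # but evaluation does see the corrupted test labels
        assert rep2.prediction.test_rmse > rep1.prediction.test_rmse
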