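import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.base import clone

from vploop.stats import (
    BaggedROSELogistic,
    ROSESampler,
    SeparationError,
    compare_groups,
    fit_logistic_stepwise,
    hosmer_lemeshow,
    km_logrank,
    nagelkerke_r2,
    roc_analysis,
    rose_balance,
    rose_bandwidth,
    screen_variables,
    stratified_partition,
)


class TestCompareGroups:
    def test_large_shift_welch_t(self):
        r = np.random.default_rng(3)
        res = compare_groups(
            {"a": r.normal(0, 1, 200), "b": r.normal(1, 1, 200)},
            "continuous", "x")
        assert res.test == "welch_t"
        assert res.p_value < 1e-10
        assert res.passes_screen

    def test_skewed_data_falls_back_to_mann_whitney(self):
        r = np.random.default_rng(4)
        res = compare_groups(
            {"a": r.exponential(1, 100), "b": r.exponential(2, 100)},
            "continuous", "x")
        assert res.test == "mann_whitney"

    def test_identical_small_categorical_fisher_p_one(self):
        res = compare_groups(
            {"a": [0, 0, 1, 1], "b": [0, 0, 1, 1]}, "categorical", "x")
        assert res.test == "fisher"
        assert res.p_value == pytest.approx(1.0)

    def test_rule_of_five_selects_fisher(self):
        a = [1] * 1 + [0] * 9
        b = [1] * 2 + [0] * 8
        res = compare_groups({"a": a, "b": b}, "categorical", "x")
        assert res.test == "fisher"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_groups({"a": [], "b": [1.0, 2.0, 3.0]}, "continuous")

    def test_small_continuous_group_rejected(self):
        with pytest.raises(ValueError, match="n >= 3"):
            compare_groups({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]},
                           "continuous")

    def test_screen_flag_tracks_threshold(self):
        r = np.random.default_rng(5)
        res = compare_groups(
            {"a": r.normal(0, 1, 50), "b": r.normal(0, 1, 50)},
            "continuous", "null_var")
        assert res.passes_screen == (res.p_value < 0.2)


class TestStratifiedPartition:
    def _frame(self, n=100, pos=0.8, seed=0):
        r = np.random.default_rng(seed)
        return pd.DataFrame({
            "x": r.normal(size=n),
            "y": (r.random(n) < pos).astype(int),
        })

    def test_proportional_allocation(self):
        df = pd.DataFrame({"y": [1] * 80 + [0] * 20, "x": range(100)})
        train, test = stratified_partition(df, "y", 0.7, seed=1)
        assert len(train) + len(test) == 100
        assert abs(train["y"].sum() - 56) <= 1

    def test_disjoint_and_exhaustive(self):
        df = self._frame()
        train, test = stratified_partition(df, "y", 0.7, seed=2)
        assert set(train.index).isdisjoint(test.index)
        assert set(train.index) | set(test.index) == set(df.index)

    def test_seed_reproducibility(self):
        df = self._frame()
        a = stratified_partition(df, "y", 0.7, seed=3)
        b = stratified_partition(df, "y", 0.7, seed=3)
        assert a[0].index.tolist() == b[0].index.tolist()

    def test_tiny_class_rejected(self):
        df = pd.DataFrame({"y": [1] * 9 + [0], "x": range(10)})
        with pytest.raises(ValueError, match="member"):
            stratified_partition(df, "y", 0.7, seed=0)

    def test_degenerate_fraction_rejected(self):
        df = pd.DataFrame({"y": [1] * 5 + [0] * 5, "x": range(10)})
        with pytest.raises(ValueError):
            stratified_partition(df, "y", 0.999, seed=0)


class TestRoseBalance:
    def _imbalanced(self, n=500, seed=0):
        r = np.random.default_rng(seed)
        y = (r.random(n) < 0.2).astype(int)
        X = pd.DataFrame({
            "a": r.normal(0, 1, n) + y,
            "b": r.normal(5, 2, n),
        })
        return X, y

    def test_balances_classes(self):
        X, y = self._imbalanced()
        props = []
        for seed in range(20):
            _, yb = rose_balance(X, y, n_out=1000, seed=seed)
            props.append(yb.mean())
        assert abs(np.mean(props) - 0.5) < 0.02

    def test_zero_shrink_reproduces_input_rows(self):
        X, y = self._imbalanced(n=100)
        Xb, yb = rose_balance(X, y, shrink=0.0, seed=1)
        pool = {tuple(row) for row in X.to_numpy()}
        assert all(tuple(row) in pool for row in Xb.to_numpy())

    def test_single_class_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="both classes"):
            rose_balance(X, np.array([1, 1, 1]))

    def test_bandwidth_formula(self):
        sd = np.array([2.0, 0.5])
        h = rose_bandwidth(n_k=100, q=2, sd=sd)
        const = (4.0 / (4 * 100)) ** (1.0 / 6)
        assert np.allclose(h, const * sd)

    def test_sampler_wrapper_matches_function(self):
        X, y = self._imbalanced(n=200)
        Xa, ya = ROSESampler(random_state=5).fit_resample(X, y)
        Xb, yb = rose_balance(X, y, seed=5)
        assert np.array_equal(Xa.to_numpy(), Xb.to_numpy())
        assert np.array_equal(ya, yb)


class TestLogisticStepwise:
    def _simulate(self, n, beta, seed, null_extra=False):
        r = np.random.default_rng(seed)
        x = r.normal(0.15, 0.10, n)
        eta = -2.0 + beta * x
        y = (r.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
        df = pd.DataFrame({"slope_index": x, "y": y})
        if null_extra:
            df["noise"] = r.normal(size=n)
        return df

    def test_strong_predictor_retained_with_bracketing_ci(self):
        df = self._simulate(5000, 8.0, seed=10)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = fit_logistic_stepwise(df, "y", ["slope_index"])
        assert rep.retained == ["slope_index"]
        orr, lo, hi = rep.odds_ratios["slope_index"]
        assert lo < orr < hi
        assert 0 <= rep.nagelkerke_r2 <= 1

    def test_null_predictor_usually_eliminated(self):
        kept = 0
        for seed in range(20):
            df = self._simulate(1500, 8.0, seed=200 + seed, null_extra=True)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = fit_logistic_stepwise(df, "y", ["slope_index", "noise"])
            kept += "noise" in rep.retained
        # a null predictor survives the p<0.05 retention rule ~5% of the time
        assert kept <= 4

    def test_perfect_separation_raises(self):
        df = pd.DataFrame({
            "x": np.concatenate([np.zeros(20), np.ones(20)]),
            "y": np.concatenate([np.zeros(20), np.ones(20)]).astype(int),
        })
        with pytest.raises(SeparationError):
            fit_logistic_stepwise(df, "y", ["x"])

    def test_single_predictor_cutoff_on_index_scale(self):
        df = self._simulate(3000, 8.0, seed=12)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = fit_logistic_stepwise(df, "y", ["slope_index"])
        assert rep.cutoff_scale == "predictor"
        assert -1 < rep.cutoff < 1  # on the slope-index scale

    def test_aic_criterion_runs(self):
        df = self._simulate(1000, 8.0, seed=13, null_extra=True)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = fit_logistic_stepwise(df, "y", ["slope_index", "noise"],
                                        criterion="aic")
        assert "slope_index" in rep.retained


class TestCalibrationMetrics:
    def test_nagelkerke_zero_for_intercept_only(self):
        assert nagelkerke_r2(-100.0, -100.0, 200) == 0.0

    def test_nagelkerke_bounded(self):
        assert 0 <= nagelkerke_r2(-50.0, -120.0, 200) <= 1

    def test_hosmer_lemeshow_accepts_correct_model(self):
        r = np.random.default_rng(20)
        p = r.uniform(0.05, 0.95, 2000)
        y = (r.random(2000) < p).astype(float)
        stat, pval = hosmer_lemeshow(y, p)
        assert pval > 0.01


class TestBaggedEnsemble:
    def _data(self, n=400, seed=0):
        r = np.random.default_rng(seed)
        x = r.normal(size=n)
        y = (r.random(n) < 1 / (1 + np.exp(-(-1.2 + 1.5 * x)))).astype(int)
        return pd.DataFrame({"x": x}), y

    def test_single_member_no_bootstrap_equals_plain_fit(self):
        import statsmodels.api as sm

        X, y = self._data()
        est = BaggedROSELogistic(n_models=1, balance=False, bootstrap=False,
                                 random_state=0).fit(X, y)
        ref = sm.Logit(y.astype(float),
                       sm.add_constant(X)).fit(disp=0)
        assert np.allclose(est.predict_proba(X)[:, 1],
                           np.asarray(ref.predict()), atol=1e-8)

    def test_probabilities_bounded(self):
        X, y = self._data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = BaggedROSELogistic(n_models=10, random_state=1).fit(X, y)
        p = est.predict_proba(X)
        assert np.all((p >= 0) & (p <= 1))
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_vote_aggregation_available(self):
        X, y = self._data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = BaggedROSELogistic(n_models=5, aggregate="vote",
                                     random_state=2).fit(X, y)
        assert set(np.unique(est.predict(X))) <= {0, 1}

    def test_sklearn_clone_compatible(self):
        est = BaggedROSELogistic(n_models=7, random_state=3)
        cloned = clone(est)
        assert cloned.get_params()["n_models"] == 7

    def test_ensemble_reduces_prediction_variance(self):
        x_eval = pd.DataFrame({"x": np.linspace(-2, 2, 9)})
        single, bagged = [], []
        for seed in range(20):
            X, y = self._data(n=150, seed=100 + seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s = BaggedROSELogistic(n_models=1, balance=False,
                                       bootstrap=False,
                                       random_state=seed).fit(X, y)
                b = BaggedROSELogistic(n_models=15,
                                       random_state=seed).fit(X, y)
            single.append(s.predict_proba(x_eval)[:, 1])
            bagged.append(b.predict_proba(x_eval)[:, 1])
        var_single = np.var(single, axis=0).mean()
        var_bagged = np.var(bagged, axis=0).mean()
        assert var_bagged < var_single

    def test_determinism_under_seed(self):
        X, y = self._data()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = BaggedROSELogistic(n_models=5, random_state=9).fit(X, y)
            b = BaggedROSELogistic(n_models=5, random_state=9).fit(X, y)
        assert np.array_equal(a.members_, b.members_)


class TestRocAnalysis:
    def test_perfect_scores(self):
        res = roc_analysis([0, 0, 1, 1], [0, 0, 1, 1])
        assert res.auc == 1.0

    def test_brute_force_concordance_equivalence(self):
        r = np.random.default_rng(30)
        scores = r.normal(size=50)
        labels = (r.random(50) < 0.4).astype(int)
        res = roc_analysis(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        pairs = [(1.0 if p > n else 0.5 if p == n else 0.0)
                 for p in pos for n in neg]
        assert res.auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_monotone_transform_invariance(self):
        r = np.random.default_rng(31)
        scores = r.normal(size=200)
        labels = (r.random(200) < 0.5).astype(int)
        a = roc_analysis(scores, labels).auc
        b = roc_analysis(np.exp(3 * scores) + 7, labels).auc
        assert a == pytest.approx(b, abs=1e-12)

    def test_null_scores_near_half(self):
        r = np.random.default_rng(32)
        res = roc_analysis(r.normal(size=2000), (r.random(2000) < 0.5))
        assert abs(res.auc - 0.5) < 0.03
        assert res.auc_ci[0] < 0.5 < res.auc_ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="binary|both classes"):
            roc_analysis([0.2, 0.8], [1, 1])

    def test_youden_tie_takes_lower_cutoff(self):
        # thresholds 3 and 1 both reach J = 0.5; the lower one wins
        scores = np.array([0.0, 1.0, 2.0, 3.0])
        labels = np.array([0, 1, 0, 1])
        res = roc_analysis(scores, labels)
        assert res.cutoff == 1.0


class TestSurvival:
    def test_km_without_censoring_is_empirical(self):
        times = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        events = np.ones(6, dtype=bool)
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        comp = km_logrank(times, events, groups, horizon=10)
        t_a, s_a = comp.curves["a"]
        # after each of the 3 deaths survival drops by 1/3
        assert s_a[-1] == pytest.approx(0.0)
        assert np.allclose(np.diff(np.unique(s_a))[0], 1 / 3, atol=1e-9)

    def test_hand_computed_product_limit_six_patients(self):
        # deaths at 2 and 5, censored at 3 within one group of 6
        times = np.array([2.0, 3.0, 5.0, 7.0, 8.0, 9.0])
        events = np.array([1, 0, 1, 0, 0, 0], dtype=bool)
        comp = km_logrank(
            np.concatenate([times, [4.0, 6.0]]),
            np.concatenate([events, [True, False]]),
            np.array(["g1"] * 6 + ["g2"] * 2),
            horizon=10,
        )
        t, s = comp.curves["g1"]
        # S(2) = 5/6; S(5) = 5/6 * 3/4 = 0.625 (product-limit by hand)
        s_at = dict(zip(t, s))
        assert s_at[2.0] == pytest.approx(5 / 6)
        assert s_at[5.0] == pytest.approx(5 / 6 * 3 / 4)

    def test_hazard_ratio_recovers_rate_ratio(self):
        r = np.random.default_rng(40)
        n = 400
        t1 = r.exponential(100, n)
        t2 = r.exponential(100 / 3, n)
        times = np.concatenate([t1, t2])
        events = np.ones(2 * n, dtype=bool)
        groups = np.array(["a"] * n + ["b"] * n)
        comp = km_logrank(times, events, groups, horizon=300)
        assert 2.4 < comp.hazard_ratio < 3.7
        assert comp.logrank_p < 1e-10

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="no events"):
            km_logrank([1.0, 2.0], [False, False], ["a", "b"])

    def test_mortality_read_at_horizon(self):
        times = np.array([100.0, 800.0, 200.0, 900.0])
        events = np.array([True, False, True, False])
        groups = np.array(["a", "a", "b", "b"])
        comp = km_logrank(times, events, groups, horizon=730)
        assert comp.mortality_at_horizon["a"] == pytest.approx(0.5)


def test_screen_variables_end_to_end():
    r = np.random.default_rng(50)
    n = 200
    y = (r.random(n) < 0.5).astype(int)
    df = pd.DataFrame({
        "y": y,
        "signal": r.normal(0, 1, n) + 0.8 * y,
        "noise": r.normal(0, 1, n),
        "cat": r.integers(0, 2, n),
    })
    res = {s.variable: s for s in
           screen_variables(df, "y", ["signal", "noise", "cat"])}
    assert res["signal"].passes_screen
    assert res["cat"].test in ("chi2", "fisher")
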