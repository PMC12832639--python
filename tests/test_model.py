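import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from eegrisk.model import (SplitSpec, bootstrap_ci, calibration_analysis,
                           decision_curve, effective_epv,
                           epv_min_sample_size, evaluate,
                           metrics_from_counts, optimal_threshold,
                           split_standardize, train_models)
from eegrisk.synth import planted_logistic_table


@pytest.fixture(scope="module")
def balanced_table():
    rng = np.random.default_rng(31)
    n = 100
    table = pd.DataFrame({
        "f1": rng.normal(size=n), "f2": rng.normal(size=n),
        "outcome": np.repeat([0, 1], n // 2)})
    return table


class TestSplitStandardize:
    def test_stratified_70_30(self, balanced_table):
        train, test, _ = split_standardize(
            balanced_table, SplitSpec(seed=1), feature_cols=["f1", "f2"])
        assert len(train) == 70 and len(test) == 30
        assert set(train["outcome"]) == set(test["outcome"]) == {0, 1}
        assert train["outcome"].sum() == 35

    def test_train_columns_standardized(self, balanced_table):
        train, _, _ = split_standardize(
            balanced_table, SplitSpec(seed=1), feature_cols=["f1", "f2"])
        assert abs(train["f1"].mean()) < 1e-9
        assert abs(train["f1"].std(ddof=0) - 1) < 1e-9

    def test_test_scaled_with_train_statistics(self, balanced_table):
        _, test, scaler = split_standardize(
            balanced_table, SplitSpec(seed=1), feature_cols=["f1", "f2"])
        # leakage guard: test mean is generally nonzero under train scaling
        assert abs(test["f1"].mean()) > 1e-12
        assert scaler.mean_.shape == (2,)


@pytest.fixture(scope="module")
def separable_models():
    rng = np.random.default_rng(5)
    n = 40
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame({
        "f1": y * 4.0 + rng.normal(scale=0.2, size=n),
        "f2": rng.normal(size=n)})
    train = X.copy()
    train["outcome"] = y
    trained = train_models(train, ["f1", "f2"], folds=5, seed=2,
                           n_repeats=1)
    return train, trained


class TestTraining:
    def test_separable_set_fit_perfectly_by_every_family(
            self, separable_models):
        train, trained = separable_models
        for name, tm in trained.items():
            pred = tm.model.predict(train[["f1", "f2"]])
            assert np.mean(pred == train["outcome"]) == 1.0, name

    def test_winning_parameters_come_from_grid(self, separable_models):
        _, trained = separable_models
        from eegrisk.model import _model_grids
        grids = _model_grids(2)
        for name, tm in trained.items():
            assert tm.best_params in grids[name][1]
            assert 0.0 <= tm.cv_auc_mean <= 1.0

    def test_identical_seed_identical_winner(self, separable_models):
        train, trained = separable_models
        again = train_models(train, ["f1", "f2"], folds=5, seed=2,
                             n_repeats=1, families=("RF", "DT", "LR"))
        for name in ("RF", "DT", "LR"):
            assert again[name].best_params == trained[name].best_params
            assert again[name].cv_auc_mean == trained[name].cv_auc_mean


class TestEvaluate:
    def test_perfect_probabilities(self):
        y = np.array([1, 1, 0, 0, 1])
        block = evaluate(y.astype(float), y)
        for key in ("accuracy", "auc", "f1", "sensitivity", "specificity"):
            assert block[key] == 1.0
        assert block["brier"] == 0.0

    def test_constant_prevalence_probability_brier(self):
        y = np.array([1] * 30 + [0] * 70)
        p = y.mean()
        block = evaluate(np.full(100, p), y)
        assert block["brier"] == pytest.approx(p * (1 - p))

    def test_hand_confusion_table(self):
        # TP=19, FN=5, TN=22, FP=3
        probs = np.concatenate([np.full(19, 0.9), np.full(5, 0.1),
                                np.full(22, 0.1), np.full(3, 0.9)])
        y = np.concatenate([np.ones(24), np.zeros(25)]).astype(int)
        block = evaluate(probs, y)
        assert block["sensitivity"] == pytest.approx(19 / 24)
        assert block["specificity"] == pytest.approx(22 / 25)
        assert block["ppv"] == pytest.approx(19 / 22)
        assert block["npv"] == pytest.approx(22 / 27)
        assert block["accuracy"] == pytest.approx(41 / 49)

    def test_f1_matches_definitional_formula(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        probs = np.clip(y * 0.6 + rng.normal(scale=0.3, size=200), 0, 1)
        block = evaluate(probs, y)
        ppv, sens = block["ppv"], block["sensitivity"]
        assert block["f1"] == pytest.approx(
            2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.2, 0.8]), np.array([1, 1]))


class TestCalibration:
    def test_probs_equal_outcomes_zero_errors(self):
        y = np.array([0, 1] * 50)
        cal = calibration_analysis(y.astype(float), y)
        assert cal["ece"] == 0.0
        assert cal["mce"] == 0.0

    def test_calibrated_by_construction_small_ece(self):
        rng = np.random.default_rng(13)
        probs = rng.uniform(0, 1, 2000)
        y = (rng.random(2000) < probs).astype(int)
        cal = calibration_analysis(probs, y)
        assert cal["ece"] < 0.05

    @pytest.mark.parametrize("seed", range(5))
    def test_ece_never_exceeds_mce(self, seed):
        rng = np.random.default_rng(seed)
        probs = rng.uniform(0, 1, 300)
        y = rng.integers(0, 2, 300)
        cal = calibration_analysis(probs, y)
        assert cal["ece"] <= cal["mce"] + 1e-12

    def test_bias_corrected_curve_present(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(150, 2))
        y = (X[:, 0] + rng.normal(scale=0.8, size=150) > 0).astype(int)
        from sklearn.linear_model import LogisticRegression

        def refit(Xb, yb):
            return LogisticRegression().fit(Xb, yb).predict_proba(X)[:, 1]

        probs = LogisticRegression().fit(X, y).predict_proba(X)[:, 1]
        cal = calibration_analysis(probs, y, boot=30, seed=0, refit=refit,
                                   X=X)
        assert "bias_corrected_curve" in cal
        assert len(cal["bias_corrected_curve"]) == 10


class TestDecisionCurve:
    def test_treat_none_is_zero_everywhere(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        dca = decision_curve(rng.uniform(0, 1, 100), y)
        assert (dca["treat_none"] == 0).all()

    def test_treat_all_approaches_prevalence_at_low_threshold(self):
        y = np.array([1] * 30 + [0] * 70)
        dca = decision_curve(np.full(100, 0.5), y,
                             thresholds=[0.001, 0.5])
        assert dca["treat_all"].iloc[0] == pytest.approx(0.3, abs=0.001)

    def test_perfect_classifier_net_benefit_equals_prevalence(self):
        y = np.array([1] * 20 + [0] * 80)
        probs = y * 0.9 + 0.05
        dca = decision_curve(probs, y, thresholds=np.arange(0.1, 0.9, 0.1))
        np.testing.assert_allclose(dca["net_benefit"], 0.2, atol=1e-12)

    def test_threshold_one_excluded(self):
        with pytest.raises(ValueError):
            decision_curve(np.array([0.5]), np.array([1]), thresholds=[1.0])


class TestBootstrapCI:
    def test_constant_metric_zero_width(self):
        y = np.array([0, 1] * 20)
        lo, hi, _ = bootstrap_ci(lambda yy, pp: 0.42, y,
                                 np.zeros(40), B=200, seed=0)
        assert lo == hi == 0.42

    def test_reproducible_under_seed(self):
        rng = np.random.default_rng(10)
        y = rng.integers(0, 2, 100)
        y[:2] = [0, 1]
        probs = np.clip(y + rng.normal(scale=0.4, size=100), 0, 1)
        a = bootstrap_ci(roc_auc_score, y, probs, B=200, seed=3)
        b = bootstrap_ci(roc_auc_score, y, probs, B=200, seed=3)
        assert a == b

    def test_auc_interval_coverage(self):
        # true AUC 0.8 via binormal construction; interval should cover
        # it in the vast majority of replicates
        hit = 0
        reps = 60
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            n = 200
            y = np.repeat([0, 1], n // 2)
            mu = np.sqrt(2) * 0.8416  # binormal separation for AUC 0.8
            scores = rng.normal(size=n) + y * mu
            probs = 1 / (1 + np.exp(-scores))
            lo, hi, _ = bootstrap_ci(roc_auc_score, y, probs, B=300,
                                     seed=r)
            hit += lo <= 0.8 <= hi
        assert hit >= int(0.9 * reps)


class TestOptimalThreshold:
    def test_perfect_separation_returns_gap_midpoint(self):
        probs = np.array([0.95, 0.92, 0.08, 0.05])
        y = np.array([1, 1, 0, 0])
        assert optimal_threshold(probs, y) == pytest.approx(0.5)

    def test_probs_equal_outcome(self):
        y = np.array([0, 1, 0, 1])
        assert optimal_threshold(y.astype(float), y) == pytest.approx(0.5)

    def test_hand_enumerated_example(self):
        probs = np.array([0.2, 0.4, 0.6, 0.8])
        y = np.array([0, 0, 1, 1])
        assert optimal_threshold(probs, y) == pytest.approx(0.5)


class TestEPV:
    def test_reference_minimum_sample_size(self):
        assert epv_min_sample_size(7, 10, 0.59) == 171

    def test_reference_effective_epv(self):
        assert effective_epv(62, 7) == 8.9

    def test_zero_incidence_exact_product(self):
        assert epv_min_sample_size(8, 10, 0.0) == 80

    def test_invalid_incidence_rejected(self):
        with pytest.raises(ValueError):
            epv_min_sample_size(7, 10, 1.0)


def test_metrics_from_counts_definitions():
    block = metrics_from_counts(19, 3, 22, 5)
    assert block["ppv"] == pytest.approx(19 / 22)
    assert block["npv"] == pytest.approx(22 / 27)
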