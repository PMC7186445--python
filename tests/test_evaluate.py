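"""AUC, repeated CV, univariate tests, gate, vetting, extreme profiling."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score
from sklearn.tree import DecisionTreeClassifier

from bedomics.augment import AdasynParams, adasyn
from bedomics.evaluate import (
    CVSpec,
    EvalReport,
    GateSpec,
    auc,
    evaluate_on_original,
    extreme_patients,
    model_gate,
    monotonicity_vetting,
    repeated_cv,
    univariate_tests,
)
from bedomics.select_train import FittedModel, train_nb
from bedomics.synthetic import feature_columns, generate_feature_table

from _oracles import pairwise_auc


class _LinearScorer:
    """Minimal estimator: score = w·x + b (for constructing FittedModels)."""

    def __init__(self, w, b=0.0):
        self.w = np.asarray(w, dtype=float)
        self.b = b

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.w + self.b


class _QuadraticScorer:
    """score = -(x0 - center)^2: a constructed unimodal dose response."""

    def __init__(self, center):
        self.center = center

    def decision_function(self, X):
        return -((np.asarray(X, dtype=float)[:, 0] - self.center) ** 2)


def _linear_model(features, w, threshold=0.0):
    return FittedModel("svm", list(features), _LinearScorer(w), threshold)


class TestAUC:
    def test_perfect_separation_is_one(self):
        assert auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_is_half(self):
        assert auc([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_four_pair_example(self):
        assert auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            auc([1, 2], [1, 1])

    def test_matches_pair_enumeration_and_trapezoid_roc(self, rng):
        for _ in range(100):
            n = int(rng.integers(6, 30))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            a = auc(scores, labels)
            assert a == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)
            assert a == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestRepeatedCV:
    @staticmethod
    def _null_recipe(table, seed):
        # train a real (but fast) model on pure-noise features
        feats = feature_columns(table)[:2]
        return train_nb(table, feats, seed=seed)

    def test_null_data_auc_near_half(self):
        df = generate_feature_table(100, 100, n_features=2, seed=31)
        spec = CVSpec(repeats=50, seed=31, leakage_mode="safe")
        report = repeated_cv(df, self._null_recipe, spec)
        assert 0.44 <= report.auc[0] <= 0.56

    def test_perfect_deterministic_classifier_zero_width_ci(self):
        df = generate_feature_table(50, 50, n_features=2, seed=32)
        df.iloc[:, 2] = df["label"] * 10.0  # feature equals scaled label
        feats = feature_columns(df)

        def recipe(table, seed):
            return _linear_model(feats, [1.0, 0.0], threshold=5.0)

        report = repeated_cv(df, recipe, CVSpec(repeats=10, seed=32, leakage_mode="safe"))
        assert report.sensitivity == (1.0, 1.0, 1.0)
        assert report.specificity == (1.0, 1.0, 1.0)
        assert report.auc == (1.0, 1.0, 1.0)

    def test_paper_mode_leaks_optimism_relative_to_safe_mode(self):
        diffs = []
        for seed in range(10):
            df = generate_feature_table(30, 90, n_features=4, shift=(1.0,), seed=100 + seed)
            paper = repeated_cv(df, self._null_recipe,
                               CVSpec(repeats=5, seed=seed, leakage_mode="paper"))
            safe = repeated_cv(df, self._null_recipe,
                               CVSpec(repeats=5, seed=seed, leakage_mode="safe"))
            diffs.append(paper.auc[0] - safe.auc[0])
        assert np.mean(diffs) > 0  # augment-before-CV is optimistic on average

    def test_ci_bounds_ordered_and_width_converges(self):
        df = generate_feature_table(40, 60, n_features=3, shift=(0.8,), seed=33)
        r_mid = repeated_cv(df, self._null_recipe, CVSpec(repeats=30, seed=33, leakage_mode="safe"))
        r_large = repeated_cv(df, self._null_recipe, CVSpec(repeats=60, seed=33, leakage_mode="safe"))
        for rep in (r_mid, r_large):
            for metric in (rep.sensitivity, rep.specificity, rep.auc):
                assert metric[1] <= metric[0] <= metric[2]
        # the percentile interval stabilizes as repeats grow
        width = lambda m: m[2] - m[1]
        assert abs(width(r_large.auc) - width(r_mid.auc)) < 0.06


class TestEvaluateOnOriginal:
    def test_overfit_tree_on_augmented_scores_perfectly_on_originals(self):
        df = generate_feature_table(41, 124, n_features=4, shift=(1.0,), seed=34)
        aug = adasyn(df, AdasynParams(seed=34))
        feats = feature_columns(df)
        tree = DecisionTreeClassifier(random_state=0).fit(
            aug[feats].to_numpy(), aug["label"].to_numpy()
        )

        class _TreeScore:
            def decision_function(self, X):
                return tree.predict_proba(np.asarray(X, float))[:, 1]

        model = FittedModel("eml", feats, _TreeScore(), 0.5)
        res = evaluate_on_original(model, df)
        assert res["sensitivity"] == 1.0
        assert res["specificity"] == 1.0
        assert res["auc"] == 1.0

    def test_constant_score_degenerates_one_sided(self):
        df = generate_feature_table(20, 20, n_features=2, seed=35)
        feats = feature_columns(df)
        model = _linear_model(feats, [0.0, 0.0], threshold=0.0)
        res = evaluate_on_original(model, df)
        # constant score >= 0 threshold → everything predicted positive
        assert {res["sensitivity"], res["specificity"]} == {1.0, 0.0}

    def test_metrics_match_brute_force_confusion_matrix(self, rng):
        df = generate_feature_table(30, 50, n_features=2, shift=(1.0,), seed=36)
        feats = feature_columns(df)
        model = _linear_model(feats, [1.0, 0.3], threshold=0.2)
        res = evaluate_on_original(model, df)
        s = model.score(df)
        y = df["label"].to_numpy()
        pred = (s >= 0.2).astype(int)
        tp = ((pred == 1) & (y == 1)).sum()
        tn = ((pred == 0) & (y == 0)).sum()
        assert res["sensitivity"] == pytest.approx(tp / y.sum())
        assert res["specificity"] == pytest.approx(tn / (len(y) - y.sum()))


class TestUnivariate:
    def test_chi_square_on_strong_2x2_association(self):
        df = pd.DataFrame({
            "label": [1] * 60 + [0] * 60,
            "cat": ["a"] * 50 + ["b"] * 10 + ["a"] * 10 + ["b"] * 50,
        })
        out = univariate_tests(df)
        row = out[out.variable == "cat"].iloc[0]
        assert row["test"] == "chi-square"
        assert row["p_value"] < 1e-6
        # hand value: chi2 = 120*(50*50-10*10)^2/(60*60*60*60) = 53.3 before
        # continuity correction; with Yates it is slightly smaller
        assert 45 < row["statistic"] <= 53.4

    def test_wilcoxon_detects_two_sd_shift(self):
        rng = np.random.default_rng(37)
        df = pd.DataFrame({
            "label": [0] * 40 + [1] * 40,
            "x": np.concatenate([rng.normal(0, 1, 40), rng.normal(2, 1, 40)]),
        })
        row = univariate_tests(df).iloc[0]
        assert row["test"] == "wilcoxon"
        assert row["p_value"] < 0.001

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(38)
        x = rng.normal(size=40)
        pvals = []
        for _ in range(1000):
            y = rng.permutation([0] * 20 + [1] * 20)
            df = pd.DataFrame({"label": y, "x": x})
            pvals.append(univariate_tests(df)["p_value"].iloc[0])
        from scipy.stats import kstest

        assert kstest(pvals, "uniform").pvalue > 0.01


class TestMonotonicityVetting:
    def _table(self):
        rng = np.random.default_rng(39)
        return pd.DataFrame({
            "patient_id": [f"P{i}" for i in range(60)],
            "label": rng.integers(0, 2, 60),
            "bed_gaussian_ptv_firstorder_p10": rng.uniform(60, 100, 60),
            "red_none_ptv_firstorder_kurtosis": rng.normal(3, 1, 60),
        })

    def test_monotone_score_passes(self):
        table = self._table()
        model = _linear_model(
            ["bed_gaussian_ptv_firstorder_p10", "red_none_ptv_firstorder_kurtosis"],
            [1.0, -0.5],
        )
        verdict = monotonicity_vetting(model, "bed_gaussian_ptv_firstorder_p10", table)
        assert verdict["pass"] is True
        assert verdict["first_decrease_at"] is None

    def test_unimodal_score_fails_and_locates_decrease(self):
        table = self._table()
        mid = 80.0
        model = FittedModel(
            "eml", ["bed_gaussian_ptv_firstorder_p10"], _QuadraticScorer(mid), 0.0
        )
        verdict = monotonicity_vetting(model, "bed_gaussian_ptv_firstorder_p10", table)
        assert verdict["pass"] is False
        assert verdict["first_decrease_at"] == pytest.approx(mid, abs=2.0)

    def test_extreme_profiles_change_the_baseline(self):
        table = self._table()
        model = _linear_model(
            ["bed_gaussian_ptv_firstorder_p10", "red_none_ptv_firstorder_kurtosis"],
            [1.0, 5.0],
        )
        v_low = monotonicity_vetting(model, "bed_gaussian_ptv_firstorder_p10", table,
                                     profile="low_risk")
        v_high = monotonicity_vetting(model, "bed_gaussian_ptv_firstorder_p10", table,
                                      profile="high_risk")
        assert v_low["pass"] and v_high["pass"]
        assert v_low["curve"][0] != v_high["curve"][0]

    def test_feature_not_in_model_rejected(self):
        model = _linear_model(["a"], [1.0])
        with pytest.raises(ValueError, match="not among"):
            monotonicity_vetting(model, "b", self._table())


class TestGate:
    @staticmethod
    def _report(sens, spec, a, mono=True):
        return EvalReport(
            sensitivity=(sens, sens, sens), specificity=(spec, spec, spec),
            auc=(a, a, a), repeats=1, monotonicity_pass=mono,
        )

    def test_svm_pattern_accepted(self):
        accept, reasons = model_gate(self._report(0.83, 0.75, 0.86), GateSpec())
        assert accept and reasons == []

    def test_nb_pattern_rejected_on_specificity(self):
        accept, reasons = model_gate(self._report(0.92, 0.44, 0.82), GateSpec())
        assert not accept
        assert any("specificity" in r for r in reasons)
        assert any("AUC" in r for r in reasons)

    def test_exact_threshold_boundary_accepts(self):
        accept, _ = model_gate(self._report(0.75, 0.75, 0.85), GateSpec())
        assert accept

    def test_non_monotonic_model_rejected_despite_metrics(self):
        accept, reasons = model_gate(self._report(0.9, 0.9, 0.95, mono=False), GateSpec())
        assert not accept
        assert any("monotonic" in r for r in reasons)


class TestExtremePatients:
    def test_five_percent_of_124_negatives_is_seven_rows(self):
        rng = np.random.default_rng(40)
        df = generate_feature_table(41, 124, n_features=3, seed=40)
        scores = rng.normal(size=165)
        y = df["label"].to_numpy()
        low, high = extreme_patients(scores, y, df)
        assert len(low) == 7 + 1  # ceil(0.05*124) rows + average row
        assert len(high) == 3 + 1  # ceil(0.05*41)
        assert "average" in low.index

    def test_group_average_row_is_arithmetic_mean(self):
        df = generate_feature_table(41, 124, n_features=3, seed=41)
        scores = df.iloc[:, 2].to_numpy()
        low, high = extreme_patients(scores, df["label"].to_numpy(), df)
        feats = feature_columns(df)
        body = low.drop(index="average")
        np.testing.assert_allclose(
            low.loc["average", feats].to_numpy(dtype=float),
            body[feats].mean().to_numpy(), atol=1e-12,
        )

    def test_tied_scores_warn_and_use_stable_order(self):
        df = generate_feature_table(20, 30, n_features=2, seed=42)
        with pytest.warns(UserWarning, match="identical"):
            low, _ = extreme_patients(np.zeros(50), df["label"].to_numpy(), df)
        first_neg = df.index[df["label"] == 0][0]
        assert low.iloc[0][feature_columns(df)[0]] == df.iloc[first_neg][feature_columns(df)[0]]
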