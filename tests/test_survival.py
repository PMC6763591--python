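"""Risk classification, Cox screening, selection pipelines, and evaluation."""

import numpy as np
import pandas as pd
import pytest

from gliomics import survival
from gliomics.phantom import CohortSpec, generate_cohort


def _clinical(os_days, index=None):
    os_days = np.asarray(os_days, float)
    idx = index if index is not None else pd.RangeIndex(len(os_days))
    return pd.DataFrame({"os_days": os_days, "event": True}, index=idx)


class TestRiskClass:
    @pytest.mark.parametrize(
        "days,expected",
        [(200, "short"), (299.9, "short"), (300, "medium"), (400, "medium"),
         (450, "medium"), (450.1, "long"), (500, "long")],
    )
    def test_cutoffs(self, days, expected):
        assert survival.assign_risk_class(days) == expected

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            survival.assign_risk_class(0)


class TestCoxFit:
    def test_beta_recovery_exponential_hazard(self):
        betas = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            x = rng.normal(size=200)
            t = rng.exponential(1.0 / np.exp(x))
            betas.append(survival.cox_univariate_fit(x, t).coefficient)
        assert abs(np.mean(betas) - 1.0) <= 0.25

    def test_constant_feature_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            survival.cox_univariate_fit(np.ones(50), np.arange(1, 51))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            survival.cox_univariate_fit(np.arange(5), np.arange(1, 6))

    def test_null_feature_usually_insignificant(self):
        rng = np.random.default_rng(1)
        T = rng.exponential(300, size=100)
        ps = [survival.cox_univariate_fit(rng.normal(size=100), T).p_value for _ in range(40)]
        assert np.mean(np.array(ps) < 0.05) < 0.2


class TestSp1Select:
    def test_perfect_predictor_selected(self):
        rng = np.random.default_rng(0)
        T = np.sort(rng.exponential(300, size=60)) + 1
        feats = pd.DataFrame({"copy_of_os": T, "noise": rng.normal(size=60)})
        sel = survival.sp1_select(feats, _clinical(T))
        assert "copy_of_os" in sel

    def test_u_shaped_effect_rejected_by_median_split(self):
        # hazard high at both extremes: continuous Cox may fire, the
        # median-dichotomized copy carries no signal
        rng = np.random.default_rng(2)
        n = 200
        x = rng.normal(size=n)
        t = rng.exponential(1.0 / np.exp(2 * np.abs(x)))
        feats = pd.DataFrame({"u_shape": x})
        sel = survival.sp1_select(feats, _clinical(t))
        assert "u_shape" not in sel

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            survival.sp1_select(pd.DataFrame(index=range(10)), _clinical(np.ones(10)))


class TestRfsSelect:
    def test_deterministic_under_seed(self, cohort):
        feats, clin, _ = cohort
        labels = survival.risk_classes(clin["os_days"])
        sub = feats.iloc[:, :20]
        assert survival.rfs_select(sub, labels, seed=0) == survival.rfs_select(
            sub, labels, seed=0
        )

    def test_fewer_subjects_than_folds_rejected(self):
        feats = pd.DataFrame(np.random.default_rng(0).normal(size=(9, 4)))
        labels = ["short"] * 3 + ["medium"] * 3 + ["long"] * 3
        with pytest.raises(ValueError):
            survival.rfs_select(feats, labels, n_folds=5)


class TestClassifierAndRegressors:
    @pytest.fixture(scope="class")
    def separable(self):
        rng = np.random.default_rng(0)
        n = 90
        labels = np.repeat(["short", "medium", "long"], n // 3)
        x = np.where(labels == "short", -5, np.where(labels == "medium", 0, 5))
        feats = pd.DataFrame(
            {"signal": x + rng.normal(0, 0.3, n), "noise": rng.normal(size=n)}
        )
        return feats, labels

    def test_separable_cohort_high_accuracy(self, separable):
        feats, labels = separable
        clf = survival.train_risk_classifier(feats, labels, seed=0)
        assert (clf.predict(feats) == labels).mean() >= 0.95

    def test_missing_class_rejected(self):
        feats = pd.DataFrame({"x": np.arange(10.0)})
        with pytest.raises(ValueError, match="missing class"):
            survival.train_risk_classifier(feats, ["short"] * 10)

    def test_reproducible_predictions(self, separable):
        feats, labels = separable
        a = survival.train_risk_classifier(feats, labels, seed=1).predict(feats)
        b = survival.train_risk_classifier(feats, labels, seed=1).predict(feats)
        np.testing.assert_array_equal(a, b)

    def test_regressor_predictions_clamped_to_class_interval(self, cohort):
        feats, clin, _ = cohort
        regs = survival.train_class_regressors(feats.iloc[:, :10], clin, seed=0)
        preds = regs["medium"].predict(feats.iloc[:, :10])
        assert np.all(preds >= 300) and np.all(preds <= 450)
        assert np.all(regs["long"].predict(feats.iloc[:, :10]) >= 450)

    def test_medium_regression_recovers_linear_effect(self):
        rng = np.random.default_rng(5)
        n, sigma = 80, 5.0
        x = rng.uniform(-1, 1, n)
        t = 375 + 60 * x + rng.normal(0, sigma, n)  # all medium-class
        # pad with a few short/long subjects so every class regressor trains
        t_all = np.concatenate([t, rng.uniform(50, 250, 6), rng.uniform(500, 900, 6)])
        x_all = np.concatenate([x, rng.uniform(-1, 1, 12)])
        feats = pd.DataFrame({"driver": x_all})
        regs = survival.train_class_regressors(feats, _clinical(t_all), seed=0)
        pred = regs["medium"].predict(feats.iloc[:n])
        rmse = np.sqrt(np.mean((pred - t) ** 2))
        assert rmse <= 1.5 * sigma

    def test_predict_dispatches_by_class(self, cohort):
        feats, clin, _ = cohort
        sub = feats.iloc[:, :10]
        labels = survival.risk_classes(clin["os_days"])
        clf = survival.train_risk_classifier(sub, labels, seed=0)
        regs = survival.train_class_regressors(sub, clin, seed=0)
        out = survival.predict_survival_days(clf, regs, sub)
        long_rows = out[out["risk_class"] == "long"]
        assert (long_rows["predicted_days"] >= 450).all()


class TestImportancePrune:
    def _model_with_importances(self, imp):
        class Fake:
            feature_importances_ = np.asarray(imp, float)

        return survival.RiskClassifier(Fake(), [f"f{i}" for i in range(len(imp))], "sp2")

    def test_threshold_arithmetic(self):
        kept = survival.importance_prune(self._model_with_importances([100, 60, 40]))
        assert kept == ["f0", "f1"]

    def test_all_equal_keeps_all(self):
        kept = survival.importance_prune(self._model_with_importances([3, 3, 3]))
        assert kept == ["f0", "f1", "f2"]

    def test_empty_result_falls_back_to_top_one(self):
        with pytest.warns(UserWarning):
            kept = survival.importance_prune(
                self._model_with_importances([100, 1, 2]), threshold=2.0
            )
        assert kept == ["f0"]


class TestConfusionStats:
    def test_identity_matrix_all_ones(self):
        s = survival.confusion_stats(np.diag([10, 10, 10]))
        for cls in ("long", "medium", "short"):
            assert all(v == 1.0 for v in s["per_class"][cls].values())
        assert s["overall_accuracy"] == 1.0

    def test_column_sums_are_reference_counts(self):
        m = [[32, 7, 10], [24, 34, 12], [0, 1, 43]]
        s = survival.confusion_stats(m)
        assert np.asarray(s["matrix"]).sum(axis=0).tolist() == [56, 42, 65]

    def test_zero_reference_column_rejected(self):
        with pytest.raises(ValueError):
            survival.confusion_stats([[1, 0, 2], [3, 0, 4], [5, 0, 6]])

    def test_stats_within_unit_interval(self, rng):
        m = rng.integers(1, 30, size=(3, 3))
        s = survival.confusion_stats(m)
        for cls_stats in s["per_class"].values():
            assert all(0.0 <= v <= 1.0 for v in cls_stats.values())


class TestLoocv:
    def test_perfect_predictor_cohort(self):
        rng = np.random.default_rng(0)
        # each OS value repeated so no leave-one-out fold isolates an extreme
        t = np.repeat([120.0, 150, 180, 350, 380, 410, 500, 600, 700], 4)
        feats = pd.DataFrame({"os_copy": t, "n": rng.normal(size=len(t))})
        rep = survival.loocv_evaluate(feats, _clinical(t), seed=0)
        assert rep["accuracy"] == 1.0
        assert rep["regression"]["medium"]["mse"] < 2500  # within the class band

    def test_error_identities(self, cohort):
        feats, clin, _ = cohort
        rep = survival.loocv_evaluate(feats.iloc[:40, :5], clin.iloc[:40], seed=0)
        for cls, e in rep["regression"].items():
            if not np.isnan(e["mse"]):
                assert e["mse"] == pytest.approx(e["rmse"] ** 2)
                assert e["mae"] <= e["rmse"] + 1e-9
        assert rep["combined_mse"] == pytest.approx(
            sum(e["mse"] for e in rep["regression"].values() if not np.isnan(e["mse"]))
        )


class TestKmLogrank:
    def test_km_starts_at_one_and_decreases(self, cohort):
        feats, clin, _ = cohort
        out = survival.km_logrank_stratify(feats["f000"], clin)
        sf = out["km_high"].survival_function_.iloc[:, 0].to_numpy()
        assert sf[0] == pytest.approx(1.0)
        assert np.all(np.diff(sf) <= 1e-12)

    def test_planted_feature_stratifies(self, cohort):
        feats, clin, planted = cohort
        out = survival.km_logrank_stratify(feats[planted[0]], clin)
        assert out["p_value"] < 0.05

    def test_degenerate_split_rejected(self, cohort):
        feats, clin, _ = cohort
        with pytest.raises(ValueError):
            survival.km_logrank_stratify(np.zeros(len(clin)), clin, threshold=1.0)

    def test_two_hazard_power(self):
        # HR = 3 between groups of 80: log-rank should almost always fire
        hits = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            x = np.concatenate([np.zeros(80), np.ones(80)])
            t = rng.exponential(np.where(x > 0, 100, 300))
            clin = _clinical(np.maximum(t, 1))
            if survival.km_logrank_stratify(x, clin, threshold=0.5)["p_value"] < 0.05:
                hits += 1
        assert hits >= 18
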