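import numpy as np
import pandas as pd
import pytest

from lesionrad.evaluation import (  # noqa: F401
    CLASSIFIER_KINDS,
    MODEL_SEQUENCES,
    SplitPlan,
    compare_auc,
    evaluate_all,
    operating_point,
    predict_scores,
    roc_auc,
    split_cohort,
    train_classifier,
)
from lesionrad.io import FeatureTable
from lesionrad.synthetic import planted_feature_table

from .oracles import brute_auc


def _table(subjects, labels, features=None):
    n = len(labels)
    data = {"subject_id": subjects,
            "lesion_id": [f"l{i}" for i in range(n)],
            "label": labels}
    if features is not None:
        data.update(features)
    else:
        data["t2wi::x"] = np.arange(n, dtype=float)
    return FeatureTable(pd.DataFrame(data))


class TestSplitCohort:
    def test_ten_balanced_subjects(self):
        table = _table([f"s{i}" for i in range(10)], [0] * 5 + [1] * 5)
        plan = split_cohort(table, 0.2, seed=1)
        assert len(plan.train_lesions) == 8
        assert len(plan.test_lesions) == 2
        test_labels = table.frame.set_index("lesion_id").loc[
            plan.test_lesions, "label"]
        assert sorted(test_labels) == [0, 1]

    def test_subject_never_splits(self):
        subjects = ["a", "a", "a"] + [f"s{i}" for i in range(9)]
        labels = [1, 1, 1] + [0, 1] * 4 + [0]
        table = _table(subjects, labels)
        for seed in range(20):
            plan = split_cohort(table, 0.25, seed=seed)
            frame = table.frame.set_index("lesion_id")
            test_subjects = set(frame.loc[plan.test_lesions, "subject_id"])
            train_subjects = set(frame.loc[plan.train_lesions, "subject_id"])
            assert not test_subjects & train_subjects

    def test_disjoint_union(self):
        table = _table([f"s{i}" for i in range(12)], [0, 1] * 6)
        plan = split_cohort(table, 0.25, seed=3)
        assert set(plan.train_lesions) | set(plan.test_lesions) == \
            set(table.frame["lesion_id"])

    def test_test_fraction_near_20_percent(self):
        # many-subject cohort with 1-3 lesions each over 50 seeds
        rng = np.random.default_rng(0)
        subjects, labels = [], []
        for si in range(90):
            label = si % 2
            for _ in range(int(rng.integers(1, 4))):
                subjects.append(f"s{si}")
                labels.append(label)
        table = _table(subjects, labels)
        n = len(labels)
        fracs = [len(split_cohort(table, 0.2, seed=s).test_lesions) / n
                 for s in range(50)]
        assert abs(np.mean(fracs) - 0.2) < 0.02
        assert max(fracs) < 0.3 and min(fracs) > 0.1

    def test_moving_subject_changes_hash(self):
        plan_a = SplitPlan(["l1", "l2"], ["l3"], seed=0)
        plan_b = SplitPlan(["l1"], ["l2", "l3"], seed=0)
        assert plan_a.split_hash != plan_b.split_hash

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            SplitPlan(["l1"], ["l1"], seed=0)

    def test_impossible_stratification(self):
        table = _table(["a", "b", "c"], [0, 0, 0])
        with pytest.raises(ValueError):
            split_cohort(table, 0.2, seed=0)

    def test_lesion_level_mode(self):
        subjects = ["a"] * 3 + [f"s{i}" for i in range(9)]
        labels = [1, 1, 1] + [0, 1] * 4 + [0]
        table = _table(subjects, labels)
        plan = split_cohort(table, 0.25, seed=5, grouping="lesion")
        assert len(plan.test_lesions) >= 2


class TestClassifiers:
    def _separable(self, n=40):
        rng = np.random.default_rng(3)
        y = np.array([0, 1] * (n // 2))
        X = np.column_stack([y * 4.0 + rng.normal(0, 0.2, n),
                             -y * 3.0 + rng.normal(0, 0.2, n)])
        return X, y

    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_separable_training_accuracy(self, kind):
        X, y = self._separable()
        model = train_classifier(kind, X, y, ["f0", "f1"], seed=0)
        Xs = model.scaler.transform(X)
        assert (model.estimator.predict(Xs) == y).mean() == 1.0

    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_deterministic_predictions(self, kind):
        X, y = self._separable()
        table = _table([f"s{i}" for i in range(len(y))], y,
                       {"f0": X[:, 0], "f1": X[:, 1]})
        m1 = train_classifier(kind, X, y, ["f0", "f1"], seed=7)
        m2 = train_classifier(kind, X, y, ["f0", "f1"], seed=7)
        np.testing.assert_array_equal(predict_scores(m1, table),
                                      predict_scores(m2, table))

    def test_scores_in_unit_interval(self):
        X, y = self._separable()
        table = _table([f"s{i}" for i in range(len(y))], y,
                       {"f0": X[:, 0], "f1": X[:, 1]})
        for kind in CLASSIFIER_KINDS:
            scores = predict_scores(
                train_classifier(kind, X, y, ["f0", "f1"], seed=0), table)
            assert np.all((scores >= 0) & (scores <= 1)), kind
            assert np.all(np.isfinite(scores))

    def test_logistic_coefficient_sign(self, rng):
        y = rng.integers(0, 2, 100)
        X = (y * 2.0 + rng.normal(0, 1, 100))[:, None]
        model = train_classifier("logistic_regression", X, y, ["f0"], seed=0)
        assert model.estimator.coef_[0, 0] > 0

    def test_duplicate_rows_identical_scores(self, rng):
        X, y = self._separable()
        table = _table(["s0", "s1"], [0, 1],
                       {"f0": [X[0, 0], X[0, 0]], "f1": [X[0, 1], X[0, 1]]})
        model = train_classifier("random_forest", X, y, ["f0", "f1"], seed=0)
        scores = predict_scores(model, table)
        assert scores[0] == scores[1]

    def test_empty_feature_set_errors(self):
        with pytest.raises(ValueError, match="no features"):
            train_classifier("knn", np.empty((10, 0)), np.array([0, 1] * 5), [])

    def test_column_mismatch_errors(self):
        X, y = self._separable()
        model = train_classifier("knn", X, y, ["f0", "f1"], seed=0)
        table = _table(["s0"], [1], {"f0": [0.0]})
        with pytest.raises(ValueError, match="missing"):
            predict_scores(model, table)

    def test_one_class_training_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            train_classifier("knn", np.ones((5, 1)), np.zeros(5, int), ["f0"])


class TestROC:
    def test_hand_example(self):
        fpr, tpr, thr, auc = roc_auc(np.array([0.9, 0.4, 0.6, 0.2]),
                                     np.array([1, 1, 0, 0]))
        assert auc == pytest.approx(0.75)  # 3 of 4 pairs concordant

    def test_perfect_ranking(self):
        labels = np.array([0, 0, 1, 1])
        _, _, _, auc = roc_auc(labels.astype(float), labels)
        assert auc == 1.0

    def test_all_ties(self):
        _, _, _, auc = roc_auc(np.full(10, 0.5), np.array([0, 1] * 5))
        assert auc == 0.5

    def test_one_class_errors(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(np.arange(4.0), np.ones(4, int))

    def test_matches_brute_force_pair_counting(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            scores = np.round(rng.uniform(size=n), 1)  # force ties
            _, _, _, auc = roc_auc(scores, labels)
            assert auc == pytest.approx(brute_auc(scores, labels)), f"seed={seed}"

    def test_curve_monotone(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        labels[:2] = [0, 1]
        fpr, tpr, _, _ = roc_auc(scores, labels)
        assert np.all(np.diff(fpr) >= 0)
        assert np.all(np.diff(tpr) >= 0)
        assert fpr[0] == 0 and tpr[0] == 0
        assert fpr[-1] == 1 and tpr[-1] == 1


class TestOperatingPoint:
    def test_perfect_classifier(self):
        labels = np.array([0, 0, 1, 1])
        thr, sens, spec = operating_point(*roc_auc(labels.astype(float), labels)[:3])
        assert sens == 1.0 and spec == 1.0
        assert 0 < thr <= 1.0  # threshold in score units

    def test_null_scores_sens_plus_spec_near_one(self):
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            scores = rng.uniform(size=200)
            labels = rng.integers(0, 2, 200)
            labels[:2] = [0, 1]
            _, sens, spec = operating_point(*roc_auc(scores, labels)[:3])
            vals.append(sens + spec)
        # Youden optimization biases upward on null data; mean stays near 1
        assert np.mean(vals) == pytest.approx(1.0, abs=0.25)

    def test_tie_broken_toward_sensitivity(self):
        # two thresholds with equal Youden: prefer the higher-sensitivity one
        fpr = np.array([0.0, 0.0, 0.5, 1.0])
        tpr = np.array([0.0, 0.5, 1.0, 1.0])
        thr = np.array([np.inf, 0.8, 0.5, 0.1])
        t, sens, spec = operating_point(fpr, tpr, thr)
        assert sens == 1.0 and t == 0.5


class TestCompareAUC:
    def test_identical_scores_p_one(self, rng):
        scores = rng.uniform(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]
        assert compare_auc(scores, scores, labels) == 1.0

    def test_power_strong_vs_null(self):
        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            labels = rng.integers(0, 2, 200)
            labels[:2] = [0, 1]
            strong = labels + rng.normal(0, 0.5, 200)
            null = rng.normal(0, 1, 200)
            if compare_auc(strong, null, labels) < 0.01:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_delong_variance_close_to_bootstrap(self):
        from lesionrad.evaluation import delong_variance
        rng = np.random.default_rng(5)
        n = 200
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        scores = labels + rng.normal(0, 1.2, n)
        auc, v10, v01 = delong_variance(scores, labels)
        var_delong = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
        boot = []
        for _ in range(2000):
            idx = rng.integers(0, n, n)
            if labels[idx].min() == labels[idx].max():
                continue
            _, _, _, a = roc_auc(scores[idx], labels[idx])
            boot.append(a)
        var_boot = np.var(boot, ddof=1)
        assert var_delong == pytest.approx(var_boot, rel=0.2)


class TestEvaluateAll:
    def test_planted_effect_grid(self):
        table, _ = planted_feature_table(n_lesions=200, seed=1)
        report = evaluate_all(table, seed=1)
        assert len(report.cells) == 20
        keys = {f"{s}::{c}" for s in MODEL_SEQUENCES for c in CLASSIFIER_KINDS}
        assert set(report.cells) == keys
        combined_lr = report.cells["combined::logistic_regression"]
        assert combined_lr["available"]
        assert combined_lr["auc"] >= 0.9

    def test_no_leakage_training_artifacts_fixed(self):
        table, _ = planted_feature_table(n_lesions=120, seed=3)
        plan = split_cohort(table, 0.2, seed=3)
        report1 = evaluate_all(table, seed=3, split_plan=plan)
        # shuffle *test* labels only (split held fixed); train rows untouched
        frame = table.frame.copy()
        is_test = frame["lesion_id"].isin(set(plan.test_lesions)).to_numpy()
        rng = np.random.default_rng(0)
        frame.loc[is_test, "label"] = rng.permutation(
            frame.loc[is_test, "label"].to_numpy())
        report2 = evaluate_all(FeatureTable(frame), seed=3, split_plan=plan)
        assert report1.selection == report2.selection
        assert report1.split["hash"] == report2.split["hash"]

    def test_unavailable_cells_recorded(self, rng):
        # pure-noise tiny cohort with a punishing variance threshold:
        # every cell must be recorded as unavailable, never dropped
        data = {"subject_id": [f"s{i}" for i in range(30)],
                "lesion_id": [f"l{i}" for i in range(30)],
                "label": [0, 1] * 15}
        for seq in ("inphase", "outphase", "t2wi", "dwi"):
            for j in range(5):
                data[f"{seq}::noise::f{j}"] = rng.standard_normal(30)
        table = FeatureTable(pd.DataFrame(data))
        with pytest.warns(UserWarning):
            report = evaluate_all(table, seed=0, variance_threshold=1e9)
        assert len(report.cells) == 20
        assert all(not c["available"] for c in report.cells.values())

    def test_report_serialization(self, tmp_path):
        table, _ = planted_feature_table(n_lesions=80, seed=9)
        report = evaluate_all(table, seed=9)
        path = tmp_path / "report.json"
        report.save(path)
        import json
        data = json.loads(path.read_text())
        assert len(data["cells"]) == 20
        text = report.table_text()
        assert "Logistic Regression" in text
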