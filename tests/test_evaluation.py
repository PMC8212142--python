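"""Evaluation protocol: splits, transforms, metrics, paired statistics."""

import numpy as np
import pandas as pd
import pytest

from isingml.datasets import LabeledDataset
from isingml.evaluation import (
    EvaluationReport,
    IsingClassifier,
    baseline_classifier,
    compare_classifiers,
    compute_metrics,
    evaluate_classifiers,
    feature_importance,
    make_splits,
    overfitting_gap,
    pca_fit_project,
    select_top_loading_features,
    subsample_training,
    zscore_fit_apply,
)
from isingml.model import SolverSpec, TrainedIsingModel
from isingml.synthetic import make_separable_toy


class TestMakeSplits:
    def test_balanced_ten_samples(self):
        labels = np.array([1] * 5 + [2] * 5)
        plan = make_splits(labels, n_splits=3, train_fraction=0.8, seed=0)
        for tr, te in zip(plan.train_indices, plan.test_indices):
            assert len(tr) == 8 and len(te) == 2
            assert np.sum(labels[tr] == 1) == 4
            assert np.sum(labels[te] == 1) == 1
            assert len(np.intersect1d(tr, te)) == 0
            assert len(np.union1d(tr, te)) == 10

    def test_deterministic(self):
        labels = np.repeat([1, 2, 3], 10)
        a = make_splits(labels, 5, 0.8, seed=3)
        b = make_splits(labels, 5, 0.8, seed=3)
        for x, y in zip(a.train_indices, b.train_indices):
            np.testing.assert_array_equal(x, y)

    def test_test_appearance_counts_binomial(self):
        labels = np.repeat([1, 2], 25)
        plan = make_splits(labels, n_splits=100, train_fraction=0.8, seed=1)
        counts = np.zeros(50)
        for te in plan.test_indices:
            counts[te] += 1
        # each sample lands in test with p = 0.2 per split: 20 +/- 8 covers
        # more than 4 binomial standard deviations
        assert np.all(counts >= 8) and np.all(counts <= 36)
        assert abs(counts.mean() - 20) < 2

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            make_splits(np.array([1, 1, 2]), 2, 0.8, seed=0)


class TestZScore:
    def test_unit_column(self):
        train = np.array([[1.0], [2.0], [3.0]])
        test = np.array([[4.0]])
        tz, sz, mu, sd = zscore_fit_apply(train, test)
        np.testing.assert_allclose(tz[:, 0], [-1, 0, 1])
        assert sz[0, 0] == pytest.approx((4 - 2) / 1)

    def test_constant_column_zeroed(self):
        train = np.full((4, 1), 7.0)
        test = np.array([[9.0]])
        tz, sz, _, sds = zscore_fit_apply(train, test)
        assert np.all(tz == 0) and np.all(sz == 0)
        assert sds[0] == 0

    def test_hand_formula(self, rng):
        train = rng.standard_normal((10, 3))
        test = rng.standard_normal((4, 3))
        _, sz, mu, sd = zscore_fit_apply(train, test)
        np.testing.assert_allclose(sz, (test - mu) / sd, atol=1e-12)

    def test_no_leakage_bitwise(self, rng):
        train = rng.standard_normal((10, 3))
        t1, t2 = rng.standard_normal((4, 3)), rng.standard_normal((6, 3))
        za, _, mu_a, sd_a = zscore_fit_apply(train, t1)
        zb, _, mu_b, sd_b = zscore_fit_apply(train, t2)
        np.testing.assert_array_equal(za, zb)
        np.testing.assert_array_equal(mu_a, mu_b)
        np.testing.assert_array_equal(sd_a, sd_b)


class TestPCA:
    def test_perfectly_correlated_features(self):
        t = np.linspace(-1, 1, 20)[:, None]
        train = np.hstack([t, 2 * t])
        train_p, _, _, ev = pca_fit_project(train, train, 2)
        assert ev[0] / ev.sum() == pytest.approx(1.0, abs=1e-12)

    def test_orthonormal_loadings(self, rng):
        train = rng.standard_normal((30, 6))
        _, _, loadings, _ = pca_fit_project(train, train[:2], 4)
        np.testing.assert_allclose(loadings.T @ loadings, np.eye(4), atol=1e-10)

    def test_full_reconstruction(self, rng):
        train = rng.standard_normal((15, 5))
        train_p, _, loadings, _ = pca_fit_project(train, train[:1], 5)
        recon = train_p @ loadings.T + train.mean(axis=0)
        np.testing.assert_allclose(recon, train, atol=1e-8)

    def test_sign_convention(self, rng):
        train = rng.standard_normal((20, 4))
        _, _, loadings, _ = pca_fit_project(train, train[:1], 3)
        for j in range(3):
            assert loadings[np.abs(loadings[:, j]).argmax(), j] > 0

    def test_too_many_components(self, rng):
        with pytest.raises(ValueError):
            pca_fit_project(rng.standard_normal((5, 3)), np.zeros((1, 3)), 4)

    def test_no_leakage_bitwise(self, rng):
        train = rng.standard_normal((20, 5))
        _, _, la, ev_a = pca_fit_project(train, rng.standard_normal((3, 5)), 3)
        _, _, lb, ev_b = pca_fit_project(train, rng.standard_normal((9, 5)), 3)
        np.testing.assert_array_equal(la, lb)
        np.testing.assert_array_equal(ev_a, ev_b)


class TestSubsample:
    def test_full_fraction_identity(self):
        labels = np.repeat([1, 2], 10)
        train = np.arange(16)
        reps = subsample_training(train, labels, 1.0, n_replicates=3, seed=0)
        for rep in reps:
            np.testing.assert_array_equal(rep, train)

    def test_stratified_counts(self):
        labels = np.repeat([1, 2], 50)
        train = np.arange(100)
        reps = subsample_training(train, labels, 0.2, n_replicates=5, seed=1)
        for rep in reps:
            assert np.sum(labels[rep] == 1) == 10
            assert np.sum(labels[rep] == 2) == 10

    def test_replicates_differ(self):
        labels = np.repeat([1, 2], 50)
        reps = subsample_training(np.arange(100), labels, 0.5,
                                  n_replicates=50, seed=2)
        unique = {tuple(r) for r in reps}
        assert len(unique) > 45

    def test_empty_class_rejected(self):
        labels = np.repeat([1, 2], 2)
        with pytest.raises(ValueError):
            subsample_training(np.arange(4), labels, 0.1, n_replicates=1, seed=0)


class TestComputeMetrics:
    def test_balanced_accuracy_mean_of_recalls(self):
        y_true = np.array([1, 1, 2, 2])
        y_pred = np.array([1, 1, 2, 1])  # recalls 1.0 and 0.5
        proba = np.eye(2)[y_pred - 1]
        m = compute_metrics(y_true, y_pred, proba, 2)
        assert m["balanced_accuracy"] == pytest.approx(0.75)

    def test_perfect_prediction_all_ones(self):
        y = np.array([1, 2, 1, 2])
        proba = np.eye(2)[y - 1] * 0.98 + 0.01
        m = compute_metrics(y, y, proba, 2)
        for v in m.values():
            assert v == pytest.approx(1.0)

    def test_three_class_hand_computation(self):
        # confusion: class1 -> [2,1,0]; class2 -> [0,2,1]; class3 -> [1,0,2]
        y_true = np.array([1, 1, 1, 2, 2, 2, 3, 3, 3])
        y_pred = np.array([1, 1, 2, 2, 2, 3, 1, 3, 3])
        proba = np.eye(3)[y_pred - 1] * 0.9 + 0.05
        m = compute_metrics(y_true, y_pred, proba, 3)
        assert m["accuracy"] == pytest.approx(6 / 9)
        assert m["balanced_accuracy"] == pytest.approx(2 / 3)
        # per-class F1: precision 2/3 recall 2/3 for every class
        assert m["f1"] == pytest.approx(2 / 3)

    def test_absent_class_warns(self):
        y_true = np.array([1, 1])
        y_pred = np.array([1, 2])
        proba = np.eye(2)[y_pred - 1]
        with pytest.warns(UserWarning, match="absent"):
            m = compute_metrics(y_true, y_pred, proba, 2)
        assert m["balanced_accuracy"] == pytest.approx(0.5)

    def test_random_predictions_near_chance(self, rng):
        k = 4
        y_true = np.repeat(np.arange(1, k + 1), 250)
        y_pred = rng.integers(1, k + 1, len(y_true))
        proba = np.full((len(y_true), k), 1 / k)
        m = compute_metrics(y_true, y_pred, proba, k)
        assert m["balanced_accuracy"] == pytest.approx(1 / k, abs=0.05)


def _report_from_values(values: dict[str, np.ndarray], metric="balanced_accuracy",
                        phase="test") -> EvaluationReport:
    rows = []
    for name, vals in values.items():
        for split, v in enumerate(vals):
            rows.append({"classifier": name, "split": split, "phase": phase,
                         "metric": metric, "value": v})
    return EvaluationReport(records=pd.DataFrame(rows))


class TestCompareClassifiers:
    def test_identical_vectors_p_one(self, rng):
        v = rng.random(20)
        report = _report_from_values({"a": v, "b": v.copy()})
        table = compare_classifiers(report)
        assert table["p_bonferroni"].iloc[0] == 1.0

    def test_uniform_improvement_significant(self, rng):
        base = rng.random(50) * 0.1 + 0.7
        report = _report_from_values({"a": base + 0.1, "b": base})
        table = compare_classifiers(report)
        assert table["p_bonferroni"].iloc[0] < 0.001

    def test_bonferroni_multiplication(self, rng):
        vals = {f"c{i}": rng.random(30) for i in range(10)}  # 45 pairs
        report = _report_from_values(vals)
        table = compare_classifiers(report)
        assert len(table) == 45
        expected = np.minimum(table["p_raw"] * 45, 1.0)
        np.testing.assert_allclose(table["p_bonferroni"], expected, atol=1e-12)


class TestOverfittingGap:
    def test_zero_gap(self, rng):
        v = rng.random(10)
        rows = []
        for phase in ("train", "test"):
            for split, x in enumerate(v):
                rows.append({"classifier": "a", "split": split, "phase": phase,
                             "metric": "balanced_accuracy", "value": x})
        report = EvaluationReport(records=pd.DataFrame(rows))
        g = overfitting_gap(report)
        assert g["gap_mean"].iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert g["gap_sem"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_constant_gap(self):
        rows = []
        for split in range(5):
            rows.append({"classifier": "a", "split": split, "phase": "train",
                         "metric": "balanced_accuracy", "value": 0.9})
            rows.append({"classifier": "a", "split": split, "phase": "test",
                         "metric": "balanced_accuracy", "value": 0.7})
        report = EvaluationReport(records=pd.DataFrame(rows))
        g = overfitting_gap(report)
        assert g["gap_mean"].iloc[0] == pytest.approx(0.2)


def _model(weights) -> TrainedIsingModel:
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    return TrainedIsingModel(weights=w, class_names=["a", "b"], solver_name="x",
                             beta_final_selected=None, n_averaged=1, training_nll=0.0)


class TestFeatureImportance:
    def test_single_model_ranking(self):
        table = feature_importance([_model([1.0, -1.0, 0.2])])
        assert list(table["feature"]) == [0, 1, 2]
        assert list(table["rank"]) == [1, 2, 3]

    def test_all_zero_weights(self):
        table = feature_importance([_model([0.0, 0.0])])
        assert np.all(table["importance"] == 0)

    def test_requires_models(self):
        with pytest.raises(ValueError):
            feature_importance([])


class TestTopLoadingSelection:
    def test_full_sort(self):
        loadings = np.array([[0.9], [-0.95], [0.1]])
        np.testing.assert_array_equal(
            select_top_loading_features(loadings, 1, 3), [1, 0, 2]
        )

    def test_top_two(self):
        loadings = np.array([[0.9], [-0.95], [0.1]])
        np.testing.assert_array_equal(
            select_top_loading_features(loadings, 1, 2), [1, 0]
        )

    def test_matches_brute_force_sort(self, rng):
        loadings = rng.standard_normal((40, 2))
        got = select_top_loading_features(loadings, 2, 10)
        order = sorted(range(40), key=lambda i: (-abs(loadings[i, 1]), i))
        np.testing.assert_array_equal(got, order[:10])

    def test_k_too_large(self, rng):
        with pytest.raises(ValueError):
            select_top_loading_features(rng.standard_normal((3, 1)), 1, 4)


class TestFullProtocol:
    def test_pipeline_deterministic(self):
        ds = make_separable_toy(40, margin=3.0, seed=0)
        clfs = [IsingClassifier(SolverSpec("field")),
                baseline_classifier("logistic")]
        plan = make_splits(ds.labels, n_splits=3, seed=7)
        a = evaluate_classifiers(ds, clfs, plan, seed=7)
        b = evaluate_classifiers(ds, clfs, plan, seed=7)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_report_contains_all_cells(self):
        ds = make_separable_toy(40, margin=3.0, seed=1)
        clfs = [IsingClassifier(SolverSpec("field"))]
        plan = make_splits(ds.labels, n_splits=2, seed=1)
        report = evaluate_classifiers(ds, clfs, plan, seed=1)
        # 1 classifier x 2 splits x 2 phases x 4 metrics
        assert len(report.records) == 16
        summary = report.summary("test")
        assert set(summary["metric"]) == {"accuracy", "balanced_accuracy", "auc", "f1"}

    def test_ising_models_collected_for_importance(self):
        ds = make_separable_toy(40, margin=3.0, seed=2)
        clfs = [IsingClassifier(SolverSpec("field"))]
        plan = make_splits(ds.labels, n_splits=2, seed=2)
        report = evaluate_classifiers(ds, clfs, plan, seed=2)
        assert len(report.models["field"]) == 2
        table = feature_importance(report.models["field"])
        assert len(table) == 2
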