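import numpy as np
import pytest

import ictalfeat as icf
from ictalfeat.classify import ModelSpec


class TestBalancedClassWeights:
    def test_balanced_labels_give_unit_weights(self):
        labels = np.repeat(list(icf.CLASS_ORDER), 10)
        weights = icf.balanced_class_weights(labels)
        assert all(w == pytest.approx(1.0) for w in weights.values())

    def test_imbalanced_formula(self):
        labels = np.array(["A"] * 90 + ["B"] * 10)
        w = icf.balanced_class_weights(labels)
        assert w["A"] == pytest.approx(100 / (2 * 90))
        assert w["B"] == pytest.approx(5.0)

    def test_single_class_weight_one(self):
        assert icf.balanced_class_weights(["A", "A"]) == {"A": 1.0}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            icf.balanced_class_weights([])


class TestSmote:
    def make_data(self, seed=0):
        rng = np.random.default_rng(seed)
        X = np.vstack([rng.normal(0, 1, (100, 4)), rng.normal(3, 1, (40, 4))])
        y = np.array([0] * 100 + [1] * 40)
        return X, y

    def test_balances_to_majority_count(self):
        X, y = self.make_data()
        X2, y2 = icf.smote_oversample(X, y, seed=1)
        counts = dict(zip(*np.unique(y2, return_counts=True)))
        assert counts == {0: 100, 1: 100}
        assert X2.shape == (200, 4)

    def test_synthetic_rows_inside_class_bounding_box(self):
        X, y = self.make_data()
        X2, y2 = icf.smote_oversample(X, y, seed=2)
        synth = X2[140:]
        rows = X[y == 1]
        assert np.all(synth >= rows.min(axis=0) - 1e-12)
        assert np.all(synth <= rows.max(axis=0) + 1e-12)

    def test_deterministic(self):
        X, y = self.make_data()
        a = icf.smote_oversample(X, y, seed=3)
        b = icf.smote_oversample(X, y, seed=3)
        np.testing.assert_array_equal(a[0], b[0])

    def test_singleton_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(11, 2))
        y = np.array([0] * 10 + [1])
        with pytest.raises(ValueError, match="single member"):
            icf.smote_oversample(X, y)


class TestFoldPlan:
    def test_balanced_classes_split_evenly(self):
        labels = np.repeat(list(icf.CLASS_ORDER), 100)
        plan = icf.make_fold_plan(labels, n_folds=10, seed=0)
        for fold in range(10):
            test_labels = labels[plan.test_indices(fold)]
            _, counts = np.unique(test_labels, return_counts=True)
            assert np.all(counts == 10)

    def test_every_index_in_exactly_one_test_fold(self):
        labels = np.repeat(list(icf.CLASS_ORDER), 20)
        plan = icf.make_fold_plan(labels, n_folds=5, seed=1)
        seen = np.concatenate([plan.test_indices(f) for f in range(5)])
        assert sorted(seen) == list(range(len(labels)))

    def test_different_seeds_differ(self):
        labels = np.repeat(list(icf.CLASS_ORDER), 20)
        a = icf.make_fold_plan(labels, 5, seed=0)
        b = icf.make_fold_plan(labels, 5, seed=1)
        assert not np.array_equal(a.assignments, b.assignments)

    def test_small_class_rejected_by_name(self):
        labels = np.array(["ABSZ"] * 3 + ["FNSZ"] * 50)
        with pytest.raises(ValueError, match="ABSZ"):
            icf.make_fold_plan(labels, n_folds=10, seed=0)

    def test_duplicating_segments_preserves_fold_proportions(self):
        labels = np.array(["ABSZ"] * 30 + ["FNSZ"] * 90)
        doubled = np.concatenate([labels, labels])
        plan = icf.make_fold_plan(doubled, n_folds=6, seed=2)
        for fold in range(6):
            test = doubled[plan.test_indices(fold)]
            assert np.mean(test == "ABSZ") == pytest.approx(0.25)


class TestNullModel:
    def test_uniform_guessing_rates(self):
        probs = icf.null_model_predict(["A"] * 10, 10_000, 6, seed=0)
        truth = np.random.default_rng(1).integers(0, 6, 10_000)
        acc = np.mean(probs.argmax(axis=1) == truth)
        assert acc == pytest.approx(1 / 6, abs=0.02)

    def test_probabilities_valid_and_deterministic(self):
        a = icf.null_model_predict([], 100, 6, seed=5)
        b = icf.null_model_predict([], 100, 6, seed=5)
        np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(a.sum(axis=1), 1.0)

    def test_too_few_classes(self):
        with pytest.raises(ValueError):
            icf.null_model_predict([], 10, 1)


class TestRunCV:
    def test_report_structure_and_determinism(self, small_features):
        plan = icf.make_fold_plan(small_features.labels, n_folds=3, seed=0)
        specs = [ModelSpec("DT", "class_weight_balanced", seed=0),
                 ModelSpec("Null", "none", seed=0)]
        rep1 = icf.run_cv(small_features, specs, plan, selection_k=10)
        rep2 = icf.run_cv(small_features, specs, plan, selection_k=10)
        assert set(rep1.results) == {"DT", "Null"}
        for name in rep1.results:
            assert len(rep1.results[name].fold_metrics) == 3
            assert rep1.results[name].mean == rep2.results[name].mean
        assert rep1.results["DT"].pooled_confusion.total == small_features.n_segments

    def test_unavailable_model_is_skipped_not_fatal(self, small_features):
        plan = icf.make_fold_plan(small_features.labels, n_folds=3, seed=0)
        specs = [ModelSpec("CatBoost", "auto_balanced", seed=0),
                 ModelSpec("Null", "none", seed=0)]
        rep = icf.run_cv(small_features, specs, plan, selection_k=10)
        assert "Null" in rep.results
        try:
            import catboost  # noqa: F401
            assert "CatBoost" in rep.results
        except ImportError:
            assert "CatBoost" in rep.unavailable

    def test_paper_compat_mode_selects_globally(self, small_features):
        plan = icf.make_fold_plan(small_features.labels, n_folds=3, seed=0)
        specs = [ModelSpec("DT", "class_weight_balanced", seed=0)]
        rep = icf.run_cv(small_features, specs, plan, selection_k=10,
                         cv_mode="paper_compat")
        sels = rep.results["DT"].fold_selected
        assert all(s == sels[0] for s in sels)

    def test_leakage_guard_training_fold_selection_unchanged(self, small_features):
        """Planting a held-out-only outlier column must not change the
        training-fold MI selection in the default fold-wise mode."""
        plan = icf.make_fold_plan(small_features.labels, n_folds=5, seed=3)
        baseline = icf.fold_feature_selections(small_features, plan,
                                               selection_k=10, seed=0)
        for fold in range(plan.n_folds):
            probe = np.zeros(small_features.n_segments)
            test_idx = plan.test_indices(fold)
            # outlier values perfectly aligned with the label: pure leakage bait
            probe[test_idx] = 1e6 * (np.array(
                [list(icf.CLASS_ORDER).index(l) for l in
                 small_features.labels[test_idx]]) + 1)
            planted = icf.FeatureMatrix(
                values=np.column_stack([small_features.values, probe]),
                names=list(small_features.names) + ["leak_probe"],
                labels=small_features.labels,
                group_ids=small_features.group_ids,
                start_times=small_features.start_times)
            sel, _ = icf.classify._fold_selection(
                planted, plan.train_indices(fold), 10, 3, 0)
            assert "leak_probe" not in sel.selected_names
            assert sel.selected_names == baseline[fold]
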