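"""Metrics oracle, classifier training contracts, reduction and ablation."""

import numpy as np
import pandas as pd
import pytest

from gaitfatigue.features import FEATURE_NAMES
from gaitfatigue.models import (ModelSpec, PartitionSpec, compare_models,
                                confusion_from_labels, default_models,
                                metrics_from_confusion, rank_features,
                                reduce_and_eval, sensor_ablation,
                                subset_feature_indices, train_eval)


def _brute_metrics(y_true, y_pred, n_classes=4):
    """Recount precision/recall/accuracy per class directly from the raw
    label pairs with explicit loops."""
    pairs = list(zip(y_true, y_pred))
    acc = sum(t == p for t, p in pairs) / len(pairs)
    precision, recall = [], []
    for c in range(n_classes):
        tp = sum(1 for t, p in pairs if t == c and p == c)
        fp = sum(1 for t, p in pairs if t != c and p == c)
        fn = sum(1 for t, p in pairs if t == c and p != c)
        precision.append(tp / (tp + fp) if tp + fp else 0.0)
        recall.append(tp / (tp + fn) if tp + fn else 0.0)
    return acc, precision, recall


class TestMetrics:
    def test_perfect_diagonal(self):
        report = metrics_from_confusion(np.diag([10, 20, 30, 40]))
        assert report.accuracy == 1.0
        assert np.all(report.precision == 1.0)
        assert np.all(report.recall == 1.0)
        assert np.all(report.f1 == 1.0)
        assert report.macro_f1 == 1.0

    def test_absent_true_positives_give_zero_recall(self):
        cm = np.diag([10, 10, 10, 0])
        cm[3, 0] = 5  # all VeryHigh rows predicted Low
        with pytest.warns(UserWarning):
            report = metrics_from_confusion(cm)
        assert report.recall[3] == 0.0

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((4, 4), dtype=int))

    def test_oracle_equivalence_on_random_predictions(self):
        """Metrics from the confusion matrix equal a brute-force recount
        from raw label pairs, and pooled precision = recall = accuracy."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(20, 200))
            y_true = rng.integers(0, 4, n)
            y_pred = rng.integers(0, 4, n)
            cm = confusion_from_labels(y_true, y_pred)
            import warnings as _w
            with _w.catch_warnings():
                _w.simplefilter("ignore")
                report = metrics_from_confusion(cm)
            acc, prec, rec = _brute_metrics(y_true, y_pred)
            assert report.accuracy == pytest.approx(acc, abs=1e-12)
            assert report.precision == pytest.approx(prec, abs=1e-12)
            assert report.recall == pytest.approx(rec, abs=1e-12)
            assert report.micro_precision == pytest.approx(acc, abs=1e-12)
            assert report.micro_recall == pytest.approx(acc, abs=1e-12)

    def test_f1_between_precision_and_recall(self):
        rng = np.random.default_rng(5)
        cm = rng.integers(1, 40, (4, 4))
        report = metrics_from_confusion(cm)
        for c in range(4):
            lo = min(report.precision[c], report.recall[c])
            hi = max(report.precision[c], report.recall[c])
            assert lo <= report.f1[c] <= hi


@pytest.fixture(scope="module")
def separable_data():
    """Linearly separated 4-class blobs: any sane classifier aces this."""
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(3 * c, 0.3, (60, 5)) for c in range(4)])
    y = np.repeat(np.arange(4), 60)
    return X, y


class TestTrainEval:
    def test_deterministic_under_fixed_seed(self, separable_data):
        X, y = separable_data
        spec = ModelSpec("RF", seed=4)
        part = PartitionSpec(seed=4)
        _, cm1, _ = train_eval(spec, X, y, part)
        _, cm2, _ = train_eval(spec, X, y, part)
        assert np.array_equal(cm1, cm2)

    def test_stratified_holdout_preserves_proportions(self, separable_data):
        X, y = separable_data
        _, cm, _ = train_eval(ModelSpec("DT", seed=0), X, y,
                              PartitionSpec(seed=0))
        per_class_test = cm.sum(axis=1)
        assert np.all(np.abs(per_class_test - 12) <= 1)  # 20% of 60 rows

    def test_kfold_mode_runs_and_averages(self, separable_data):
        X, y = separable_data
        report, cm, _ = train_eval(ModelSpec("DT", seed=0), X, y,
                                   PartitionSpec(mode="kfold", k=5, seed=0))
        assert cm.sum() == len(y)      # every row tested exactly once
        assert 0.9 <= report.accuracy <= 1.0

    def test_single_class_errors(self):
        X = np.zeros((30, 3))
        y = np.zeros(30, dtype=int)
        with pytest.raises(ValueError, match="2 classes"):
            train_eval(ModelSpec("RF"), X, y, PartitionSpec())

    def test_class_smaller_than_fold_count_errors(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 3))
        y = np.array([0] * 20 + [1] * 5)
        with pytest.raises(ValueError, match="fewer rows"):
            train_eval(ModelSpec("DT"), X, y,
                       PartitionSpec(mode="kfold", k=10))

    def test_permuted_labels_score_at_chance(self, separable_data):
        """Permutation null: with labels shuffled, test accuracy lands in
        the 95% binomial interval of the majority-class proportion."""
        X, y = separable_data
        rng = np.random.default_rng(11)
        y_perm = rng.permutation(y)
        report, cm, _ = train_eval(ModelSpec("DT", seed=1), X, y_perm,
                                   PartitionSpec(seed=1))
        n_test = cm.sum()
        p0 = 0.25  # balanced four-class problem
        half_width = 1.96 * np.sqrt(p0 * (1 - p0) / n_test)
        assert abs(report.accuracy - p0) <= half_width + 0.05


class TestCompareModels:
    def test_six_reports_ranked_by_f1(self, separable_data):
        X, y = separable_data
        table, results = compare_models(default_models(seed=0), X, y,
                                        PartitionSpec(seed=0))
        assert len(table) == 6 and len(results) == 6
        assert list(table["f1"]) == sorted(table["f1"], reverse=True)

    def test_rf_configuration_echoed(self, separable_data):
        X, y = separable_data
        table, _ = compare_models([ModelSpec("RF", seed=0)], X, y,
                                  PartitionSpec(seed=0))
        assert "n_estimators=100" in table.iloc[0]["hyperparameters"]

    def test_degenerate_dataset_propagates_error(self):
        X = np.zeros((2, 3))
        y = np.array([0, 1])
        with pytest.raises(ValueError):
            compare_models([ModelSpec("RF")], X, y, PartitionSpec())


class TestRankFeatures:
    def test_normalization_and_cumulative_curve(self, separable_data):
        X, y = separable_data
        _, _, model = train_eval(ModelSpec("RF", seed=0), X, y,
                                 PartitionSpec(seed=0))
        ranking = rank_features(model, names=tuple(f"f{i}" for i in range(5)))
        assert ranking.importances.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ranking.importances) <= 1e-12)
        assert ranking.cumulative[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ranking.cumulative) >= -1e-12)

    def test_non_ensemble_model_rejected(self, separable_data):
        X, y = separable_data
        _, _, model = train_eval(ModelSpec("KNN"), X, y, PartitionSpec(seed=0))
        with pytest.raises(ValueError, match="feature_importances_"):
            rank_features(model, names=("a", "b", "c", "d", "e"))

    def test_null_feature_ranked_below_informative_ones(self):
        """A feature independent of the label ends up ranked last in at
        least 9 of 10 replicates."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = np.repeat(np.arange(4), 50)
            X = np.column_stack([
                y + rng.normal(0, 0.5, 200),
                2 * y + rng.normal(0, 0.5, 200),
                -y + rng.normal(0, 0.5, 200),
                rng.normal(0, 1, 200),      # pure noise
            ])
            _, _, model = train_eval(ModelSpec("RF", seed=seed), X, y,
                                     PartitionSpec(seed=seed))
            ranking = rank_features(model, names=("a", "b", "c", "noise"))
            wins += ranking.order[-1] == 3
        assert wins >= 9


class TestReduceAndAblate:
    def test_full_feature_count_reproduces_full_model(self, separable_data):
        X, y = separable_data
        part = PartitionSpec(seed=2)
        spec = ModelSpec("RF", seed=2)
        report_full, _, model = train_eval(spec, X, y, part)
        ranking = rank_features(model, names=tuple("abcde"))
        table, _ = reduce_and_eval(X, y, ranking, part, spec=spec,
                                   k_list=(5,))
        assert table.iloc[0]["f1"] == pytest.approx(report_full.macro_f1,
                                                    abs=1e-12)
        assert table.iloc[0]["accuracy"] == pytest.approx(report_full.accuracy,
                                                          abs=1e-12)

    def test_k_exceeding_features_errors(self, separable_data):
        X, y = separable_data
        spec = ModelSpec("RF", seed=0)
        _, _, model = train_eval(spec, X, y, PartitionSpec(seed=0))
        ranking = rank_features(model, names=tuple("abcde"))
        with pytest.raises(ValueError, match="exceeds"):
            reduce_and_eval(X, y, ranking, PartitionSpec(seed=0), spec=spec,
                            k_list=(6,))

    def test_single_k_gives_single_row(self, separable_data):
        X, y = separable_data
        spec = ModelSpec("RF", seed=0)
        _, _, model = train_eval(spec, X, y, PartitionSpec(seed=0))
        ranking = rank_features(model, names=tuple("abcde"))
        table, cms = reduce_and_eval(X, y, ranking, PartitionSpec(seed=0),
                                     spec=spec, k_list=(3,))
        assert len(table) == 1 and set(cms) == {3}

    def test_subset_index_sets_match_sensor_map(self):
        assert subset_feature_indices(("foot",)).tolist() == list(range(19))
        assert subset_feature_indices(("l5s1",)).tolist() == list(range(19, 39))
        assert subset_feature_indices(("foot", "l5s1", "emg")).size == 43
        with pytest.raises(ValueError):
            subset_feature_indices(("chest",))

    def test_ablation_table_shape(self):
        rng = np.random.default_rng(0)
        y = np.repeat(np.arange(4), 30)
        X = rng.normal(0, 1, (120, 43)) + y[:, None] * 0.8
        table, cms = sensor_ablation(X, y, PartitionSpec(seed=0),
                                     spec=ModelSpec("DT", seed=0))
        assert list(table["sensors"]) == ["all", "l5s1+foot", "l5s1", "foot"]
        assert list(table["features"]) == [43, 39, 20, 19]


def test_model_spec_round_trip_serialization():
    for spec in default_models(seed=9):
        d = spec.to_dict()
        clone = ModelSpec(d["algorithm"],
                          hyperparameters={k: (tuple(v) if isinstance(v, list)
                                               else v)
                                           for k, v in d["hyperparameters"].items()},
                          seed=d["seed"])
        assert clone.hyperparameters == spec.hyperparameters


def test_unknown_algorithm_rejected():
    with pytest.raises(ValueError, match="unknown algorithm"):
        ModelSpec("XGB")
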