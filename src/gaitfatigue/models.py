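"""Classifier comparison, metrics, feature reduction and sensor ablation.

Six classifier configurations are compared for four-state fatigue
classification, each with fixed hyperparameters (no search): random forest
(100 trees), a three-hidden-layer perceptron (100 units each, tanh, Adam,
L2 1e-4, constant learning rate, up to 1000 iterations), an RBF support
vector machine (C = 64, class-balanced weights), an entropy decision tree
(depth <= 12, min split 11, min leaf 4), 3-nearest-neighbours (Euclidean),
and Newton-CG logistic regression with effectively no regularization
(C = 1e6).  Evaluation uses a stratified 80/20 holdout or 10-fold
cross-validation; because the class distribution is imbalanced, models are
ranked by F1 first and accuracy second.

Metrics come from the 4x4 confusion matrix: accuracy is trace/total, and
per-class one-vs-rest precision, recall and F1 = 2PR/(P+R) are averaged
either macro (mean of per-class values, the headline convention) or
pooled/micro (computed from summed counts; for single-label multiclass
problems pooled precision = pooled recall = accuracy).

Phase 2 ranks features by the random forest's impurity importances and
re-evaluates the model on the top-k features (k in {25, 16, 13, 11, 8})
and on sensor subsets (all sensors; L5-S1 + foot; L5-S1 alone; foot
alone), quantifying the cost of removing hardware — in particular the EMG
electrodes, which are the most invasive part of the setup.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_NAMES, SENSOR_FEATURES
from .labels import FatigueClass

__all__ = [
    "ModelSpec",
    "PartitionSpec",
    "MetricsReport",
    "ImportanceRanking",
    "DEFAULT_MODELS",
    "metrics_from_confusion",
    "confusion_from_labels",
    "train_eval",
    "compare_models",
    "rank_features",
    "reduce_and_eval",
    "sensor_ablation",
]

N_CLASSES = len(FatigueClass)

#: Fixed hyperparameters per algorithm.
_HYPERPARAMETERS: dict[str, dict] = {
    "RF": {"n_estimators": 100},
    "ANN": {"hidden_layer_sizes": (100, 100, 100), "activation": "tanh",
            "solver": "adam", "alpha": 1e-4, "learning_rate": "constant",
            "max_iter": 1000},
    "SVM": {"kernel": "rbf", "C": 64, "class_weight": "balanced"},
    "DT": {"criterion": "entropy", "max_depth": 12, "min_samples_split": 11,
           "min_samples_leaf": 4},
    "KNN": {"n_neighbors": 3, "metric": "euclidean"},
    "LR": {"solver": "newton-cg", "C": 1_000_000, "max_iter": 500},
}


@dataclass
class ModelSpec:
    """One classifier configuration (algorithm + fixed hyperparameters)."""

    algorithm: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in _HYPERPARAMETERS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                             f"choose from {sorted(_HYPERPARAMETERS)}")
        merged = dict(_HYPERPARAMETERS[self.algorithm])
        merged.update(self.hyperparameters)
        self.hyperparameters = merged

    def build(self):
        """Instantiate the scikit-learn estimator for this spec."""
        hp = self.hyperparameters
        if self.algorithm == "RF":
            return RandomForestClassifier(random_state=self.seed, **hp)
        if self.algorithm == "ANN":
            return MLPClassifier(random_state=self.seed, **hp)
        if self.algorithm == "SVM":
            return SVC(random_state=self.seed, **hp)
        if self.algorithm == "DT":
            return DecisionTreeClassifier(random_state=self.seed, **hp)
        if self.algorithm == "KNN":
            return KNeighborsClassifier(**hp)
        if self.algorithm == "LR":
            return LogisticRegression(**hp)
        raise AssertionError("unreachable")  # pragma: no cover

    def to_dict(self) -> dict:
        hp = {k: (list(v) if isinstance(v, tuple) else v)
              for k, v in self.hyperparameters.items()}
        return {"algorithm": self.algorithm, "hyperparameters": hp,
                "seed": self.seed}


def default_models(seed: int = 0) -> list[ModelSpec]:
    return [ModelSpec(alg, seed=seed) for alg in _HYPERPARAMETERS]


DEFAULT_MODELS = tuple(_HYPERPARAMETERS)


@dataclass
class PartitionSpec:
    """Holdout or k-fold evaluation protocol."""

    mode: str = "holdout"        # "holdout" or "kfold"
    test_fraction: float = 0.20
    k: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("holdout", "kfold"):
            raise ValueError("mode must be 'holdout' or 'kfold'")
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class MetricsReport:
    """Accuracy and per-class / averaged precision, recall and F1."""

    accuracy: float
    precision: np.ndarray        # per class, one-vs-rest
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    micro_precision: float
    micro_recall: float
    micro_f1: float
    averaging: str = "macro"     # headline convention
    n: int = 0                   # rows evaluated

    @property
    def headline_f1(self) -> float:
        return self.macro_f1 if self.averaging == "macro" else self.micro_f1

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": list(map(float, self.precision)),
            "recall": list(map(float, self.recall)),
            "f1": list(map(float, self.f1)),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "micro_precision": self.micro_precision,
            "micro_recall": self.micro_recall,
            "micro_f1": self.micro_f1,
            "averaging": self.averaging,
            "n": self.n,
        }


def confusion_from_labels(y_true: np.ndarray, y_pred: np.ndarray,
                          n_classes: int = N_CLASSES) -> np.ndarray:
    """4x4 confusion matrix; rows are true classes, columns predictions."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def _safe_div(num: float, den: float, what: str, cls: int) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined for class {cls} (zero denominator); "
                      "reporting 0", stacklevel=3)
        return 0.0
    return num / den


def metrics_from_confusion(cm: np.ndarray, averaging: str = "macro"
                           ) -> MetricsReport:
    """Compute accuracy, precision, recall and F1 from a confusion matrix.

    Per class (one-vs-rest): precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2PR/(P+R).  Accuracy is trace/total.  ``averaging`` selects the
    headline convention; both macro and pooled (micro) values are always
    computed.
    """
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValueError("confusion matrix counts must be non-negative")
    total = int(cm.sum())
    if total == 0:
        raise ValueError("confusion matrix is all zero")
    if averaging not in ("macro", "pooled", "micro"):
        raise ValueError("averaging must be 'macro' or 'pooled'/'micro'")

    k = cm.shape[0]
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp

    precision = np.array([_safe_div(tp[c], tp[c] + fp[c], "precision", c)
                          for c in range(k)])
    recall = np.array([_safe_div(tp[c], tp[c] + fn[c], "recall", c)
                       for c in range(k)])
    f1 = np.array([
        0.0 if precision[c] + recall[c] == 0
        else 2 * precision[c] * recall[c] / (precision[c] + recall[c])
        for c in range(k)
    ])

    accuracy = float(tp.sum() / total)
    micro_p = float(tp.sum() / (tp.sum() + fp.sum()))
    micro_r = float(tp.sum() / (tp.sum() + fn.sum()))
    micro_f1 = (0.0 if micro_p + micro_r == 0
                else 2 * micro_p * micro_r / (micro_p + micro_r))
    return MetricsReport(
        accuracy=accuracy,
        precision=precision, recall=recall, f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        micro_precision=micro_p, micro_recall=micro_r, micro_f1=float(micro_f1),
        averaging="macro" if averaging == "macro" else "micro",
        n=total,
    )


def _encode_labels(y) -> np.ndarray:
    """Map fatigue-class labels (names or codes) to ordinal codes 0-3."""
    arr = np.asarray(y)
    if arr.dtype.kind in "iu":
        return arr.astype(int)
    name_map = {c.label: int(c) for c in FatigueClass}
    try:
        return np.array([name_map[str(v)] for v in arr], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unknown fatigue class label {exc.args[0]!r}") from exc


def _check_partitionable(y: np.ndarray, partition: PartitionSpec) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to train a classifier")
    if partition.mode == "kfold" and counts.min() < partition.k:
        raise ValueError(
            f"class {classes[np.argmin(counts)]} has fewer rows "
            f"({counts.min()}) than folds ({partition.k})")


def train_eval(spec: ModelSpec, X, y, partition: PartitionSpec
               ) -> tuple[MetricsReport, np.ndarray, object]:
    """Fit one classifier under the partition protocol and evaluate it.

    Holdout: stratified (configurable) 80/20 split by the partition seed,
    fit on train, score on test.  K-fold: metrics averaged across the 10
    folds, confusion matrices summed.  Returns (metrics, confusion
    matrix, fitted estimator); in k-fold mode the estimator is refitted on
    the full data after evaluation.
    """
    X = np.asarray(X, dtype=float)
    y = _encode_labels(y)
    _check_partitionable(y, partition)

    if partition.mode == "holdout":
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=partition.test_fraction,
            random_state=partition.seed,
            stratify=y if partition.stratified else None)
        model = spec.build()
        model.fit(X_tr, y_tr)
        cm = confusion_from_labels(y_te, model.predict(X_te))
        report = metrics_from_confusion(cm)
        return report, cm, model

    splitter = StratifiedKFold(n_splits=partition.k, shuffle=True,
                               random_state=partition.seed)
    fold_reports = []
    cm_total = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    for tr_idx, te_idx in splitter.split(X, y):
        model = spec.build()
        model.fit(X[tr_idx], y[tr_idx])
        cm = confusion_from_labels(y[te_idx], model.predict(X[te_idx]))
        cm_total += cm
        fold_reports.append(metrics_from_confusion(cm))
    mean = {f: float(np.mean([getattr(r, f) for r in fold_reports]))
            for f in ("accuracy", "macro_precision", "macro_recall", "macro_f1",
                      "micro_precision", "micro_recall", "micro_f1")}
    report = MetricsReport(
        accuracy=mean["accuracy"],
        precision=np.mean([r.precision for r in fold_reports], axis=0),
        recall=np.mean([r.recall for r in fold_reports], axis=0),
        f1=np.mean([r.f1 for r in fold_reports], axis=0),
        macro_precision=mean["macro_precision"],
        macro_recall=mean["macro_recall"],
        macro_f1=mean["macro_f1"],
        micro_precision=mean["micro_precision"],
        micro_recall=mean["micro_recall"],
        micro_f1=mean["micro_f1"],
        n=int(cm_total.sum()),
    )
    model = spec.build()
    model.fit(X, y)
    return report, cm_total, model


def compare_models(specs: list[ModelSpec], X, y, partition: PartitionSpec
                   ) -> tuple[pd.DataFrame, dict[str, tuple[MetricsReport, np.ndarray, object]]]:
    """Evaluate several classifiers and rank them by F1, then accuracy."""
    results: dict[str, tuple[MetricsReport, np.ndarray, object]] = {}
    rows = []
    for spec in specs:
        report, cm, model = train_eval(spec, X, y, partition)
        results[spec.algorithm] = (report, cm, model)
        rows.append({
            "model": spec.algorithm,
            "hyperparameters": "; ".join(f"{k}={v}" for k, v in
                                         spec.hyperparameters.items()),
            "accuracy": report.accuracy,
            "precision": report.macro_precision,
            "recall": report.macro_recall,
            "f1": report.macro_f1,
        })
    table = pd.DataFrame(rows).sort_values(["f1", "accuracy"],
                                           ascending=False, kind="mergesort")
    return table.reset_index(drop=True), results


@dataclass
class ImportanceRanking:
    """Features ordered by impurity importance, with the cumulative curve."""

    order: np.ndarray            # feature indices, most important first
    importances: np.ndarray      # sorted descending, sums to 1
    names: tuple[str, ...]

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.importances)


def rank_features(model, names: tuple[str, ...] = FEATURE_NAMES
                  ) -> ImportanceRanking:
    """Importance ranking from a fitted tree ensemble.

    Importances are normalized to sum to 1 and sorted descending; the
    cumulative curve supports choosing a feature budget.
    """
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        raise ValueError("model does not expose feature_importances_; "
                         "fit a tree ensemble (e.g. the RF spec) first")
    imp = np.asarray(imp, dtype=float)
    if imp.sum() <= 0:
        raise ValueError("all feature importances are zero")
    imp = imp / imp.sum()
    order = np.argsort(-imp, kind="stable")
    return ImportanceRanking(order=order, importances=imp[order],
                             names=tuple(names[i] for i in order))


def reduce_and_eval(X, y, ranking: ImportanceRanking, partition: PartitionSpec,
                    spec: ModelSpec | None = None,
                    k_list: tuple[int, ...] = (25, 16, 13, 11, 8),
                    estimators_per_k: dict[int, int] | None = None,
                    ) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Re-evaluate the classifier on the top-k ranked features.

    Columns are selected in their original index order so that k equal to
    the full feature count reproduces the full model exactly.
    ``estimators_per_k`` optionally overrides the tree count per grid row.
    """
    X = np.asarray(X, dtype=float)
    n_feat = X.shape[1]
    spec = spec or ModelSpec("RF", seed=partition.seed)
    rows = []
    confusions: dict[int, np.ndarray] = {}
    for k in k_list:
        if k > n_feat:
            raise ValueError(f"k={k} exceeds available features ({n_feat})")
        cols = np.sort(ranking.order[:k])
        row_spec = spec
        if estimators_per_k and k in estimators_per_k:
            hp = dict(spec.hyperparameters)
            hp["n_estimators"] = estimators_per_k[k]
            row_spec = ModelSpec(spec.algorithm, hyperparameters=hp,
                                 seed=spec.seed)
        report, cm, _ = train_eval(row_spec, X[:, cols], y, partition)
        confusions[k] = cm
        rows.append({
            "features": k,
            "estimators": row_spec.hyperparameters.get("n_estimators"),
            "accuracy": report.accuracy,
            "precision": report.macro_precision,
            "recall": report.macro_recall,
            "f1": report.macro_f1,
        })
    return pd.DataFrame(rows), confusions


DEFAULT_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": ("foot", "l5s1", "emg"),
    "l5s1+foot": ("foot", "l5s1"),
    "l5s1": ("l5s1",),
    "foot": ("foot",),
}


def subset_feature_indices(sites: tuple[str, ...]) -> np.ndarray:
    idx: list[int] = []
    for site in sites:
        if site not in SENSOR_FEATURES:
            raise ValueError(f"unknown sensor subset element {site!r}")
        idx.extend(SENSOR_FEATURES[site])
    if not idx:
        raise ValueError("sensor subset induces an empty feature set")
    return np.array(sorted(idx), dtype=int)


def sensor_ablation(X, y, partition: PartitionSpec,
                    spec: ModelSpec | None = None,
                    subsets: dict[str, tuple[str, ...]] | None = None,
                    ) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Retrain and evaluate on per-sensor feature subsets.

    EMG features are part of the "all" subset only: every reduced subset
    drops them, reflecting that EMG electrodes are the first hardware to
    remove in practice.
    """
    X = np.asarray(X, dtype=float)
    spec = spec or ModelSpec("RF", seed=partition.seed)
    subsets = subsets or DEFAULT_SUBSETS
    rows = []
    confusions: dict[str, np.ndarray] = {}
    for name, sites in subsets.items():
        cols = subset_feature_indices(tuple(sites))
        report, cm, _ = train_eval(spec, X[:, cols], y, partition)
        confusions[name] = cm
        rows.append({
            "sensors": name,
            "features": cols.size,
            "accuracy": report.accuracy,
            "precision": report.macro_precision,
            "recall": report.macro_recall,
            "f1": report.macro_f1,
        })
    return pd.DataFrame(rows), confusions
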