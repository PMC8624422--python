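"""Classical classifiers under stratified 10-fold cross-validation.

Feature columns are z-scored inside each fold using training-fold statistics
only, so no test information leaks into standardisation.  Metrics are
reported both pooled over folds (one confusion matrix of all test windows)
and per fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .metrics import ConfusionMatrix, MetricsReport, metrics_from_confusion
from .pipeline import FeatureTable

__all__ = ["CVConfig", "kfold_split", "make_model", "train_classical",
           "CLASSICAL_MODELS"]

CLASSICAL_MODELS = ("svm_linear", "svm_rbf", "svm_poly", "knn3", "knn5")


@dataclass(frozen=True)
class CVConfig:
    k: int = 10
    seed: int = 0
    stratified: bool = True
    group_by_segment: bool = False

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


def kfold_split(labels: np.ndarray, cv: CVConfig,
                groups: np.ndarray | None = None):
    """Deterministic stratified folds as (train_indices, test_indices) pairs."""
    labels = np.asarray(labels)
    if labels.size < cv.k:
        raise ValueError("fewer rows than folds")
    _, counts = np.unique(labels, return_counts=True)
    if cv.stratified and counts.min() < cv.k:
        raise ValueError(
            f"smallest class has {counts.min()} members; use k <= {counts.min()}")
    if cv.group_by_segment:
        if groups is None:
            raise ValueError("group_by_segment requires group ids")
        splitter = StratifiedGroupKFold(n_splits=cv.k, shuffle=True,
                                        random_state=cv.seed)
        return list(splitter.split(np.zeros(labels.size), labels, groups))
    splitter = StratifiedKFold(n_splits=cv.k, shuffle=True,
                               random_state=cv.seed)
    return list(splitter.split(np.zeros(labels.size), labels))


def make_model(name: str):
    """SVM (linear/RBF/polynomial kernel) or KNN (k = 3 or 5), z-scored."""
    if name == "svm_linear":
        clf = SVC(kernel="linear")
    elif name == "svm_rbf":
        clf = SVC(kernel="rbf")
    elif name == "svm_poly":
        clf = SVC(kernel="poly", degree=3)
    elif name == "knn3":
        clf = KNeighborsClassifier(n_neighbors=3)
    elif name == "knn5":
        clf = KNeighborsClassifier(n_neighbors=5)
    else:
        raise ValueError(f"unknown model {name!r}; choose from {CLASSICAL_MODELS}")
    return make_pipeline(StandardScaler(), clf)


def _segment_groups(table: FeatureTable) -> np.ndarray:
    # window_id pattern "<segment>[w<i>]"
    return np.array([wid.split("[")[0] for wid in table.frame["window_id"]])


def train_classical(table: FeatureTable, model: str = "svm_rbf",
                    cv: CVConfig = CVConfig()) -> MetricsReport:
    """Per-fold fit and evaluation; pooled confusion matrix -> metrics."""
    X, y = table.X, table.y
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    groups = _segment_groups(table) if cv.group_by_segment else None
    pooled = None
    per_fold = []
    for train_idx, test_idx in kfold_split(y, cv, groups):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError("degenerate single-class training fold")
        clf = make_model(model)
        clf.fit(X[train_idx], y[train_idx])
        pred = clf.predict(X[test_idx])
        cm = ConfusionMatrix.from_labels(y[test_idx], pred, classes=classes)
        pooled = cm if pooled is None else pooled + cm
        fold_vals = metrics_from_confusion(cm)
        per_fold.append({"acc": fold_vals.acc, "sens": fold_vals.sens,
                         "spec": fold_vals.spec, "prec": fold_vals.prec,
                         "f1": fold_vals.f1})
    report = metrics_from_confusion(pooled)
    report.per_fold = per_fold
    return report
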