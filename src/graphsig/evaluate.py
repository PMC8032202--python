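"""Cross-validated classification on embeddings.

Two protocols: leave-one-subject-out (LOSO), where all of a subject's
points are held out together and the subject's prediction averages its
per-point predictions, and stratified k-fold over points.  The classifier
is pluggable (RBF SVM by default, random forest as the alternative); the
evaluation contract does not depend on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "LabeledEmbedding",
    "ClassifierConfig",
    "EvaluationReport",
    "loso_cv",
    "kfold_cv",
    "chance_level",
]


@dataclass
class LabeledEmbedding:
    """Embedding coordinates with per-point labels and subject ids."""

    coordinates: np.ndarray
    labels: np.ndarray
    group_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.coordinates.ndim != 2:
            raise ValueError("coordinates must be 2-D")
        if len(self.labels) != len(self.coordinates):
            raise ValueError("labels length does not match coordinates")
        if self.group_ids is not None:
            self.group_ids = np.asarray(self.group_ids)
            if len(self.group_ids) != len(self.coordinates):
                raise ValueError("group_ids length does not match coordinates")


@dataclass
class ClassifierConfig:
    """Classifier kind and hyperparameters."""

    kind: str = "svm-rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    n_estimators: int = 200
    seed: int = 0
    score_mode: str = "hard"  # "hard" averages labels, "decision" averages scores

    def build(self):
        if self.kind == "svm-rbf":
            return SVC(C=self.C, gamma=self.gamma, kernel="rbf",
                       random_state=self.seed)
        if self.kind == "random-forest":
            return RandomForestClassifier(n_estimators=self.n_estimators,
                                          random_state=self.seed)
        raise ValueError("classifier kind must be 'svm-rbf' or 'random-forest'")


@dataclass
class EvaluationReport:
    """Per-point predictions plus aggregated metrics."""

    point_predictions: np.ndarray
    point_labels: np.ndarray
    accuracy: float
    confusion: np.ndarray
    classes: np.ndarray
    auc: float | None = None
    per_class_accuracy: dict | None = None
    subject_ids: np.ndarray | None = None
    subject_scores: np.ndarray | None = None
    subject_predictions: np.ndarray | None = None
    subject_labels: np.ndarray | None = None
    config: ClassifierConfig | None = None


def loso_cv(data: LabeledEmbedding, config: ClassifierConfig | None = None,
            positive_label=None) -> EvaluationReport:
    """Leave-one-subject-out evaluation with per-subject averaging.

    For each subject, a classifier trained on every other subject's points
    predicts the held-out points; the subject score is the mean predicted
    membership of the positive class (hard labels by default) and the
    subject is called positive when the score reaches 0.5.  Metrics
    (confusion matrix, accuracy, AUC over subject scores) are subject-level.
    """
    if data.group_ids is None:
        raise ValueError("LOSO requires group_ids")
    config = config or ClassifierConfig()
    subjects = np.unique(data.group_ids)
    classes = np.unique(data.labels)
    if classes.size != 2:
        raise ValueError("LOSO aggregation is defined for binary labels")
    positive = classes[1] if positive_label is None else positive_label
    negative = classes[classes != positive][0]

    subj_labels, subj_scores = [], []
    point_preds = np.empty_like(data.labels)
    for subject in subjects:
        held = data.group_ids == subject
        train_labels = data.labels[~held]
        if np.unique(train_labels).size < 2:
            raise ValueError(
                f"training fold for held-out subject {subject!r} is single-class"
            )
        clf = config.build().fit(data.coordinates[~held], train_labels)
        label = np.unique(data.labels[held])
        if label.size != 1:
            raise ValueError("labels must be constant within a subject")
        preds = clf.predict(data.coordinates[held])
        point_preds[held] = preds
        if config.score_mode == "decision" and hasattr(clf, "decision_function"):
            raw = clf.decision_function(data.coordinates[held])
            # decision_function is positive toward classes[1]
            score = float(np.mean((raw > 0) if positive == classes[1] else (raw < 0)))
        else:
            score = float(np.mean(preds == positive))
        subj_labels.append(label[0])
        subj_scores.append(score)

    subj_labels = np.asarray(subj_labels)
    subj_scores = np.asarray(subj_scores)
    subj_preds = np.where(subj_scores >= 0.5, positive, negative)  # tie -> positive
    acc = float(np.mean(subj_preds == subj_labels))
    cm = confusion_matrix(subj_labels, subj_preds, labels=classes)
    auc = None
    if np.unique(subj_labels).size == 2:
        auc = float(roc_auc_score(subj_labels == positive, subj_scores))
    return EvaluationReport(
        point_predictions=point_preds, point_labels=data.labels,
        accuracy=acc, confusion=cm, classes=classes, auc=auc,
        subject_ids=subjects, subject_scores=subj_scores,
        subject_predictions=subj_preds, subject_labels=subj_labels,
        config=config,
    )


def kfold_cv(data: LabeledEmbedding, k: int = 10,
             config: ClassifierConfig | None = None,
             seed: int = 0) -> EvaluationReport:
    """Stratified k-fold over points with per-class accuracies."""
    if k < 2:
        raise ValueError("k must be >= 2")
    n = len(data.labels)
    if k > n:
        raise ValueError("k exceeds the number of points")
    config = config or ClassifierConfig()
    _, counts = np.unique(data.labels, return_counts=True)
    if k <= counts.min():
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        # stratification impossible (e.g. leave-one-out); plain shuffled folds
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    preds = np.empty_like(data.labels)
    for train, test in splitter.split(data.coordinates, data.labels):
        clf = config.build().fit(data.coordinates[train], data.labels[train])
        preds[test] = clf.predict(data.coordinates[test])
    classes = np.unique(data.labels)
    cm = confusion_matrix(data.labels, preds, labels=classes)
    per_class = {
        (cls.item() if isinstance(cls, np.generic) else cls):
            float(np.mean(preds[data.labels == cls] == cls))
        for cls in classes
    }
    return EvaluationReport(
        point_predictions=preds, point_labels=data.labels,
        accuracy=float(np.mean(preds == data.labels)), confusion=cm,
        classes=classes, per_class_accuracy=per_class, config=config,
    )


def chance_level(class_counts: Sequence[int], positive_index: int = 0) -> float:
    """Percentage share of the designated class among all subjects."""
    counts = np.asarray(class_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("class counts must be positive")
    total = counts.sum()
    if total == 0:
        raise ZeroDivisionError("total count is zero")
    return float(100.0 * counts[positive_index] / total)
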