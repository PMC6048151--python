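"""Cross-validated two-class classification of plasma miRNA profiles.

A linear maximum-margin classifier (libsvm via scikit-learn's ``SVC``,
kernel="linear", cost C = 1 by default) is evaluated by stratified k-fold
cross-validation: train on k-1 folds, predict the held-out fold, and pool
all held-out predictions into a single confusion matrix — so the matrix
total equals the cohort size and every subject is predicted exactly once.

The positive class is the case label ("OSCC"); derived metrics use the
standard definitions sens = TP/(TP+FN), spec = TN/(TN+FP),
PPV = TP/(TP+FP), NPV = TN/(TN+FN), acc = (TP+TN)/total, reported as
percentages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .errors import ChipDataError, ConfigError
from .preprocess import CohortMatrix

POSITIVE_LABEL = "OSCC"
NEGATIVE_LABEL = "HD"


@dataclass(frozen=True)
class FoldPlan:
    k: int
    assignments: pd.Series  # index subject_id -> fold index


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class ClassifierMetrics:
    """Percent metrics; a NaN marks an undefined (zero-denominator) metric."""

    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float

    def rounded(self) -> dict[str, float]:
        """One-decimal reporting precision, half-up."""
        out = {}
        for k, v in self.__dict__.items():
            out[k] = (
                float(Decimal(repr(v)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
                if np.isfinite(v)
                else float("nan")
            )
        return out

    def to_json(self, path, cm: ConfusionMatrix | None = None) -> None:
        payload = self.rounded()
        if cm is not None:
            payload.update(tp=cm.tp, fp=cm.fp, fn=cm.fn, tn=cm.tn)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


class PlasmaClassifier(BaseEstimator, ClassifierMixin):
    """Linear maximum-margin two-class classifier over standardized ΔCq.

    Thin sklearn estimator around ``SVC(kernel="linear", C=C)``;
    deterministic given its inputs.
    """

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        y = np.asarray(y)
        if len(np.unique(y)) < 2:
            raise ChipDataError("training set holds a single class")
        self.svc_ = SVC(kernel="linear", C=self.C)
        self.svc_.fit(np.asarray(X, dtype=float), y)
        self.classes_ = self.svc_.classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "svc_")
        return self.svc_.predict(np.asarray(X, dtype=float))


def stratified_kfold(labels: pd.Series, k: int, seed: int) -> FoldPlan:
    """Seeded, label-stratified partition; every subject tested once."""
    if k < 2:
        raise ConfigError("k must be >= 2")
    counts = labels.value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ConfigError(f"class(es) {small} smaller than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assign = pd.Series(-1, index=labels.index, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assign.iloc[test_idx] = fold
    return FoldPlan(k=k, assignments=assign)


def train_and_predict(X_train, y_train, X_test, C: float = 1.0) -> np.ndarray:
    """Fit the linear classifier on the training split, label the test rows."""
    return PlasmaClassifier(C=C).fit(X_train, y_train).predict(X_test)


def cross_validate(
    cohort: CohortMatrix, k: int = 10, seed: int = 0, C: float = 1.0
) -> tuple[pd.DataFrame, ConfusionMatrix]:
    """Stratified k-fold CV with pooled held-out predictions.

    Returns ``(predictions, cm)`` where predictions has one row per subject
    (subject_id, true_label, predicted_label, fold) and ``cm`` pools every
    held-out prediction.
    """
    X = cohort.values.to_numpy(dtype=float)
    y = cohort.labels.to_numpy()
    plan = stratified_kfold(cohort.labels, k, seed)
    predicted = pd.Series(index=cohort.labels.index, dtype=object)
    for fold in range(plan.k):
        test_mask = (plan.assignments == fold).to_numpy()
        preds = train_and_predict(X[~test_mask], y[~test_mask], X[test_mask], C=C)
        predicted.iloc[np.where(test_mask)[0]] = preds
    frame = pd.DataFrame(
        {
            "subject_id": cohort.labels.index,
            "true_label": y,
            "predicted_label": predicted.to_numpy(),
            "fold": plan.assignments.to_numpy(),
        }
    )
    cm = confusion_from_predictions(frame["true_label"], frame["predicted_label"])
    return frame, cm


def confusion_from_predictions(true_labels, predicted_labels) -> ConfusionMatrix:
    t = np.asarray(true_labels) == POSITIVE_LABEL
    p = np.asarray(predicted_labels) == POSITIVE_LABEL
    return ConfusionMatrix(
        tp=int(np.sum(t & p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
        tn=int(np.sum(~t & ~p)),
    )


def confusion_metrics(cm: ConfusionMatrix) -> ClassifierMetrics:
    """Derived percent metrics; zero-denominator metrics come back NaN
    (undefined), never fabricated."""

    def ratio(num: int, den: int) -> float:
        return 100.0 * num / den if den > 0 else float("nan")

    return ClassifierMetrics(
        sensitivity=ratio(cm.tp, cm.tp + cm.fn),
        specificity=ratio(cm.tn, cm.tn + cm.fp),
        ppv=ratio(cm.tp, cm.tp + cm.fp),
        npv=ratio(cm.tn, cm.tn + cm.fn),
        accuracy=ratio(cm.tp + cm.tn, cm.total),
    )
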