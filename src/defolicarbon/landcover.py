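"""Supervised land-cover classification and confusion-matrix accuracy.

The classifier is a maximum-margin (support-vector) model behind a small
pluggable interface; accuracy assessment follows the standard confusion-
matrix convention with rows as reference labels and columns as predicted
labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVC


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k label-count matrix; rows = reference, columns = predicted."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("confusion matrix must be square")
        if counts.shape[0] != len(self.labels):
            raise ValueError("label count must match matrix size")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, reference, predicted, labels) -> "ConfusionMatrix":
        labels = tuple(labels)
        index = {lbl: i for i, lbl in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=int)
        for r, p in zip(reference, predicted):
            counts[index[r], index[p]] += 1
        return cls(counts=counts, labels=labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


class SVMClassifier:
    """Default maximum-margin classifier: RBF kernel, unit regularization,
    fixed seed.  Any object with fit/predict can be swapped in."""

    def __init__(self, kernel: str = "rbf", C: float = 1.0, seed: int = 0):
        self._model = SVC(kernel=kernel, C=C, random_state=seed)

    def fit(self, X, y):
        self._model.fit(np.asarray(X, dtype=float), np.asarray(y))
        return self

    def predict(self, X):
        return self._model.predict(np.asarray(X, dtype=float))


def classify(
    features: np.ndarray,
    training_features: np.ndarray,
    training_labels: np.ndarray,
    classes: tuple[str, ...],
    model=None,
) -> np.ndarray:
    """Label every pixel from per-pixel features and training samples.

    ``features`` may be (n_pixels, n_features) or (rows, cols, n_features);
    the output matches the leading shape.  Every class in ``classes`` must
    appear in the training labels.
    """
    training_labels = np.asarray(training_labels)
    missing = set(classes) - set(np.unique(training_labels).tolist())
    if missing:
        raise ValueError(f"classes absent from training data: {sorted(missing)}")
    if model is None:
        model = SVMClassifier()
    model.fit(np.asarray(training_features, dtype=float), training_labels)
    features = np.asarray(features, dtype=float)
    lead_shape = features.shape[:-1]
    pred = model.predict(features.reshape(-1, features.shape[-1]))
    return np.asarray(pred).reshape(lead_shape)


def accuracy_metrics(cm: ConfusionMatrix) -> dict:
    """Overall, per-class producer and per-class user accuracies, percent.

    overall = 100 trace/total; producer(c) = 100 diag(c)/column-total(c);
    user(c) = 100 diag(c)/row-total(c).  Classes with a zero denominator
    report NaN.
    """
    counts = np.asarray(cm.counts, dtype=float)
    total = counts.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    diag = np.diag(counts)
    col_tot = counts.sum(axis=0)
    row_tot = counts.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        producer = np.where(col_tot > 0, 100.0 * diag / np.where(col_tot > 0, col_tot, 1), np.nan)
        user = np.where(row_tot > 0, 100.0 * diag / np.where(row_tot > 0, row_tot, 1), np.nan)
    return {
        "overall": float(100.0 * diag.sum() / total),
        "producer": dict(zip(cm.labels, producer.tolist())),
        "user": dict(zip(cm.labels, user.tolist())),
    }
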