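"""Leave-one-subject-out evaluation, accuracy reporting and confusion counts.

Every model in this package is scored subject-independently: each fold trains
on all subjects but one and tests on every window of the held-out subject.
The headline number is the unweighted mean +/- SD of per-subject accuracies;
the pooled accuracy (trace of the cumulative confusion matrix over its total)
is reported alongside and equals the window-weighted mean of the per-subject
accuracies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .synth import WindowSet

__all__ = [
    "loso_folds",
    "loso_folds_from_arrays",
    "confusion_counts",
    "EvalReport",
    "evaluate",
]


def loso_folds_from_arrays(groups: np.ndarray
                           ) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(test_subject, train_mask, test_mask) per subject, ordered by id."""
    groups = np.asarray(groups)
    subjects = sorted(set(groups.tolist()))
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for LOSO")
    folds = []
    for s in subjects:
        test = groups == s
        folds.append((s, ~test, test))
    return folds


def loso_folds(windowset: WindowSet) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """Leave-one-subject-out folds over a window set (masks in window order)."""
    return loso_folds_from_arrays(windowset.subject_ids())


def confusion_counts(true_labels: Sequence, predicted: Sequence,
                     classes: Sequence[str]) -> np.ndarray:
    """2x2 counts indexed (true, predicted) in the order of ``classes``."""
    true_labels = np.asarray(true_labels)
    predicted = np.asarray(predicted)
    if true_labels.shape != predicted.shape:
        raise ValueError("label vectors differ in length")
    k = len(classes)
    counts = np.zeros((k, k), dtype=int)
    index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true_labels, predicted):
        counts[index[t], index[p]] += 1
    return counts


@dataclass
class EvalReport:
    """Cross-validation outcome: per-subject accuracies and pooled counts."""

    subjects: list[str]
    per_subject_accuracy: list[float]
    confusion: np.ndarray  # (true, predicted), cumulative over folds
    classes: tuple[str, str]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_subject_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.per_subject_accuracy))

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion) / self.confusion.sum())

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "subjects": self.subjects,
            "per_subject_accuracy": self.per_subject_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "pooled_accuracy": self.pooled_accuracy,
            "confusion": self.confusion.tolist(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def confusion_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.confusion,
                            index=[f"true_{c}" for c in self.classes],
                            columns=[f"pred_{c}" for c in self.classes])


FitPredict = Callable[[np.ndarray, np.ndarray], np.ndarray]
"""A procedure mapping (train_mask, test_mask) to predicted labels for the
test rows; closures capture the data so the harness stays model-agnostic."""


def evaluate(procedure: FitPredict, labels: np.ndarray, groups: np.ndarray,
             negative: str, positive: str) -> EvalReport:
    """Run a fit-and-predict procedure in LOSO CV and aggregate accuracies.

    ``procedure(train_mask, test_mask)`` must return predicted labels for the
    masked test rows. Every training fold must contain both classes.
    """
    labels = np.asarray(labels)
    folds = loso_folds_from_arrays(np.asarray(groups))
    classes = (negative, positive)
    subjects, accs = [], []
    confusion = np.zeros((2, 2), dtype=int)
    for subject, train_mask, test_mask in folds:
        train_labels = set(labels[train_mask])
        if not {negative, positive} <= train_labels:
            raise ValueError(
                f"training fold for held-out subject {subject!r} lacks a class")
        pred = np.asarray(procedure(train_mask, test_mask))
        truth = labels[test_mask]
        subjects.append(subject)
        accs.append(float((pred == truth).mean()))
        confusion += confusion_counts(truth, pred, classes)
    return EvalReport(subjects=subjects, per_subject_accuracy=accs,
                      confusion=confusion, classes=classes)
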