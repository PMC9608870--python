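"""Leave-one-subject-out evaluation: folds, balancing, splits, metrics.

Subject leakage is prevented by folding at the subject level: every fold
trains on all subjects but one and tests on the held-out subject's trials.
Class imbalance in the training side is removed by subsampling the majority
class (without replacement, seeded) to the minority count, and 1/11 of the
balanced training trials are held out, stratified by class, as the early
stopping validation set.  Predicted probability >= 0.5 means "patient".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

__all__ = [
    "FoldResult",
    "RocCurve",
    "loocv_folds",
    "balance_classes",
    "split_validation",
    "evaluate_fold",
    "roc_auc",
]


@dataclass
class FoldResult:
    """Held-out predictions and confusion counts for one LOOCV fold."""

    subject_id: int
    probabilities: np.ndarray
    labels: np.ndarray  # 1 = patient, 0 = control
    trial_index: np.ndarray  # indices into the full trial set

    @property
    def predictions(self) -> np.ndarray:
        return (self.probabilities >= 0.5).astype(int)

    @property
    def confusion(self) -> dict[str, int]:
        pred, y = self.predictions, self.labels
        return {
            "TP": int(np.sum((pred == 1) & (y == 1))),
            "FP": int(np.sum((pred == 1) & (y == 0))),
            "TN": int(np.sum((pred == 0) & (y == 0))),
            "FN": int(np.sum((pred == 0) & (y == 1))),
        }

    @property
    def accuracy(self) -> float:
        c = self.confusion
        return (c["TP"] + c["TN"]) / len(self.labels)


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def loocv_folds(trial_table: pd.DataFrame) -> list[tuple[np.ndarray, int]]:
    """One (train_subjects, test_subject) pair per subject with >= 1 trial.

    ``trial_table`` needs columns ``subject_id`` and ``group``.  Subjects
    listed in the table with zero trials (possible after QC filtering of a
    categorical table) are excluded with a warning.
    """
    counts = trial_table.groupby("subject_id", observed=False).size()
    empty = counts[counts == 0].index.to_list()
    if empty:
        warnings.warn(f"excluding subjects with no trials: {empty}")
    subjects = np.array(sorted(counts[counts > 0].index))
    if len(subjects) < 2:
        raise ValueError("need at least two subjects for LOOCV")
    return [(subjects[subjects != s], int(s)) for s in subjects]


def balance_classes(groups: np.ndarray, seed: int) -> np.ndarray:
    """Indices of a class-balanced subset of the training trials.

    The majority class is subsampled without replacement (seeded) down to
    the minority count; the minority class is kept in full.  Returned
    indices are sorted.
    """
    groups = np.asarray(groups)
    classes, counts = np.unique(groups, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present to balance")
    n_min = counts.min()
    rng = np.random.default_rng(seed)
    keep = []
    for cls, cnt in zip(classes, counts):
        idx = np.flatnonzero(groups == cls)
        if cnt > n_min:
            idx = rng.choice(idx, size=n_min, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def split_validation(
    labels: np.ndarray, fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified trial-level (train, validation) index split.

    |validation| = round(fraction * N), apportioned over classes by largest
    remainder so the validation class ratio tracks the input ratio.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels)
    n = len(labels)
    n_val = int(np.floor(fraction * n + 0.5))
    if n_val == 0 or n_val == n:
        raise ValueError("validation split would leave an empty set")

    classes = np.unique(labels)
    quotas = {}
    exact = {c: fraction * np.sum(labels == c) for c in classes}
    for c in classes:
        quotas[c] = int(np.floor(exact[c]))
    remainder_order = sorted(classes, key=lambda c: exact[c] - quotas[c], reverse=True)
    i = 0
    while sum(quotas.values()) < n_val:
        quotas[remainder_order[i % len(classes)]] += 1
        i += 1
    while sum(quotas.values()) > n_val:
        quotas[remainder_order[-(1 + i % len(classes))]] -= 1
        i += 1

    rng = np.random.default_rng(seed)
    val = []
    for c in classes:
        idx = rng.permutation(np.flatnonzero(labels == c))
        val.append(idx[: quotas[c]])
    val_idx = np.sort(np.concatenate(val))
    train_idx = np.setdiff1d(np.arange(n), val_idx)
    if len(train_idx) == 0:
        raise ValueError("validation split would leave an empty training set")
    return train_idx, val_idx


def evaluate_fold(
    model,
    test_images: np.ndarray,
    test_labels: np.ndarray,
    subject_id: int,
    trial_index: np.ndarray | None = None,
    batch: int = 256,
) -> FoldResult:
    """Predict the held-out subject's trials and tabulate the confusion."""
    test_labels = np.asarray(test_labels).astype(int)
    probs = np.concatenate(
        [model.forward(test_images[i : i + batch]) for i in range(0, len(test_images), batch)]
    )
    if trial_index is None:
        trial_index = np.arange(len(test_labels))
    return FoldResult(
        subject_id=int(subject_id),
        probabilities=probs,
        labels=test_labels,
        trial_index=np.asarray(trial_index),
    )


def roc_auc(probabilities: np.ndarray, labels: np.ndarray) -> RocCurve:
    """ROC curve by threshold sweep and AUC by the rank (Mann-Whitney)
    formulation, which handles tied scores as half-concordant."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("ROC requires both classes")
    fpr, tpr, thr = roc_curve(labels, probabilities)
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=float(roc_auc_score(labels, probabilities)))


def fold_summary(folds: list[FoldResult]) -> pd.DataFrame:
    """Per-subject table: trials, accuracy, confusion counts."""
    rows = []
    for f in folds:
        c = f.confusion
        rows.append(
            {"subject_id": f.subject_id, "n_trials": len(f.labels), "accuracy": f.accuracy, **c}
        )
    return pd.DataFrame(rows)
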