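"""Evaluation metrics implemented from first principles.

Accuracy = (TP + TN) / (TP + TN + FP + FN); precision = TP / (TP + FP);
recall = TP / (TP + FN); F1 = 2PR / (P + R); the ROC curve plots the true
positive rate against the false positive rate over a descending threshold
sweep, and its trapezoidal area equals the tie-adjusted Mann-Whitney
pairwise ranking probability.  Zero-denominator cases return 0 with a
warning.  Scikit-learn is used only as an independent cross-check in the
test suite, never here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ROCCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def _check_lengths(y_true, y_pred) -> None:
    if len(y_true) == 0:
        raise ValueError("empty input")
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred have different lengths")


def binary_counts(y_true: Sequence, y_pred: Sequence, positive_label) -> ConfusionCounts:
    _check_lengths(y_true, y_pred)
    labels = set(y_true)
    if positive_label not in labels and positive_label not in set(y_pred):
        raise ValueError(f"positive_label {positive_label!r} not observed")
    tp = tn = fp = fn = 0
    for t, p in zip(y_true, y_pred):
        if t == positive_label:
            tp += p == positive_label
            fn += p != positive_label
        else:
            fp += p == positive_label
            tn += p != positive_label
    return ConfusionCounts(tp, tn, fp, fn)


def accuracy(y_true: Sequence, y_pred: Sequence) -> float:
    """Fraction of exact label matches (binary or multiclass)."""
    _check_lengths(y_true, y_pred)
    return float(np.mean([t == p for t, p in zip(y_true, y_pred)]))


def _safe_ratio(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what} undefined (zero denominator); returning 0")
        return 0.0
    return num / den


def precision_recall(y_true, y_pred, positive_label) -> tuple[float, float]:
    c = binary_counts(y_true, y_pred, positive_label)
    p = _safe_ratio(c.TP, c.TP + c.FP, "precision")
    r = _safe_ratio(c.TP, c.TP + c.FN, "recall")
    return p, r


def f1_score(
    y_true: Sequence,
    y_pred: Sequence,
    positive_label=None,
    average: str = "binary",
) -> float:
    """Harmonic mean of precision and recall; macro = unweighted per-class mean."""
    _check_lengths(y_true, y_pred)
    if average == "binary":
        if positive_label is None:
            raise ValueError("binary F1 requires positive_label")
        p, r = precision_recall(y_true, y_pred, positive_label)
        return _safe_ratio(2 * p * r, p + r, "F1")
    if average == "macro":
        labels = sorted(set(y_true))
        scores = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for lab in labels:
                p, r = precision_recall(y_true, y_pred, lab)
                scores.append(0.0 if p + r == 0 else 2 * p * r / (p + r))
        return float(np.mean(scores))
    raise ValueError(f"unknown average {average!r}")


def roc_auc(y_true_binary: Sequence, scores: Sequence[float]) -> ROCCurve:
    """ROC curve from a descending threshold sweep and its trapezoidal AUC.

    Ties in ``scores`` are handled by placing one threshold per unique score,
    which makes the trapezoidal area equal the Mann-Whitney pairwise
    probability P(score_pos > score_neg) + 0.5 P(tie) exactly.
    """
    y = np.asarray(y_true_binary).astype(bool)
    s = np.asarray(scores, dtype=float)
    if y.size != s.size or y.size == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    # cumulative counts at each unique-score block boundary
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), y.size - 1]
    tps = np.cumsum(y_sorted)[distinct]
    fps = np.cumsum(~y_sorted)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def confusion_matrix(
    y_true: Sequence,
    y_pred: Sequence,
    labels: Sequence,
    normalize: bool = False,
) -> np.ndarray:
    """Entry (i, j) counts true label i predicted as j; optionally row-normalized."""
    _check_lengths(y_true, y_pred)
    index = {lab: i for i, lab in enumerate(labels)}
    observed = set(y_true) | set(y_pred)
    unknown = observed - set(labels)
    if unknown:
        raise ValueError(f"labels outside the provided set: {sorted(unknown)[:5]}")
    m = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(y_true, y_pred):
        m[index[t], index[p]] += 1
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = m / m.sum(axis=1, keepdims=True)
        return np.nan_to_num(frac)
    return m


def cross_entropy(z: Sequence[float], q: Sequence[float]) -> float:
    """The classification loss -sum_i z_i log q_i for one cell's one-hot
    target ``z`` and predicted class distribution ``q``."""
    z = np.asarray(z, dtype=float)
    q = np.asarray(q, dtype=float)
    if z.shape != q.shape:
        raise ValueError("z and q must have the same shape")
    with np.errstate(divide="ignore"):
        logq = np.where(z > 0, np.log(np.where(z > 0, q, 1.0)), 0.0)
    return float(-(z * logq).sum())
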