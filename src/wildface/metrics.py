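"""Evaluation metrics: accuracy, F1, confusion matrix, ROC-AUC.

AUC is computed in the Mann-Whitney rank form (ties averaged): per class
one-vs-rest, plus a micro-average obtained by pooling every (sample, class)
score with its binary indicator.  F1 defaults to the macro average over
classes present in the truth (robust under class imbalance); micro-F1 is
carried alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata


def _binary_auc(scores: np.ndarray, positives: np.ndarray) -> float:
    """Mann-Whitney AUC of `scores` against a boolean positive mask."""
    n_pos = int(positives.sum())
    n_neg = positives.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(scores)  # average ranks for ties
    rank_sum = ranks[positives].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def roc_auc(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-class one-vs-rest AUCs and the pooled micro-average AUC.

    ``scores`` is (N, K) per-class; ``truth`` integer labels.  Classes absent
    from the truth get NaN per-class AUC and are excluded from pooling only
    through their indicator column being all-zero (they still contribute
    negatives to the micro pool, as in the standard micro-average).
    """
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth)
    n, k = scores.shape
    per_class = np.array([_binary_auc(scores[:, c], truth == c) for c in range(k)])
    onehot = np.zeros((n, k), dtype=bool)
    onehot[np.arange(n), truth] = True
    micro = _binary_auc(scores.ravel(), onehot.ravel())
    return per_class, micro


@dataclass
class Metrics:
    accuracy: float
    f1: float  # macro average
    micro_f1: float
    confusion: np.ndarray  # (K, K) counts, rows = truth
    per_class_auc: np.ndarray
    micro_auc: float
    per_class_accuracy: np.ndarray

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "micro_f1": self.micro_f1,
            "micro_auc": self.micro_auc,
            "per_class_auc": [None if np.isnan(a) else float(a) for a in self.per_class_auc],
            "per_class_accuracy": [float(a) for a in self.per_class_accuracy],
            "confusion": self.confusion.tolist(),
        }


def compute_metrics(scores: np.ndarray, truth: np.ndarray, n_classes: int) -> Metrics:
    """All evaluation metrics from per-class scores and integer truth."""
    scores = np.asarray(scores, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.intp)
    preds = scores.argmax(axis=1)
    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (truth, preds), 1)
    accuracy = float(np.trace(confusion) / max(confusion.sum(), 1))

    row = confusion.sum(axis=1)  # per-class true counts
    col = confusion.sum(axis=0)  # per-class predicted counts
    diag = np.diag(confusion).astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / col, 0.0)
        recall = np.where(row > 0, diag / row, 0.0)
        f1_c = np.where(precision + recall > 0, 2 * precision * recall / (precision + recall), 0.0)
        per_class_accuracy = np.where(row > 0, diag / row, np.nan)
    present = row > 0
    macro_f1 = float(f1_c[present].mean()) if present.any() else 0.0
    micro_f1 = accuracy  # single-label multiclass: micro-F1 == accuracy

    per_class_auc, micro_auc = roc_auc(scores, truth)
    return Metrics(
        accuracy=accuracy,
        f1=macro_f1,
        micro_f1=micro_f1,
        confusion=confusion,
        per_class_auc=per_class_auc,
        micro_auc=micro_auc,
        per_class_accuracy=per_class_accuracy,
    )
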