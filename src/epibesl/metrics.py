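"""Evaluation metrics: AUROC, AUPR, MCC, F1, per-fold aggregation.

Accuracy is deliberately not reported: at 1:20 imbalance the all-negative
classifier scores ~95% accuracy while being useless, so the harness sticks
to ranking metrics (AUROC, AUPR) and imbalance-aware thresholded metrics
(MCC, F1).  Pooled metrics are computed on the concatenated out-of-fold
predictions; mean-over-folds is reported alongside because figures in the
literature use either convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import (average_precision_score, f1_score,
                             matthews_corrcoef, roc_auc_score)

from .errors import UndefinedMetricError, ValidationError


def _check(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have matching shapes")
    return scores, labels


def auroc(scores, labels) -> float:
    """Area under the ROC curve (= probability a random positive outranks a
    random negative, ties counting one half)."""
    scores, labels = _check(scores, labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUROC undefined with a single class")
    return float(roc_auc_score(labels, scores))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve, step-wise (non-interpolated)."""
    scores, labels = _check(scores, labels)
    if (labels == 1).sum() == 0:
        raise UndefinedMetricError("AUPR undefined without positives")
    return float(average_precision_score(labels, scores))


def confusion_counts(scores, labels, threshold: float = 0.5) -> dict[str, int]:
    scores, labels = _check(scores, labels)
    pred = (scores >= threshold).astype(int)
    return {
        "tp": int(((pred == 1) & (labels == 1)).sum()),
        "fp": int(((pred == 1) & (labels == 0)).sum()),
        "fn": int(((pred == 0) & (labels == 1)).sum()),
        "tn": int(((pred == 0) & (labels == 0)).sum()),
    }


def mcc(scores, labels, threshold: float = 0.5) -> float:
    """Matthews correlation coefficient at ``threshold``; 0 when the
    denominator vanishes (the standard convention)."""
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0,1)")
    scores, labels = _check(scores, labels)
    return float(matthews_corrcoef(labels, (scores >= threshold).astype(int)))


def f1(scores, labels, threshold: float = 0.5) -> float:
    if not 0 < threshold < 1:
        raise ValidationError("threshold must lie in (0,1)")
    scores, labels = _check(scores, labels)
    return float(f1_score(labels, (scores >= threshold).astype(int),
                          zero_division=0))


def recall(scores, labels, threshold: float = 0.5) -> float:
    counts = confusion_counts(scores, labels, threshold)
    denom = counts["tp"] + counts["fn"]
    return counts["tp"] / denom if denom else 0.0


def summarize(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    out = {
        "auroc": auroc(scores, labels),
        "aupr": aupr(scores, labels),
        "mcc": mcc(scores, labels, threshold),
        "f1": f1(scores, labels, threshold),
        "recall": recall(scores, labels, threshold),
        "threshold": threshold,
    }
    out.update(confusion_counts(scores, labels, threshold))
    return out


@dataclass
class EvaluationReport:
    """Per-fold and pooled metrics for a cross-validated run."""

    per_fold: list[dict[str, float]]
    pooled: dict[str, float]
    mean_over_folds: dict[str, float]
    threshold: float = 0.5

    @classmethod
    def from_folds(cls, fold_scores: list[np.ndarray],
                   fold_labels: list[np.ndarray],
                   threshold: float = 0.5) -> "EvaluationReport":
        per_fold = [summarize(s, y, threshold)
                    for s, y in zip(fold_scores, fold_labels)]
        pooled = summarize(np.concatenate(fold_scores),
                           np.concatenate(fold_labels), threshold)
        keys = ("auroc", "aupr", "mcc", "f1", "recall")
        mean = {k: float(np.mean([f[k] for f in per_fold])) for k in keys}
        return cls(per_fold=per_fold, pooled=pooled, mean_over_folds=mean,
                   threshold=threshold)
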