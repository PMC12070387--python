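"""Confusion-matrix metrics, ROC curves and report assembly.

Accuracy, precision, recall and F1 follow the standard binary definitions:

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

Degenerate 0/0 ratios (no predicted positives, or no actual positives) are
reported as 0 and flagged explicitly rather than raising, since small
cross-validation folds can legitimately produce them.

AUC is computed by the trapezoidal rule on a tie-grouped ROC curve, which is
algebraically identical to the Mann-Whitney concordance statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyEvalError, RocError, ShapeMismatchError

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "RocCurve",
    "confusion_counts",
    "compute_metrics",
    "f1_score",
    "roc_auc",
    "evaluate_predictions",
    "mean_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    accuracy: float
    precision: float
    recall: float
    f1: float
    counts: ConfusionCounts
    auc: float | None = None
    degenerate: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "auc": self.auc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
            "degenerate": ";".join(self.degenerate),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.to_dict()])


@dataclass
class RocCurve:
    """ROC operating points (FPR, TPR) from (0,0) to (1,1), plus the AUC."""

    points: list[tuple[float, float]]
    auc: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["fpr", "tpr"])


def confusion_counts(labels: np.ndarray, predictions: np.ndarray) -> ConfusionCounts:
    """Count TP/TN/FP/FN for binary labels and hard binary predictions."""
    y = np.asarray(labels).ravel()
    p = np.asarray(predictions).ravel()
    if y.shape != p.shape:
        raise ShapeMismatchError(f"labels {y.shape} vs predictions {p.shape}")
    if y.size == 0:
        raise EmptyEvalError("no samples to evaluate")
    y = y.astype(int)
    p = p.astype(int)
    tp = int(np.sum((y == 1) & (p == 1)))
    tn = int(np.sum((y == 0) & (p == 0)))
    fp = int(np.sum((y == 0) & (p == 1)))
    fn = int(np.sum((y == 1) & (p == 0)))
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Derive accuracy/precision/recall/F1 from confusion counts (AUC unset)."""
    if counts.total == 0:
        raise EmptyEvalError("confusion counts sum to zero")
    degenerate: list[str] = []
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        precision = 0.0
        degenerate.append("precision_undefined")
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall = 0.0
        degenerate.append("recall_undefined")
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f1 = 0.0
        if not degenerate:
            degenerate.append("f1_undefined")
    else:
        f1 = f1_score(precision, recall)
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        recall=recall,
        f1=f1,
        counts=counts,
        degenerate=degenerate,
    )


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC curve and AUC from continuous scores.

    Thresholds sweep the unique scores in descending order; tied scores form a
    single step so the curve is well defined under ties.
    """
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=np.float64).ravel()
    if y.shape != s.shape:
        raise ShapeMismatchError(f"labels {y.shape} vs scores {s.shape}")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise RocError("ROC requires both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tps = np.cumsum(y_sorted == 1)
    fps = np.cumsum(y_sorted == 0)
    # keep only the last index of each tied-score block
    last_of_block = np.r_[np.diff(s_sorted) != 0, True]
    tpr = np.r_[0.0, tps[last_of_block] / n_pos]
    fpr = np.r_[0.0, fps[last_of_block] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=list(zip(fpr.tolist(), tpr.tolist())), auc=auc)


def evaluate_predictions(
    labels: np.ndarray, scores: np.ndarray, threshold: float = 0.5
) -> MetricReport:
    """Full report from probabilistic scores: threshold at 0.5, plus AUC.

    AUC is left unset when only one class is present in ``labels``.
    """
    y = np.asarray(labels).ravel().astype(int)
    s = np.asarray(scores, dtype=np.float64).ravel()
    preds = (s >= threshold).astype(int)
    report = compute_metrics(confusion_counts(y, preds))
    if 0 < y.sum() < y.size:
        report.auc = roc_auc(y, s).auc
    return report


def mean_report(reports: list[MetricReport]) -> MetricReport:
    """Unweighted mean of fold reports; counts are summed for reference."""
    if not reports:
        raise EmptyEvalError("no reports to average")
    counts = ConfusionCounts(
        tp=sum(r.counts.tp for r in reports),
        tn=sum(r.counts.tn for r in reports),
        fp=sum(r.counts.fp for r in reports),
        fn=sum(r.counts.fn for r in reports),
    )
    aucs = [r.auc for r in reports if r.auc is not None]
    return MetricReport(
        accuracy=float(np.mean([r.accuracy for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
        recall=float(np.mean([r.recall for r in reports])),
        f1=float(np.mean([r.f1 for r in reports])),
        counts=counts,
        auc=float(np.mean(aucs)) if aucs else None,
        degenerate=sorted({d for r in reports for d in r.degenerate}),
    )
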