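"""Binary-classification evaluation: confusion counts, threshold metrics,
ROC/AUC, adaptive thresholding and best-epoch selection.

Conventions: scores are positive-class probabilities; an exam is predicted
positive iff its score is strictly greater than the threshold; degenerate
metric denominators yield 0 with a logged warning instead of raising, so
batch evaluation never aborts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = [
    "ConfusionCounts",
    "RocCurve",
    "EvalReport",
    "confusion",
    "metrics_from_counts",
    "roc_auc",
    "adaptive_threshold",
    "select_best_epoch",
    "evaluate_scores",
    "report_to_tsv",
    "roc_to_text",
]

logger = logging.getLogger(__name__)

METRIC_COLUMNS = ("AUC", "ACC", "Precision", "Recall", "Specificity", "F1")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            if getattr(self, name) < 0:
                raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class RocCurve:
    """ROC curve over all score thresholds plus the trapezoidal AUC."""

    thresholds: np.ndarray  # descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts, the six headline metrics and the threshold used."""

    counts: ConfusionCounts
    acc: float
    precision: float
    recall: float
    specificity: float
    f1: float
    auc: float
    threshold: float

    def as_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def _validate_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.size == 0:
        raise ValueError("empty score vector")
    if scores.size != labels.size:
        raise ValueError("scores and labels must have equal length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return scores, labels


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/FP/TN/FN with prediction positive iff score > threshold."""
    scores, labels = _validate_scores_labels(scores, labels)
    pred = scores > threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        fp=int(np.sum(pred & ~pos)),
        tn=int(np.sum(~pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("degenerate denominator for %s; returning 0", name)
        return 0.0
    return num / den


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall, specificity and F1 from the counts."""
    if c.total == 0:
        raise ValueError("no evaluated exams")
    acc = (c.tp + c.tn) / c.total
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    specificity = _safe_div(c.tn, c.tn + c.fp, "specificity")
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "f1")
    return {
        "acc": acc,
        "precision": precision,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
    }


def roc_auc(scores, labels) -> RocCurve:
    """ROC curve over all unique thresholds and its trapezoidal area.

    The trapezoidal area equals the Mann-Whitney pairwise statistic with
    ties counted one half.  Raises if only one class is present (the AUC is
    undefined there).
    """
    scores, labels = _validate_scores_labels(scores, labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    fpr, tpr, thr = _sk_roc_curve(labels, scores, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc)


def adaptive_threshold(val_scores, val_labels) -> float:
    """Accuracy-maximising threshold on a validation set.

    Candidates are the midpoints between adjacent sorted unique scores plus
    -inf/+inf sentinels (so "predict everything positive/negative" is always
    on the table).  Ties in accuracy break toward the smallest threshold,
    which favours sensitivity; the choice is logged.
    """
    scores, labels = _validate_scores_labels(val_scores, val_labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("validation set must contain both classes")
    uniq = np.unique(scores)
    candidates = np.concatenate(
        ([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf])
    )
    # accuracy at each candidate, vectorised: pred[i, k] = score_i > cand_k
    pred = scores[:, None] > candidates[None, :]
    correct = pred == (labels[:, None] == 1)
    acc = correct.mean(axis=0)
    best = candidates[np.argmax(acc)]  # argmax returns the first (smallest) maximiser
    logger.info(
        "adaptive threshold %.6g with validation accuracy %.4f", best, acc.max()
    )
    return float(best)


def select_best_epoch(val_aucs) -> int:
    """0-based index of the epoch with maximal validation AUC (earliest tie)."""
    aucs = np.asarray(val_aucs, dtype=float).ravel()
    if aucs.size == 0:
        raise ValueError("empty AUC history")
    return int(np.argmax(aucs))


def evaluate_scores(scores, labels, threshold: float = 0.5) -> EvalReport:
    """Full report: confusion at the threshold plus threshold-free AUC."""
    c = confusion(scores, labels, threshold)
    m = metrics_from_counts(c)
    auc = roc_auc(scores, labels).auc
    return EvalReport(counts=c, auc=auc, threshold=float(threshold), **m)


def report_to_tsv(report: EvalReport) -> str:
    """One-row tab-separated metrics table (columns AUC..F1)."""
    vals = (
        report.auc,
        report.acc,
        report.precision,
        report.recall,
        report.specificity,
        report.f1,
    )
    header = "\t".join(METRIC_COLUMNS)
    row = "\t".join(f"{v:.4f}" for v in vals)
    return f"{header}\n{row}\n"


def roc_to_text(curve: RocCurve) -> str:
    """Two-column (FPR, TPR) text export of the ROC points."""
    lines = ["FPR\tTPR"]
    lines += [f"{f:.6f}\t{t:.6f}" for f, t in zip(curve.fpr, curve.tpr)]
    return "\n".join(lines) + "\n"


def report_to_json(report: EvalReport) -> str:
    return json.dumps(report.as_dict(), indent=2)
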