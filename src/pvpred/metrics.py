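"""Binary-classification evaluation: confusion metrics and ROC/auROC.

Conventions: the positive class is the virion protein class.

    Sn  = TP / (TP + FN)            sensitivity (recall on positives)
    Sp  = TN / (TN + FP)            specificity (recall on negatives)
    Acc = (TP + TN) / total
    Mcc = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

Mcc with any zero factor in its denominator is defined as 0 (the standard
convention for degenerate confusion matrices). The ROC sweep descends
through the unique decision scores, moving tied samples as a block — this
avoids the optimistic stair-casing a per-sample sweep would produce — and
auROC is the trapezoidal area, which equals the Mann-Whitney pair-counting
statistic with ties counted one half.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionMatrix":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        )


@dataclass
class MetricsReport:
    """Sn/Sp/Acc/Mcc plus (optionally) the ROC curve and its area."""

    confusion: ConfusionMatrix
    sn: float
    sp: float
    acc: float
    mcc: float
    roc_points: np.ndarray | None = None  # (fpr, tpr) rows
    auroc: float | None = None
    scores: np.ndarray | None = field(default=None, repr=False)
    labels: np.ndarray | None = field(default=None, repr=False)

    def to_tsv(self, path: str | Path) -> None:
        rows = {
            "tp": self.confusion.tp, "fn": self.confusion.fn,
            "fp": self.confusion.fp, "tn": self.confusion.tn,
            "sn_pct": round(100 * self.sn, 2),
            "sp_pct": round(100 * self.sp, 2),
            "acc_pct": round(100 * self.acc, 2),
            "mcc": round(self.mcc, 4),
        }
        if self.auroc is not None:
            rows["auroc"] = round(self.auroc, 4)
        pd.Series(rows, name="value").rename_axis("metric").to_csv(path, sep="\t")


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsReport:
    """Sn, Sp, Acc and Mcc from raw confusion counts (no ROC)."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pos = cm.tp + cm.fn
    neg = cm.tn + cm.fp
    sn = cm.tp / pos if pos else 0.0
    sp = cm.tn / neg if neg else 0.0
    acc = (cm.tp + cm.tn) / cm.total
    denom = (
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / math.sqrt(denom)
    return MetricsReport(confusion=cm, sn=sn, sp=sp, acc=acc, mcc=mcc)


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal auROC from decision scores.

    Returns
    -------
    points : ndarray of shape (n_thresholds + 1, 2)
        (false-positive rate, true-positive rate) pairs, starting at (0, 0)
        and ending at (1, 1).
    auroc : float
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lab = labels[order]
    # group ties: indices where a threshold block ends
    block_end = np.nonzero(np.diff(s))[0]
    ends = np.concatenate([block_end, [len(s) - 1]])
    tp_cum = np.cumsum(lab == 1)[ends]
    fp_cum = np.cumsum(lab == 0)[ends]
    tpr = np.concatenate([[0.0], tp_cum / n_pos])
    fpr = np.concatenate([[0.0], fp_cum / n_neg])
    auroc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auroc


def evaluate_predictions(
    y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None
) -> MetricsReport:
    """Full report: confusion metrics plus ROC when scores are available."""
    report = metrics_from_confusion(ConfusionMatrix.from_predictions(y_true, y_pred))
    if scores is not None:
        report.roc_points, report.auroc = roc_curve(scores, y_true)
        report.scores = np.asarray(scores, dtype=float)
        report.labels = np.asarray(y_true).astype(int)
    return report


def roc_to_tsv(points: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(points, columns=["fpr", "tpr"]).to_csv(path, sep="\t", index=False)
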