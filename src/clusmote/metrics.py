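"""Imbalance-aware classifier evaluation metrics.

Seven quantities reported per evaluation fold: TPR (sensitivity, SE),
TNR (specificity, SP), precision (PPV), FPR, ROC AUC, the geometric
mean

    Gmean = sqrt(SP * SE),

and the adjusted geometric mean

    AGm = (Gmean + SP * Nn) / (1 + Nn)   if SE > 0,   else 0,

with Nn the proportion of negative samples in the evaluated set; AGm
rewards specificity more the more negatives dominate, which suits
screening problems where false positives waste downstream experiments.
The F-measure uses the count form 2*TP / (2*TP + FN + FP), identical to
the harmonic mean of precision and sensitivity where both are defined.

Fold aggregation is macro: the arithmetic mean of each per-fold metric
(so the aggregated Gmean is generally not the Gmean of the aggregated
SP and SE).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

REPORT_COLUMNS = ["TPR", "TNR", "Precision", "FPR", "AUC",
                  "Gmean", "AGm", "Fmeasure"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("counts must be non-negative")
        if self.TP + self.FP + self.TN + self.FN < 1:
            raise ValueError("at least one sample required")


@dataclass(frozen=True)
class MetricReport:
    TPR: float
    TNR: float
    Precision: float
    FPR: float
    AUC: float
    Gmean: float
    AGm: float
    Fmeasure: float
    Nn: float

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def confusion(y_true, y_pred) -> ConfusionCounts:
    """2x2 confusion counts with the minority/epitope class (1) positive."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def fmeasure(c: ConfusionCounts) -> float:
    denom = 2 * c.TP + c.FN + c.FP
    if denom == 0:
        logger.info("F-measure undefined (no positives anywhere); using 0")
        return 0.0
    return 2 * c.TP / denom


def gmean(SP: float, SE: float) -> float:
    return float(np.sqrt(SP * SE))


def adjusted_gmean(SP: float, SE: float, Nn: float) -> float:
    if SE == 0:
        return 0.0
    return (gmean(SP, SE) + SP * Nn) / (1 + Nn)


def roc_auc(y_true, scores) -> float:
    """Mann–Whitney concordance AUC (ties count one half)."""
    y_true = np.asarray(y_true)
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC needs both classes in y_true")
    return float(roc_auc_score(y_true, np.asarray(scores, dtype=float)))


def fold_report(y_true, y_pred, scores) -> MetricReport:
    """All metrics for one evaluation fold."""
    c = confusion(y_true, y_pred)
    n_pos, n_neg = c.TP + c.FN, c.TN + c.FP
    SE = c.TP / n_pos if n_pos else 0.0
    SP = c.TN / n_neg if n_neg else 0.0
    if c.TP + c.FP == 0:
        logger.info("no positive predictions; precision set to 0")
        ppv = 0.0
    else:
        ppv = c.TP / (c.TP + c.FP)
    Nn = n_neg / (n_pos + n_neg)
    return MetricReport(
        TPR=SE, TNR=SP, Precision=ppv, FPR=1.0 - SP,
        AUC=roc_auc(y_true, scores),
        Gmean=gmean(SP, SE), AGm=adjusted_gmean(SP, SE, Nn),
        Fmeasure=fmeasure(c), Nn=Nn,
    )


def aggregate(reports: list[MetricReport]) -> MetricReport:
    """Macro aggregation: element-wise arithmetic mean over folds."""
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    vals = {f.name: float(np.mean([getattr(r, f.name) for r in reports]))
            for f in fields(MetricReport)}
    return MetricReport(**vals)
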