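"""Threshold and ranking metrics for binary hairpin classification.

Seven quantities summarize a classifier here: sensitivity (SE),
specificity (SP), positive predictive value (PPV), F-score, the
geometric mean of SE and SP (g-mean), and the two ranking areas AUROC
and AUPR. Threshold metrics use a 0.5 decision cut with score >= 0.5
called positive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

DECISION_THRESHOLD = 0.5


class UndefinedMetricError(ValueError):
    """A metric has no value on this input (e.g. single-class labels)."""


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    SE: float
    SP: float
    PPV: float
    F_score: float
    g_mean: float
    AUROC: float | None = None
    AUPR: float | None = None
    ppv_defined: bool = True

    def as_dict(self) -> dict:
        return {
            "SE": self.SE,
            "SP": self.SP,
            "PPV": self.PPV,
            "F_score": self.F_score,
            "g_mean": self.g_mean,
            "AUROC": self.AUROC,
            "AUPR": self.AUPR,
        }


def confusion(
    scores, labels, threshold: float = DECISION_THRESHOLD
) -> ConfusionCounts:
    """Confusion counts at a score threshold (>= threshold is positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("cannot evaluate an empty set")
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics_from_counts(c: ConfusionCounts) -> MetricsReport:
    """SE, SP, PPV, F-score and g-mean from confusion counts.

    PPV is reported as 0 (flagged) when no example is called positive.
    """
    se = c.TP / (c.TP + c.FN) if (c.TP + c.FN) else 0.0
    sp = c.TN / (c.TN + c.FP) if (c.TN + c.FP) else 0.0
    ppv_defined = (c.TP + c.FP) > 0
    ppv = c.TP / (c.TP + c.FP) if ppv_defined else 0.0
    f = 2 * c.TP / (2 * c.TP + c.FP + c.FN) if (2 * c.TP + c.FP + c.FN) else 0.0
    return MetricsReport(
        SE=se,
        SP=sp,
        PPV=ppv,
        F_score=f,
        g_mean=g_mean(se, sp),
        ppv_defined=ppv_defined,
    )


def g_mean(se: float, sp: float) -> float:
    return math.sqrt(se * sp)


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError(
            "ranking metrics need both classes present"
        )


def auroc(scores, labels) -> float:
    """Area under the ROC curve (rank statistic, ties averaged)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aupr(scores, labels) -> float:
    """Area under the precision-recall curve with step-wise interpolation
    (precision held constant between successive recall points)."""
    labels = np.asarray(labels)
    _check_two_classes(labels)
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def evaluate(scores, labels, threshold: float = DECISION_THRESHOLD) -> MetricsReport:
    """Full seven-metric report; ranking areas None when only one class."""
    report = metrics_from_counts(confusion(scores, labels, threshold))
    labels_arr = np.asarray(labels)
    if len(np.unique(labels_arr)) == 2:
        return MetricsReport(
            SE=report.SE,
            SP=report.SP,
            PPV=report.PPV,
            F_score=report.F_score,
            g_mean=report.g_mean,
            AUROC=auroc(scores, labels),
            AUPR=aupr(scores, labels),
            ppv_defined=report.ppv_defined,
        )
    return report


def relative_improvement(ours: float, best_other: float) -> float:
    """Percentage improvement of ``ours`` over ``best_other``,
    100 * (ours - best_other) / best_other, rounded to 2 decimals."""
    if best_other <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (ours - best_other) / best_other, 2)
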