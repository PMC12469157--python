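"""Classification metrics and decision curve analysis.

Threshold metrics (precision, sensitivity, specificity, accuracy, F1) at a
configurable cutoff, ranking metrics (ROC-AUC with Mann-Whitney tie handling,
PR-AUC by step-curve summation), and net-benefit decision curves against the
treat-all / treat-none policies:

    NB(p_t) = TP/N - FP/N * p_t / (1 - p_t)
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "MetricsReport",
    "NetBenefitCurve",
    "confusion_metrics",
    "roc_auc",
    "pr_auc",
    "full_report",
    "decision_curve",
]


@dataclass(frozen=True)
class MetricsReport:
    """Confusion-matrix metrics at one threshold; NaN marks an undefined ratio."""

    precision: float
    sensitivity: float
    specificity: float
    accuracy: float
    f1: float
    threshold: float
    roc_auc: float = math.nan
    pr_auc: float = math.nan

    def to_dict(self) -> dict[str, float]:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "f1": self.f1,
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "threshold": self.threshold,
        }


@dataclass(frozen=True)
class NetBenefitCurve:
    thresholds: np.ndarray
    model_nb: np.ndarray
    treat_all_nb: np.ndarray
    treat_none_nb: np.ndarray


def _validate(probabilities, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcomes must have equal length")
    if not set(np.unique(y)).issubset({0, 1}):
        raise ValueError("outcomes must be binary 0/1")
    return p, y.astype(int)


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def confusion_metrics(probabilities, outcomes, threshold: float = 0.5) -> MetricsReport:
    """Threshold metrics; predicted positive iff probability >= threshold.

    A ratio with zero denominator (e.g. precision with no predicted
    positives) is reported as NaN rather than silently coerced to 0.
    """
    p, y = _validate(probabilities, outcomes)
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    pre = _ratio(tp, tp + fp)
    sen = _ratio(tp, tp + fn)
    spe = _ratio(tn, tn + fp)
    acc = _ratio(tp + tn, len(y))
    f1 = _ratio(2 * pre * sen, pre + sen) if (pre + sen) and not (
        math.isnan(pre) or math.isnan(sen)
    ) else math.nan
    return MetricsReport(
        precision=pre, sensitivity=sen, specificity=spe,
        accuracy=acc, f1=f1, threshold=threshold,
    )


def roc_auc(probabilities, outcomes) -> float:
    """Area under the ROC curve.

    Equals the Mann-Whitney probability that a random case outscores a random
    control, with ties counted 1/2.
    """
    p, y = _validate(probabilities, outcomes)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc requires both outcome classes")
    return float(roc_auc_score(y, p))


def pr_auc(probabilities, outcomes) -> float:
    """Area under the precision-recall step curve (average-precision style).

    No linear interpolation between PR points, avoiding the optimistic bias
    of trapezoidal PR areas.
    """
    p, y = _validate(probabilities, outcomes)
    if y.sum() == 0:
        raise ValueError("pr_auc requires at least one positive outcome")
    return float(average_precision_score(y, p))


def full_report(probabilities, outcomes, threshold: float = 0.5) -> MetricsReport:
    """Confusion metrics plus both ranking areas in one report."""
    base = confusion_metrics(probabilities, outcomes, threshold)
    return MetricsReport(
        precision=base.precision, sensitivity=base.sensitivity,
        specificity=base.specificity, accuracy=base.accuracy, f1=base.f1,
        threshold=threshold,
        roc_auc=roc_auc(probabilities, outcomes),
        pr_auc=pr_auc(probabilities, outcomes),
    )


def decision_curve(probabilities, outcomes, thresholds=None) -> NetBenefitCurve:
    """Net-benefit curve for the model vs treat-all and treat-none policies.

    Default threshold grid is 0.01..0.99 in steps of 0.01.  Treat-none has
    zero net benefit everywhere; treat-all tends to the outcome prevalence as
    the threshold approaches 0.
    """
    p, y = _validate(probabilities, outcomes)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if ((thresholds <= 0) | (thresholds >= 1)).any():
        raise ValueError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    n_pos = y.sum()
    odds = thresholds / (1.0 - thresholds)

    pred = p[None, :] >= thresholds[:, None]
    tp = (pred & (y == 1)[None, :]).sum(axis=1)
    fp = (pred & (y == 0)[None, :]).sum(axis=1)
    model_nb = tp / n - fp / n * odds
    treat_all_nb = n_pos / n - (n - n_pos) / n * odds
    return NetBenefitCurve(
        thresholds=thresholds, model_nb=model_nb,
        treat_all_nb=treat_all_nb, treat_none_nb=np.zeros_like(thresholds),
    )
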