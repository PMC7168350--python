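"""Binary-classification metrics, ROC analysis and model comparison.

Implements the four headline metrics

    MCC = (TP*TN - FP*FN) / sqrt((TN+FN)(TP+FP)(TN+FP)(TP+FN))
    Ac  = (TP + TN) / (TP + FN + FP + TN)
    Sn  = TP / (TP + FN)
    Sp  = TN / (TN + FP)

plus trapezoid/Mann-Whitney AUC, specificity-controlled threshold
selection (pick the operating point where Sp first reaches a target,
then report Sn there), and a paired two-tailed t-test over CV folds for
comparing two models. A sample is called positive when its score is >=
the threshold. MCC is defined as 0 when any factor of its denominator
is 0 (a degenerate confusion table).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("negative confusion counts")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    mcc: float
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float | None = None
    threshold: float | None = None

    def as_dict(self) -> dict:
        return {"MCC": self.mcc, "Ac": self.accuracy,
                "Sn": self.sensitivity, "Sp": self.specificity,
                "AUC": self.auc, "threshold": self.threshold}


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def confusion_counts(scores, labels, threshold: float = 0.5
                     ) -> ConfusionCounts:
    """Tally TP/TN/FP/FN calling positive at score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores/labels misaligned")
    calls = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(tp=int((calls & pos).sum()),
                           tn=int((~calls & ~pos).sum()),
                           fp=int((calls & ~pos).sum()),
                           fn=int((~calls & pos).sum()))


def compute_metrics(counts: ConfusionCounts, auc: float | None = None,
                    threshold: float | None = None) -> MetricsReport:
    """MCC, accuracy, sensitivity and specificity from a confusion table."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    denom_factors = [tn + fn, tp + fp, tn + fp, tp + fn]
    if 0 in denom_factors:
        logger.info("degenerate MCC denominator %s -> MCC=0", denom_factors)
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / math.sqrt(math.prod(denom_factors))
    ac = (tp + tn) / counts.total
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    return MetricsReport(mcc, ac, sn, sp, auc=auc, threshold=threshold)


def roc_auc(scores, labels) -> ROCCurve:
    """Threshold-sweep ROC with trapezoid AUC.

    Tied scores step diagonally (equivalent to the Mann-Whitney
    statistic with half credit for ties).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes required for ROC")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    return ROCCurve(fpr, tpr, thr, float(_trapezoid_auc(fpr, tpr)))


def threshold_at_specificity(scores, labels, target_sp: float
                             ) -> tuple[float, float, float]:
    """Smallest threshold whose specificity reaches ``target_sp``.

    Returns ``(threshold, achieved_sp, achieved_sn)``. Raises if no
    threshold in [0, 1] reaches the target (e.g. all negatives share
    the maximal score), reporting the achievable maximum.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if not 0 <= target_sp < 1:
        if target_sp >= 1:
            raise ValueError("target specificity must be < 1 to be "
                             "meaningfully reachable; use 0.99...")
        raise ValueError("target specificity must be in [0, 1)")
    neg = scores[labels == 0]
    if neg.size == 0:
        raise ValueError("negatives required to control specificity")
    candidates = np.unique(np.concatenate([scores, [1.0]]))
    for t in candidates:
        sp = float((neg < t).mean())
        if sp >= target_sp:
            cc = confusion_counts(scores, labels, t)
            sn = cc.tp / (cc.tp + cc.fn) if cc.tp + cc.fn else 0.0
            return float(t), sp, sn
    max_sp = float((neg < candidates[-1]).mean())
    raise ValueError(
        f"specificity {target_sp} unreachable; maximum achievable "
        f"is {max_sp:.4f}")


def metrics_at_specificity(scores, labels, target_sp: float) -> MetricsReport:
    """Full metrics report at the Sp-controlled operating point."""
    t, _, _ = threshold_at_specificity(scores, labels, target_sp)
    counts = confusion_counts(scores, labels, t)
    curve = roc_auc(scores, labels)
    return compute_metrics(counts, auc=curve.auc, threshold=t)


def compare_models_ttest(per_fold_a, per_fold_b) -> float:
    """Paired two-tailed t-test p-value on fold-wise metric differences.

    Identical fold metrics give difference 0 everywhere; the p-value is
    reported as 1 by convention. Nonzero constant differences give p=0
    (infinite t statistic).
    """
    a = np.asarray(per_fold_a, dtype=float)
    b = np.asarray(per_fold_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired fold metrics must be equal-length vectors")
    if len(a) < 2:
        raise ValueError("need >= 2 folds")
    d = a - b
    if np.allclose(d, 0):
        return 1.0
    if np.std(d, ddof=1) == 0:
        return 0.0
    return float(stats.ttest_rel(a, b).pvalue)
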