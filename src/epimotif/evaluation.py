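"""ROC curves and AUC for interval score rankings.

The ROC is built by sweeping a threshold down the distinct score values;
ties are grouped at a single threshold step, and the AUC is the trapezoidal
integral of the curve — equivalent to the Mann-Whitney statistic with
half-credit for tied positive/negative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = ["ROCResult", "roc_curve", "averaged_roc", "AveragedROC"]


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_pos: int
    n_neg: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"auc out of range: {self.auc}")
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise ValueError("fpr and tpr must be non-decreasing")


def roc_curve(scores, labels) -> ROCResult:
    """ROC curve and AUC from scores and binary labels.

    Higher scores are treated as more binding-like.  Both classes must be
    present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be matching 1-D arrays")
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to build a ROC curve")

    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # keep only the last index of each tied-score group
    last = np.r_[np.nonzero(np.diff(s))[0], s.size - 1]
    tpr = np.r_[0.0, tp[last] / n_pos]
    fpr = np.r_[0.0, fp[last] / n_neg]
    thresholds = np.r_[np.inf, s[last]]
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        thresholds=thresholds, fpr=fpr, tpr=tpr,
        auc=auc, n_pos=n_pos, n_neg=n_neg,
    )


@dataclass(frozen=True)
class AveragedROC:
    """Test-set evaluation across chromosomes.

    ``pooled`` concatenates every chromosome's intervals into a single
    ranking (the primary summary); ``per_chromosome_auc`` holds each
    chromosome's own AUC and ``macro_auc`` their unweighted mean.
    """

    pooled: ROCResult
    per_chromosome_auc: dict[str, float]
    macro_auc: float


def averaged_roc(
    per_chromosome: Mapping[str, tuple[Sequence[float], Sequence[int]]],
) -> AveragedROC:
    """Evaluate per-chromosome score/label pairs jointly and separately.

    Chromosomes with a single class are excluded from the macro average
    but still contribute to the pooled ranking.
    """
    if not per_chromosome:
        raise ValueError("need at least one chromosome")
    all_scores, all_labels = [], []
    per_auc: dict[str, float] = {}
    for chrom, (scores, labels) in per_chromosome.items():
        all_scores.append(np.asarray(scores, dtype=float))
        all_labels.append(np.asarray(labels, dtype=int))
        labs = all_labels[-1]
        if 0 < labs.sum() < labs.size:
            per_auc[chrom] = roc_curve(scores, labels).auc
    pooled = roc_curve(np.concatenate(all_scores), np.concatenate(all_labels))
    macro = float(np.mean(list(per_auc.values()))) if per_auc else pooled.auc
    return AveragedROC(pooled=pooled, per_chromosome_auc=per_auc, macro_auc=macro)
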