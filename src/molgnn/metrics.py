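"""Evaluation metrics and the statistical tests driving the training protocol.

AUC uses the Mann-Whitney formulation (probability that a random positive
outscores a random negative, ties counted half) so tie handling is explicit.
The Wilcoxon rank-sum test is exact by enumeration for pooled sample sizes up
to 12 and uses the tie-corrected normal approximation beyond that; the Sidak
correction adjusts the per-comparison significance level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt
from typing import Literal, Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.tp + self.tn + self.fp + self.fn < 1:
            raise ValueError("confusion counts must describe at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricReport:
    auc: float
    acc: float
    f1: float
    mcc: float


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank sum of the first sample (mid-ranks)
    p_value: float
    sidedness: Literal["one_sided", "two_sided"]


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve via all-pairs concordance.

    Equals P(score+ > score-) + 0.5 * P(score+ = score-); requires both
    classes present.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    ranks = rankdata(scores)  # mid-ranks give ties weight 1/2
    rank_sum_pos = float(np.sum(ranks[labels == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def confusion_counts(
    predictions: Sequence[int], labels: Sequence[int]
) -> ConfusionCounts:
    predictions = np.asarray(predictions, dtype=int)
    labels = np.asarray(labels, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((predictions == 1) & (labels == 1))),
        tn=int(np.sum((predictions == 0) & (labels == 0))),
        fp=int(np.sum((predictions == 1) & (labels == 0))),
        fn=int(np.sum((predictions == 0) & (labels == 1))),
    )


def classification_metrics(counts: ConfusionCounts, auc: float = float("nan")) -> MetricReport:
    """ACC, F1 and MCC from a confusion table (AUC passed through).

    Zero-denominator F1 and MCC are 0 by convention, keeping reports total.
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    acc = (tp + tn) / counts.total
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / sqrt(denom) if denom > 0 else 0.0
    return MetricReport(auc=auc, acc=acc, f1=f1, mcc=mcc)


# Threshold between exact enumeration and the normal approximation: all
# C(12, k) <= 924 rank assignments are enumerable instantly.
EXACT_ENUMERATION_LIMIT = 12


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    sidedness: Literal["one_sided", "two_sided"] = "one_sided",
    alternative: Literal["greater", "less"] = "greater",
) -> RankSumResult:
    """Wilcoxon rank-sum (Mann-Whitney) test with mid-ranks for ties.

    The statistic is the rank sum of ``x`` in the pooled mid-ranked sample.
    For pooled sizes n+m <= 12 the p-value is exact, from full enumeration of
    the C(n+m, n) equally likely rank assignments (conditional on the observed
    tie pattern); otherwise the tie-corrected normal approximation is used.
    One-sided ``greater`` tests whether ``x`` tends larger than ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    w = float(np.sum(ranks[:n]))

    if n + m <= EXACT_ENUMERATION_LIMIT:
        total = comb(n + m, n)
        ge = le = 0
        for idx in combinations(range(n + m), n):
            s = float(np.sum(ranks[list(idx)]))
            if s >= w - 1e-9:
                ge += 1
            if s <= w + 1e-9:
                le += 1
        p_greater = ge / total
        p_less = le / total
    else:
        mean = n * (n + m + 1) / 2.0
        tie_counts = np.unique(pooled, return_counts=True)[1]
        big_n = n + m
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (big_n * (big_n - 1))
        var = n * m / 12.0 * ((big_n + 1) - tie_term)
        if var == 0:
            p_greater = p_less = 0.5
        else:
            z = (w - mean) / sqrt(var)
            p_greater = 0.5 * (1 - erf(z / sqrt(2)))
            p_less = 0.5 * (1 + erf(z / sqrt(2)))

    if sidedness == "two_sided":
        p = min(1.0, 2.0 * min(p_greater, p_less))
    else:
        p = p_greater if alternative == "greater" else p_less
    return RankSumResult(statistic=w, p_value=float(p), sidedness=sidedness)


def sidak_alpha(alpha: float, m: int) -> float:
    """Sidak-corrected per-comparison level: 1 - (1 - alpha)^(1/m)."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def scores_to_report(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> MetricReport:
    """Full metric report from probability scores and binary labels.

    ``threshold`` applies to the probability (sigmoid of the logit).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc = roc_auc(scores, labels)
    counts = confusion_counts((scores >= threshold).astype(int), labels)
    return classification_metrics(counts, auc=auc)
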