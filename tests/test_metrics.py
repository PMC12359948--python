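"""Metrics and statistical tests against independent references."""

from itertools import permutations
from math import comb

import numpy as np
import pytest
from scipy.stats import mannwhitneyu, rankdata
from sklearn.metrics import accuracy_score, f1_score, matthews_corrcoef, roc_auc_score

from molgnn.metrics import (
    ConfusionCounts,
    classification_metrics,
    confusion_counts,
    roc_auc,
    scores_to_report,
    sidak_alpha,
    wilcoxon_rank_sum,
)


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([0.9, 0.8, 0.3, 0.1], [1, 1, 0, 0], 1.0),
        ([0.9, 0.8, 0.3, 0.1], [0, 0, 1, 1], 0.0),
        ([0.9, 0.8, 0.3, 0.1], [1, 0, 1, 0], 0.75),
        ([0.5, 0.5], [1, 0], 0.5),  # tie counted half
    ],
)
def test_roc_auc_examples(scores, labels, expected):
    assert roc_auc(scores, labels) == pytest.approx(expected)


def test_roc_auc_single_class_errors():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.2], [1, 1])


def test_roc_auc_matches_sklearn_and_complement():
    rng = np.random.default_rng(12)
    for _ in range(50):
        n = int(rng.integers(4, 40))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # induce ties
        ours = roc_auc(scores, labels)
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
        if len(np.unique(scores)) == n:  # complement identity (no ties)
            assert roc_auc(-scores, labels) == pytest.approx(1 - ours, abs=1e-12)


def test_classification_metrics_worked_example():
    rep = classification_metrics(ConfusionCounts(tp=3, tn=3, fp=1, fn=1))
    assert rep.acc == pytest.approx(0.75)
    assert rep.f1 == pytest.approx(0.75)
    assert rep.mcc == pytest.approx(0.5)  # (9-1)/16
    perfect = classification_metrics(ConfusionCounts(tp=4, tn=4, fp=0, fn=0))
    assert (perfect.acc, perfect.f1, perfect.mcc) == (1.0, 1.0, 1.0)
    degenerate = classification_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=5))
    assert degenerate.f1 == 0.0 and degenerate.mcc == 0.0


def test_classification_metrics_match_sklearn():
    rng = np.random.default_rng(13)
    for _ in range(50):
        n = int(rng.integers(4, 50))
        labels = rng.integers(0, 2, size=n)
        preds = rng.integers(0, 2, size=n)
        rep = classification_metrics(confusion_counts(preds, labels))
        assert rep.acc == pytest.approx(accuracy_score(labels, preds))
        assert rep.f1 == pytest.approx(f1_score(labels, preds, zero_division=0))
        if len(np.unique(preds)) > 1 and len(np.unique(labels)) > 1:
            assert rep.mcc == pytest.approx(matthews_corrcoef(labels, preds))


def test_class_swap_invariance():
    """Swapping (tp,tn) and (fp,fn) preserves accuracy and |MCC|."""
    rng = np.random.default_rng(14)
    for _ in range(20):
        tp, tn, fp, fn = (int(v) for v in rng.integers(0, 20, 4))
        if tp + tn + fp + fn == 0:
            continue
        a = classification_metrics(ConfusionCounts(tp, tn, fp, fn))
        b = classification_metrics(ConfusionCounts(tn, tp, fn, fp))
        assert a.acc == pytest.approx(b.acc)
        assert abs(a.mcc) == pytest.approx(abs(b.mcc))


def brute_force_rank_sum_p(x, y, alternative):
    """Full enumeration over label assignments, ranks recomputed from scratch."""
    pooled = np.concatenate([x, y])
    n = len(x)
    # mid-ranks via sorting (independent of scipy.rankdata)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    w_obs = ranks[:n].sum()
    from itertools import combinations

    total = comb(len(pooled), n)
    count = 0
    for idx in combinations(range(len(pooled)), n):
        w = ranks[list(idx)].sum()
        if alternative == "greater" and w >= w_obs - 1e-9:
            count += 1
        elif alternative == "less" and w <= w_obs + 1e-9:
            count += 1
    return count / total


def test_wilcoxon_textbook_example():
    """Fully separated samples of 3: one-sided p = 1/C(6,3) = 0.05."""
    res = wilcoxon_rank_sum([4, 5, 6], [1, 2, 3], "one_sided", "greater")
    assert res.statistic == pytest.approx(15.0)
    assert res.p_value == pytest.approx(0.05)


def test_wilcoxon_identical_samples():
    res = wilcoxon_rank_sum([1.0, 1.0, 1.0], [1.0, 1.0, 1.0], "two_sided")
    assert res.p_value == pytest.approx(1.0)


def test_wilcoxon_exact_matches_enumeration_oracle():
    rng = np.random.default_rng(15)
    for _ in range(40):
        n = int(rng.integers(1, 7))
        m = int(rng.integers(1, min(12 - n, 7) + 1))
        # mix of continuous values and ties
        x = np.round(rng.normal(size=n), 1)
        y = np.round(rng.normal(size=m), 1)
        for alt in ("greater", "less"):
            ours = wilcoxon_rank_sum(x, y, "one_sided", alt).p_value
            assert ours == pytest.approx(
                brute_force_rank_sum_p(x, y, alt), abs=1e-12
            )


def test_wilcoxon_approximation_matches_scipy():
    """Large samples: tie-corrected normal approximation vs scipy."""
    rng = np.random.default_rng(16)
    for _ in range(50):
        n = int(rng.integers(10, 30))
        m = int(rng.integers(10, 30))
        x = np.round(rng.normal(size=n), 1)
        y = np.round(rng.normal(0.3, size=m), 1)
        ours = wilcoxon_rank_sum(x, y, "one_sided", "greater").p_value
        ref = mannwhitneyu(
            x, y, alternative="greater", method="asymptotic", use_continuity=False
        ).pvalue
        assert ours == pytest.approx(ref, abs=1e-6)


def test_sidak_alpha():
    assert sidak_alpha(0.05, 1) == pytest.approx(0.05)
    assert sidak_alpha(0.05, 2) == pytest.approx(1 - 0.95**0.5, abs=1e-12)
    assert sidak_alpha(0.05, 2) == pytest.approx(0.025320566, abs=1e-6)
    alphas = [sidak_alpha(0.05, m) for m in range(1, 10)]
    assert all(a2 < a1 for a1, a2 in zip(alphas, alphas[1:]))
    with pytest.raises(ValueError):
        sidak_alpha(1.5, 2)
    with pytest.raises(ValueError):
        sidak_alpha(0.05, 0)


def test_scores_to_report_thresholding():
    rep = scores_to_report([0.9, 0.6, 0.4, 0.2], [1, 1, 0, 0])
    assert rep.auc == 1.0 and rep.acc == 1.0 and rep.f1 == 1.0 and rep.mcc == 1.0
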