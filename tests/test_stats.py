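"""Metrics and statistical tests, including the NA conventions and independent
oracles (hypergeometric enumeration for Fisher, closed-form Welch/t formulas)."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pdxomc.stats import (
    ConfusionCounts,
    confusion,
    fisher_two_sided,
    is_na,
    mcc,
    metric_set,
    paired_t,
    phi_coefficient,
    precision_recall_f1,
    roc_auc,
    t_test_two_sided,
)

# ---------------------------------------------------------------------------
# Confusion counts
# ---------------------------------------------------------------------------


def test_confusion_partitions_the_sample_set():
    cc = confusion([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
    assert (cc.tp, cc.tn, cc.fp, cc.fn) == (5, 5, 0, 0)
    inverted = confusion([0] * 5 + [1] * 5, [1] * 5 + [0] * 5)
    assert (inverted.tp, inverted.tn, inverted.fp, inverted.fn) == (0, 0, 5, 5)


def test_confusion_erlotinib_marker_breakdown():
    # 100 NSCLC tumours: 19 EGFR-mutant predicted sensitive (3 respond),
    # 81 wild-type predicted resistant (6 respond).
    pred = [1] * 19 + [0] * 81
    truth = [1] * 3 + [0] * 16 + [1] * 6 + [0] * 75
    cc = confusion(pred, truth)
    assert (cc.tp, cc.fp, cc.fn, cc.tn) == (3, 16, 6, 75)


def test_confusion_rejects_mismatched_or_nonbinary_input():
    with pytest.raises(ValueError):
        confusion([1, 0], [1, 0, 1])
    with pytest.raises(ValueError):
        confusion([1, 2], [1, 0])


# ---------------------------------------------------------------------------
# MCC / precision / recall / F1
# ---------------------------------------------------------------------------


def test_mcc_of_the_egfr_marker_is_weak():
    assert round(mcc(ConfusionCounts(tp=3, tn=75, fp=16, fn=6)), 2) == 0.11


def test_mcc_extremes():
    assert mcc(ConfusionCounts(5, 5, 0, 0)) == 1.0
    assert mcc(ConfusionCounts(0, 0, 5, 5)) == -1.0


def test_mcc_na_when_a_marginal_sum_is_zero():
    # never predicts resistant: TN + FN = 0
    assert is_na(mcc(ConfusionCounts(tp=2, tn=0, fp=2, fn=0)))
    # never predicts sensitive: TP + FP = 0
    assert is_na(mcc(ConfusionCounts(tp=0, tn=2, fp=0, fn=2)))


@given(
    st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50)
)
@settings(deadline=None, derandomize=True)
def test_mcc_symmetries(tp, tn, fp, fn):
    """Swapping classes leaves MCC unchanged; swapping predictions negates it."""
    if tp + tn + fp + fn == 0:
        return
    m = mcc(ConfusionCounts(tp, tn, fp, fn))
    swapped = mcc(ConfusionCounts(tn, tp, fn, fp))
    negated = mcc(ConfusionCounts(fp, fn, tp, tn))
    if is_na(m):
        assert is_na(swapped)
    else:
        assert m == pytest.approx(swapped)
        assert m == pytest.approx(-negated)


def test_precision_recall_of_the_egfr_marker():
    pr, rc, _, _ = precision_recall_f1(ConfusionCounts(tp=3, tn=75, fp=16, fn=6))
    assert round(pr * 100) == 16
    assert round(rc * 100) == 33


@pytest.mark.parametrize(
    "pr,rc,expected",
    [(0.77, 0.91, 0.83), (0.82, 0.88, 0.85), (0.62, 0.81, 0.70)],
)
def test_f1_harmonic_mean(pr, rc, expected):
    assert round(2 * pr * rc / (pr + rc), 2) == expected


def test_f1_zero_and_na_rules():
    # no true positives but predictions on both sides: PR = RC = 0 -> F1 = 0
    pr, rc, f1, _ = precision_recall_f1(ConfusionCounts(tp=0, tn=5, fp=2, fn=3))
    assert (pr, rc, f1) == (0.0, 0.0, 0.0)
    # never predicts sensitive: PR is NA, so F1 is NA too
    pr, rc, f1, _ = precision_recall_f1(ConfusionCounts(tp=0, tn=5, fp=0, fn=3))
    assert is_na(pr) and rc == 0.0 and is_na(f1)


def test_metric_set_collects_all_conventions():
    ms = metric_set(ConfusionCounts(tp=3, tn=75, fp=16, fn=6))
    assert round(ms.mcc, 2) == 0.11
    assert ms.specificity == pytest.approx(75 / 91)
    assert is_na(ms.auc)  # no scores supplied


# ---------------------------------------------------------------------------
# Fisher's exact test
# ---------------------------------------------------------------------------


def _fisher_enumeration_oracle(a, b, c, d):
    """Two-sided Fisher p by exhaustive enumeration over tables with the
    observed margins: sum the hypergeometric probabilities of every table no
    more likely than the observed one."""
    r1, n1, n = a + b, a + c, a + b + c + d
    p_obs = sps.hypergeom.pmf(a, n, n1, r1)
    total = 0.0
    for x in range(max(0, r1 - (n - n1)), min(r1, n1) + 1):
        px = sps.hypergeom.pmf(x, n, n1, r1)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


def test_fisher_equal_proportions_is_null():
    res = fisher_two_sided([[5, 5], [5, 5]])
    assert res.p_value == 1.0
    assert res.effect == 0.0


def test_fisher_perfect_separation():
    res = fisher_two_sided([[10, 0], [0, 10]])
    assert res.effect == 1.0
    assert res.p_value == pytest.approx(_fisher_enumeration_oracle(10, 0, 0, 10))


def test_fisher_degenerate_margin_is_uninformative():
    res = fisher_two_sided([[0, 0], [5, 5]])
    assert res.p_value == 1.0 and res.effect == 0.0


def test_fisher_matches_enumeration_on_small_tables():
    for a in range(5):
        for b in range(5):
            for c in range(5):
                for d in range(5):
                    if 0 in (a + b, c + d, a + c, b + d):
                        continue
                    got = fisher_two_sided([[a, b], [c, d]]).p_value
                    want = _fisher_enumeration_oracle(a, b, c, d)
                    assert got == pytest.approx(want, abs=1e-9), (a, b, c, d)


@given(st.integers(0, 20), st.integers(0, 20), st.integers(0, 20), st.integers(0, 20))
@settings(deadline=None, derandomize=True)
def test_phi_equals_mcc_formula_on_the_table(a, b, c, d):
    """The phi effect size of a 2x2 table is the MCC formula applied to its cells."""
    if 0 in (a + b, c + d, a + c, b + d):
        assert phi_coefficient(a, b, c, d) == 0.0
        return
    via_mcc = mcc(ConfusionCounts(tp=a, tn=d, fp=b, fn=c))
    assert phi_coefficient(a, b, c, d) == pytest.approx(via_mcc)


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------


def test_welch_identical_groups():
    res = t_test_two_sided([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == pytest.approx(1.0)
    assert res.effect == 0.0


def test_welch_matches_closed_form():
    rng = np.random.default_rng(1)
    a = rng.normal(0.0, 1.0, 12)
    b = rng.normal(1.5, 2.0, 9)
    res = t_test_two_sided(a, b)
    # independent recomputation of the Welch statistic and df
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2 * sps.t.sf(abs(t), df)
    assert res.p_value == pytest.approx(p)
    assert res.effect == pytest.approx(a.mean() - b.mean())


def test_welch_degenerate_conventions():
    # constant and equal: uninformative, ranked last
    assert t_test_two_sided([2.0, 2.0], [2.0, 2.0, 2.0]).p_value == 1.0
    # constant but separated: maximally informative
    assert t_test_two_sided([2.0, 2.0], [3.0, 3.0]).p_value == 0.0
    # too small a group: NA
    assert is_na(t_test_two_sided([1.0], [1.0, 2.0]).p_value)


def test_paired_t_identical_vectors_is_na():
    assert is_na(paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))


def test_paired_t_constant_positive_difference():
    a = np.arange(10, dtype=float)
    assert paired_t(a + 0.2, a, sides="one", direction="greater") < 1e-6
    assert paired_t(a + 0.2, a, sides="one", direction="less") == 1.0


def test_paired_t_matches_t_distribution_oracle():
    rng = np.random.default_rng(7)
    a = rng.normal(0.3, 1.0, 10)
    b = rng.normal(0.0, 1.0, 10)
    d = a - b
    t = d.mean() / (d.std(ddof=1) / math.sqrt(len(d)))
    assert paired_t(a, b, sides="two") == pytest.approx(2 * sps.t.sf(abs(t), len(d) - 1))
    assert paired_t(a, b, sides="one", direction="greater") == pytest.approx(
        sps.t.sf(t, len(d) - 1)
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def test_roc_perfect_ranking():
    curve = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
    assert curve.auc == pytest.approx(1.0)


def test_roc_binary_predictor_single_intermediate_point():
    """A hard 0/1 predictor has one intermediate ROC point and
    AUC = (TPR + 1 - FPR) / 2."""
    truth = [1] * 5 + [0] * 5
    scores = [1, 1, 1, 0, 0] + [1, 0, 0, 0, 0]  # TPR 0.6, FPR 0.2
    curve = roc_auc([float(s) for s in scores], truth)
    interior = [pt for pt in curve.points if pt not in ((0.0, 0.0), (1.0, 1.0))]
    assert interior == [(0.2, 0.6)]
    assert curve.auc == pytest.approx((0.6 + 1 - 0.2) / 2) == pytest.approx(0.7)


def test_roc_tied_scores_is_chance():
    assert roc_auc([0.5] * 8, [1, 0] * 4).auc == pytest.approx(0.5)


def test_roc_single_class_truth_has_no_auc():
    assert is_na(roc_auc([0.2, 0.8], [1, 1]).auc)


def test_roc_random_scores_near_chance():
    rng = np.random.default_rng(11)
    aucs = [
        roc_auc(rng.random(1000), rng.integers(0, 2, 1000)).auc for _ in range(5)
    ]
    assert 0.45 <= np.mean(aucs) <= 0.55
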