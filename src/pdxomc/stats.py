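"""Classification metrics and statistical tests with explicit NA conventions.

Binary classification of PDX response (positive = sensitive/responder) is
summarised by the Matthews Correlation Coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FN)(FN+TN)(TN+FP)(FP+TP)),

which is NA (returned as ``nan``) whenever any of the four marginal sums is
zero -- a classifier that never predicts one of the classes, or a test set
containing a single class, has no defined MCC. Precision, recall, specificity
and F1 follow the usual definitions with PR NA when TP+FP = 0, RC NA when
TP+FN = 0, F1 = 0 when PR = RC = 0 and F1 NA when either PR or RC is NA.
NA values propagate; they are never coerced to 0.

Univariate association tests (two-sided Fisher's exact test for binary
features, Welch's two-sided unpaired t-test for real-valued ones) and the
paired t-test used for model comparison are thin, convention-fixing wrappers
around scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "TestResult",
    "RocCurve",
    "confusion",
    "mcc",
    "precision_recall_f1",
    "metric_set",
    "fisher_two_sided",
    "phi_coefficient",
    "t_test_two_sided",
    "paired_t",
    "roc_auc",
    "is_na",
]

NA = float("nan")


def is_na(x: float) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts; positive = sensitive."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        counts = (self.tp, self.tn, self.fp, self.fn)
        if any(c < 0 for c in counts):
            raise ValueError("confusion counts must be non-negative")
        if sum(counts) < 1:
            raise ValueError("confusion counts must total at least 1")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Derived metrics; ``nan`` encodes NA."""

    mcc: float
    pr: float
    rc: float
    f1: float
    specificity: float
    auc: float = NA

    def as_dict(self) -> dict[str, float]:
        return {
            "mcc": self.mcc,
            "pr": self.pr,
            "rc": self.rc,
            "f1": self.f1,
            "specificity": self.specificity,
            "auc": self.auc,
        }


@dataclass(frozen=True)
class TestResult:
    """A p-value with an effect size (phi for 2x2 tables, mean difference for
    t-tests); ``direction`` is the sign of the effect."""

    p_value: float
    effect: float

    @property
    def direction(self) -> int:
        if is_na(self.effect) or self.effect == 0:
            return 0
        return 1 if self.effect > 0 else -1


def confusion(pred: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Confusion counts from per-sample predicted and observed classes.

    Classes are 1 (sensitive, the positive class) and 0 (resistant). The two
    vectors must be aligned sample-for-sample.
    """
    pred_a = np.asarray(pred, dtype=int)
    truth_a = np.asarray(truth, dtype=int)
    if pred_a.shape != truth_a.shape:
        raise ValueError("prediction and truth cover different sample sets")
    if pred_a.size == 0:
        raise ValueError("empty sample set")
    for arr in (pred_a, truth_a):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("classes must be binary 0/1")
    return ConfusionCounts(
        tp=int(((pred_a == 1) & (truth_a == 1)).sum()),
        tn=int(((pred_a == 0) & (truth_a == 0)).sum()),
        fp=int(((pred_a == 1) & (truth_a == 0)).sum()),
        fn=int(((pred_a == 0) & (truth_a == 1)).sum()),
    )


def mcc(cc: ConfusionCounts) -> float:
    """Matthews correlation coefficient; NA when any marginal sum is zero."""
    tp, tn, fp, fn = float(cc.tp), float(cc.tn), float(cc.fp), float(cc.fn)
    denom_terms = (tp + fn, fn + tn, tn + fp, fp + tp)
    if any(t == 0 for t in denom_terms):
        return NA
    return (tp * tn - fp * fn) / math.sqrt(math.prod(denom_terms))


def precision_recall_f1(cc: ConfusionCounts) -> tuple[float, float, float, float]:
    """(precision, recall, F1, specificity) with the NA conventions above."""
    pr = cc.tp / (cc.tp + cc.fp) if (cc.tp + cc.fp) > 0 else NA
    rc = cc.tp / (cc.tp + cc.fn) if (cc.tp + cc.fn) > 0 else NA
    spec = cc.tn / (cc.tn + cc.fp) if (cc.tn + cc.fp) > 0 else NA
    if is_na(pr) or is_na(rc):
        f1 = NA
    elif pr == 0 and rc == 0:
        f1 = 0.0
    else:
        f1 = 2 * pr * rc / (pr + rc)
    return pr, rc, f1, spec


def metric_set(cc: ConfusionCounts, auc: float = NA) -> MetricSet:
    pr, rc, f1, spec = precision_recall_f1(cc)
    return MetricSet(mcc=mcc(cc), pr=pr, rc=rc, f1=f1, specificity=spec, auc=auc)


def phi_coefficient(a: int, b: int, c: int, d: int) -> float:
    """Phi effect size of the 2x2 table [[a, b], [c, d]].

    With rows = altered/unaltered and columns = sensitive/resistant, phi > 0
    means the alteration is enriched among sensitive tumours (a sensitising
    marker). Numerically identical to the MCC formula applied to the table;
    0 for degenerate (zero-margin) tables.
    """
    margins = ((a + b), (c + d), (a + c), (b + d))
    if any(m == 0 for m in margins):
        return 0.0
    return (a * d - b * c) / math.sqrt(math.prod(float(m) for m in margins))


@lru_cache(maxsize=200_000)
def _fisher_cached(a: int, b: int, c: int, d: int) -> float:
    return float(sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def fisher_two_sided(table: Sequence[Sequence[int]]) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table with phi as effect size.

    The two-sided p-value sums the probabilities of all tables (with the same
    margins) no more likely than the observed one. Rows are altered/unaltered,
    columns sensitive/resistant. A zero row or column margin is degenerate:
    p = 1, phi = 0.
    """
    (a, b), (c, d) = table
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("table counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a + b + c + d < 1:
        raise ValueError("table must contain at least one observation")
    if 0 in ((a + b), (c + d), (a + c), (b + d)):
        return TestResult(p_value=1.0, effect=0.0)
    return TestResult(p_value=_fisher_cached(a, b, c, d),
                      effect=phi_coefficient(a, b, c, d))


def t_test_two_sided(
    values_a: Sequence[float],
    values_b: Sequence[float],
    equal_var: bool = False,
) -> TestResult:
    """Two-sided unpaired t-test (Welch by default) on two samples.

    ``effect`` is mean(a) - mean(b); with a = sensitive and b = resistant a
    positive effect means higher values in sensitive tumours. Conventions for
    degenerate inputs: a group with fewer than 2 values gives an NA result;
    two constant groups give p = 1 when equal (the feature carries no
    information and is ranked last) and p -> 0 when different (perfect
    separation).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        return TestResult(p_value=NA, effect=NA)
    effect = float(a.mean() - b.mean())
    if a.std() == 0.0 and b.std() == 0.0:
        return TestResult(p_value=1.0 if effect == 0.0 else 0.0, effect=effect)
    p = float(sps.ttest_ind(a, b, equal_var=equal_var).pvalue)
    if math.isnan(p):
        p = 1.0
    return TestResult(p_value=p, effect=effect)


def paired_t(
    a: Sequence[float],
    b: Sequence[float],
    sides: str = "two",
    direction: str = "greater",
) -> float:
    """Classical paired t-test on the differences a - b.

    ``sides`` is "one" or "two"; a one-sided test uses ``direction``
    ("greater": is a better than b?). All-zero differences give NA (there is
    nothing to test); a constant nonzero difference degenerates to p -> 0 on
    the consistent side (p -> 1 on the other).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be one-dimensional and equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diffs = a - b
    if np.all(diffs == 0):
        return NA
    if sides not in ("one", "two"):
        raise ValueError("sides must be 'one' or 'two'")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    if np.std(diffs) == 0.0:
        # zero-variance nonzero difference: the t statistic diverges
        if sides == "two":
            return 0.0
        consistent = (diffs[0] > 0) == (direction == "greater")
        return 0.0 if consistent else 1.0
    alternative = "two-sided" if sides == "two" else direction
    return float(sps.ttest_rel(a, b, alternative=alternative).pvalue)


@dataclass(frozen=True)
class RocCurve:
    """An ROC curve as (FPR, TPR) points from (0,0) to (1,1) with its
    trapezoidal AUC (nan when the truth contains a single class)."""

    points: tuple[tuple[float, float], ...]
    auc: float


def roc_auc(scores: Sequence[float], truth: Sequence[int]) -> RocCurve:
    """ROC curve over all distinct score thresholds, with trapezoidal AUC.

    ``scores`` are sensitivity probabilities in [0, 1]. A hard binary 0/1
    predictor yields a single intermediate point and AUC = (TPR + 1 - FPR)/2.
    Single-class truth has no ROC: the curve degenerates to the diagonal
    endpoints with NA AUC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(truth, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and truth cover different sample sets")
    if s.size and (s.min() < 0 or s.max() > 1):
        raise ValueError("scores must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        return RocCurve(points=((0.0, 0.0), (1.0, 1.0)), auc=NA)
    from sklearn.metrics import roc_curve as _sk_roc

    fpr, tpr, _ = _sk_roc(y, s, drop_intermediate=False)
    pts = tuple((float(f), float(t)) for f, t in zip(fpr, tpr))
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(points=pts, auc=auc)
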