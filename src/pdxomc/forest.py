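"""Class-weighted random forest for small binary-response cohorts.

The model-selection procedure in this package evaluates a full inner
leave-one-out cross-validation of a random forest for every candidate feature
subset of every outer training fold -- hundreds of thousands of forest fits on
cohorts of a few dozen PDXs. General-purpose implementations carry per-fit
overheads of hundreds of milliseconds at these sizes, so the hot path here is
a compact CART/gini forest compiled with numba: bootstrap resampling, a random
subset of m_try = floor(sqrt(#features)) candidate features per split, trees
grown to purity, and class-weighted impurity and leaf votes. The sensitivity
score of a test sample is the fraction of trees voting sensitive.

Class weighting counterbalances class imbalance by penalising minority-class
misclassification more: the minority class receives the majority-class
proportion as its weight and vice versa, so both classes contribute equal
total weight.

``NativeRandomForest`` is the default backend; ``SklearnRandomForest`` wraps
``sklearn.ensemble.RandomForestClassifier`` behind the same interface and
serves as an independent cross-check (and a drop-in alternative where speed
does not matter). Both are deterministic given their seed.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "NativeRandomForest",
    "SklearnRandomForest",
    "make_rf",
    "mtry_sqrt",
    "class_weights",
    "loocv_scores_native",
]

_SEED_MOD = 2**31 - 1


def mtry_sqrt(n_features: int) -> int:
    """Number of candidate features per split: floor(sqrt(k)), at least 1."""
    return max(1, int(math.isqrt(max(1, n_features))))


def class_weights(y: np.ndarray, enabled: bool = True) -> tuple[float, float]:
    """(w_sensitive, w_resistant): each class weighted by the *other* class's
    proportion, so the minority class carries the heavier per-sample penalty."""
    if not enabled:
        return 1.0, 1.0
    n = float(len(y))
    n1 = float(np.sum(y == 1))
    n0 = n - n1
    if n1 == 0 or n0 == 0:
        return 1.0, 1.0
    return n0 / n, n1 / n


@njit(cache=True, fastmath=True)
def _grow_and_vote(Xf, y, w1, w0, Xte_f, mtry, votes,
                   feat, thr, left, right, vote,
                   idx, stack_node, stack_lo, stack_hi,
                   featperm, vals, order):  # pragma: no cover - compiled
    # Xf / Xte_f are feature-major (k, n) matrices.
    k, n = Xf.shape
    for i in range(n):
        idx[i] = np.random.randint(0, n)
    n_nodes = 1
    stack_node[0] = 0
    stack_lo[0] = 0
    stack_hi[0] = n
    sp = 1
    while sp > 0:
        sp -= 1
        node = stack_node[sp]
        lo = stack_lo[sp]
        hi = stack_hi[sp]
        m = hi - lo
        sw1 = 0.0
        sw0 = 0.0
        for i in range(lo, hi):
            if y[idx[i]] == 1:
                sw1 += w1
            else:
                sw0 += w0
        if sw1 == 0.0 or sw0 == 0.0 or m < 2:
            feat[node] = -1
            vote[node] = 1 if sw1 > sw0 else 0
            continue
        for i in range(k):
            featperm[i] = i
        best_gain = 0.0
        best_f = -1
        best_thr = 0.0
        tried = 0
        tot = sw1 + sw0
        parent = 1.0 - ((sw1 / tot) ** 2 + (sw0 / tot) ** 2)
        # Draw features without replacement (partial Fisher-Yates); constant
        # features do not count towards mtry, mirroring the usual behaviour of
        # continuing the search when a drawn feature admits no split.
        for pos in range(k):
            r = pos + np.random.randint(0, k - pos)
            tmpf = featperm[pos]
            featperm[pos] = featperm[r]
            featperm[r] = tmpf
            f = featperm[pos]
            row = Xf[f]
            vmin = row[idx[lo]]
            vmax = vmin
            for i in range(lo + 1, hi):
                v = row[idx[i]]
                if v < vmin:
                    vmin = v
                elif v > vmax:
                    vmax = v
            if vmax <= vmin:
                continue
            tried += 1
            # insertion sort of node samples by feature value
            for i in range(m):
                v = row[idx[lo + i]]
                j = i - 1
                while j >= 0 and vals[j] > v:
                    vals[j + 1] = vals[j]
                    order[j + 1] = order[j]
                    j -= 1
                vals[j + 1] = v
                order[j + 1] = idx[lo + i]
            lw1 = 0.0
            lw0 = 0.0
            for i in range(m - 1):
                s = order[i]
                if y[s] == 1:
                    lw1 += w1
                else:
                    lw0 += w0
                if vals[i + 1] <= vals[i]:
                    continue
                lw = lw1 + lw0
                rw = tot - lw
                rw1 = sw1 - lw1
                rw0 = sw0 - lw0
                gl = lw - (lw1 * lw1 + lw0 * lw0) / lw
                gr = rw - (rw1 * rw1 + rw0 * rw0) / rw
                gain = parent - (gl + gr) / tot
                if gain > best_gain:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (vals[i] + vals[i + 1])
            if tried >= mtry:
                break
        if best_f < 0:
            feat[node] = -1
            vote[node] = 1 if sw1 > sw0 else 0
            continue
        row = Xf[best_f]
        i = lo
        j = hi - 1
        while i <= j:
            if row[idx[i]] <= best_thr:
                i += 1
            else:
                t2 = idx[i]
                idx[i] = idx[j]
                idx[j] = t2
                j -= 1
        mid = i
        if mid == lo or mid == hi:
            feat[node] = -1
            vote[node] = 1 if sw1 > sw0 else 0
            continue
        feat[node] = best_f
        thr[node] = best_thr
        left[node] = n_nodes
        right[node] = n_nodes + 1
        n_nodes += 2
        stack_node[sp] = left[node]
        stack_lo[sp] = lo
        stack_hi[sp] = mid
        sp += 1
        stack_node[sp] = right[node]
        stack_lo[sp] = mid
        stack_hi[sp] = hi
        sp += 1
    for t in range(Xte_f.shape[1]):
        node = 0
        while feat[node] >= 0:
            if Xte_f[feat[node], t] <= thr[node]:
                node = left[node]
            else:
                node = right[node]
        votes[t] += vote[node]


@njit(cache=True)
def _forest_votes(Xf, y, Xte_f, n_trees, mtry, w1, w0, seed):  # pragma: no cover
    np.random.seed(seed)
    k, n = Xf.shape
    max_nodes = 2 * n + 1
    feat = np.empty(max_nodes, np.int64)
    thr = np.empty(max_nodes, np.float64)
    left = np.empty(max_nodes, np.int64)
    right = np.empty(max_nodes, np.int64)
    vote = np.empty(max_nodes, np.int8)
    idx = np.empty(n, np.int64)
    stack_node = np.empty(max_nodes, np.int64)
    stack_lo = np.empty(max_nodes, np.int64)
    stack_hi = np.empty(max_nodes, np.int64)
    featperm = np.empty(k, np.int64)
    vals = np.empty(n, np.float64)
    order = np.empty(n, np.int64)
    votes = np.zeros(Xte_f.shape[1], np.float64)
    for _ in range(n_trees):
        _grow_and_vote(Xf, y, w1, w0, Xte_f, mtry, votes,
                       feat, thr, left, right, vote,
                       idx, stack_node, stack_lo, stack_hi, featperm, vals, order)
    return votes / n_trees


@njit(cache=True)
def _loocv_scores(Xf, y, n_trees, mtry, weighted, seed):  # pragma: no cover
    # Fused leave-one-out loop: one forest per fold, class weights recomputed
    # from each training fold. Returns the held-out sensitivity scores.
    k, n = Xf.shape
    out = np.empty(n, np.float64)
    Xtr = np.empty((k, n - 1), np.float64)
    ytr = np.empty(n - 1, np.int8)
    Xte = np.empty((k, 1), np.float64)
    for i in range(n):
        p = 0
        n1 = 0
        for j in range(n):
            if j == i:
                continue
            for f in range(k):
                Xtr[f, p] = Xf[f, j]
            ytr[p] = y[j]
            if y[j] == 1:
                n1 += 1
            p += 1
        n0 = (n - 1) - n1
        for f in range(k):
            Xte[f, 0] = Xf[f, i]
        if n1 == 0 or n0 == 0:
            # degenerate training fold: majority-class vote
            out[i] = 1.0 if n1 > n0 else 0.0
            continue
        if weighted:
            w1 = n0 / (n - 1.0)
            w0 = n1 / (n - 1.0)
        else:
            w1 = 1.0
            w0 = 1.0
        out[i] = _forest_votes(
            Xtr, ytr, Xte, n_trees, mtry, w1, w0, (seed + i) % 2147483647
        )[0]
    return out


def loocv_scores_native(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int,
    seed: int,
    class_weighting: bool = True,
) -> np.ndarray:
    """LOOCV sensitivity scores of the native forest on (samples x features) X.

    One forest per fold, seeded deterministically from ``seed`` and the fold
    index; a fold whose training data collapses to a single class scores the
    held-out sample as that majority class (0 or 1).
    """
    X = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
    y = np.asarray(y, dtype=np.int8)
    if X.shape[1] != y.shape[0]:
        raise ValueError("X and y disagree on sample count")
    if X.shape[1] < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    mtry = mtry_sqrt(X.shape[0])
    return _loocv_scores(X, y, int(n_trees), mtry, class_weighting, int(seed) % _SEED_MOD)


class NativeRandomForest:
    """numba-backed class-weighted random forest (the default backend).

    The fitted model keeps its training data and rebuilds the (deterministic,
    seed-defined) forest on each ``predict_score`` call; at the cohort sizes
    this package targets a rebuild costs well under a millisecond per tree and
    avoids persisting tree structures.
    """

    def __init__(self, n_trees: int = 1000, class_weighting: bool = True, seed: int = 0):
        if n_trees < 10:
            raise ValueError("n_trees must be at least 10")
        self.n_trees = int(n_trees)
        self.class_weighting = bool(class_weighting)
        self.seed = int(seed) % _SEED_MOD
        self._Xf: np.ndarray | None = None
        self._y: np.ndarray | None = None

    @property
    def mtry(self) -> int:
        if self._Xf is None:
            raise RuntimeError("model not fitted")
        return mtry_sqrt(self._Xf.shape[0])

    def fit(self, X: np.ndarray, y: np.ndarray) -> "NativeRandomForest":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.int8)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        self._Xf = np.ascontiguousarray(X.T)
        self._y = y
        self._w1, self._w0 = class_weights(y, self.class_weighting)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        """Sensitivity score per sample: fraction of trees voting sensitive."""
        if self._Xf is None:
            raise RuntimeError("model not fitted")
        Xte = np.ascontiguousarray(np.asarray(X, dtype=np.float64).T)
        return _forest_votes(
            self._Xf, self._y, Xte, self.n_trees, self.mtry,
            self._w1, self._w0, self.seed,
        )


class SklearnRandomForest:
    """scikit-learn backend with the same contract as :class:`NativeRandomForest`."""

    def __init__(self, n_trees: int = 1000, class_weighting: bool = True, seed: int = 0):
        if n_trees < 10:
            raise ValueError("n_trees must be at least 10")
        self.n_trees = int(n_trees)
        self.class_weighting = bool(class_weighting)
        self.seed = int(seed) % _SEED_MOD
        self._clf = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SklearnRandomForest":
        from sklearn.ensemble import RandomForestClassifier

        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        w1, w0 = class_weights(y, self.class_weighting)
        self._clf = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features="sqrt",
            class_weight={1: w1, 0: w0},
            random_state=self.seed,
            n_jobs=1,
        ).fit(np.asarray(X, dtype=float), y)
        return self

    def predict_score(self, X: np.ndarray) -> np.ndarray:
        if self._clf is None:
            raise RuntimeError("model not fitted")
        proba = self._clf.predict_proba(np.asarray(X, dtype=float))
        pos = list(self._clf.classes_).index(1)
        return proba[:, pos]


def make_rf(backend: str, n_trees: int, class_weighting: bool, seed: int):
    if backend == "native":
        return NativeRandomForest(n_trees, class_weighting, seed)
    if backend == "sklearn":
        return SklearnRandomForest(n_trees, class_weighting, seed)
    raise ValueError(f"unknown random-forest backend {backend!r}")
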