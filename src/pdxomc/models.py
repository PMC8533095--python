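"""The four model families and their cross-validation drivers.

* **RF-all** -- a class-weighted random forest trained on every feature of a
  profile, evaluated by standard leave-one-out cross-validation (LOOCV).
* **RF-OMC** -- a random forest wrapped in Optimal Model Complexity selection:
  features are ranked univariately on the training fold, candidate models are
  trained on the top-2, top-3, ..., top-floor(n/2) features plus one on all
  features, each candidate is scored by its inner-LOOCV MCC, and the best
  candidate (ties going to the smaller, more parsimonious subset) is refitted
  on the whole training fold. Performance is estimated by *nested* LOOCV: the
  selection runs inside each outer training fold, so the held-out PDX never
  influences ranking, selection or training.
* **Single-gene marker** -- the classical actionable-mutation baseline: in each
  training fold the gene whose mutation status is most significantly
  associated with sensitivity (lowest Fisher p among genes with phi > 0) is
  chosen, and the held-out PDX is predicted sensitive iff it carries an SNV in
  that gene.
* **Random controls** -- a prior-probability coin flip per fold, and RF on a
  uniformly random feature subset of the same size as an OMC selection.

All drivers are pure functions of (data, configuration, seed).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .datamodel import CaseDataset
from .forest import loocv_scores_native, make_rf
from .ranking import RankedFeatures, rank_features, top_k
from .stats import MetricSet, confusion, is_na, mcc, metric_set, roc_auc

logger = logging.getLogger(__name__)

__all__ = [
    "RFConfig",
    "FoldPrediction",
    "OMCModelTrace",
    "ALL_FEATURES",
    "train_rf",
    "loocv",
    "rf_all_loocv",
    "rf_omc_select",
    "nested_loocv_rf_omc",
    "single_gene_marker_loocv",
    "final_single_gene_marker",
    "random_prior_baseline",
    "random_feature_rf",
    "predictions_to_metrics",
]

_SEED_MOD = 2**31 - 1

#: Sentinel for "use every feature of the profile".
ALL_FEATURES = "ALL"


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters and run options.

    1000 trees and m_try = floor(sqrt(#features)) are robust defaults for
    binary classification and are deliberately not tuned per training set.
    ``n_trees`` may be lowered (>= 10) for desk-scale runs: with the very small
    feature subsets OMC tends to select, a few dozen trees behave like a
    thousand. ``backend`` selects the forest implementation ("native", the
    compiled default, or "sklearn").
    """

    n_trees: int = 1000
    mtry_rule: str = "sqrt"
    class_weighting: bool = True
    seed: int = 0
    backend: str = "native"
    decision_threshold: float = 0.5
    rerank_per_inner_fold: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 10:
            raise ValueError("n_trees must be at least 10")
        if self.mtry_rule != "sqrt":
            raise ValueError("only the sqrt m_try rule is supported")
        if not 0.0 < self.decision_threshold < 1.0:
            raise ValueError("decision threshold must lie in (0, 1)")

    def with_seed(self, seed: int) -> "RFConfig":
        return RFConfig(
            n_trees=self.n_trees,
            mtry_rule=self.mtry_rule,
            class_weighting=self.class_weighting,
            seed=int(seed),
            backend=self.backend,
            decision_threshold=self.decision_threshold,
            rerank_per_inner_fold=self.rerank_per_inner_fold,
        )


@dataclass(frozen=True)
class FoldPrediction:
    """Held-out prediction for one PDX: classes are 1 sensitive / 0 resistant;
    ``score`` is the model's sensitivity probability."""

    pdx_id: str
    truth: int
    predicted: int
    score: float


@dataclass(frozen=True)
class OMCModelTrace:
    """Record of one OMC selection on a training fold."""

    candidate_sizes: tuple[object, ...]        # ints plus the ALL sentinel
    inner_mcc: tuple[float, ...]               # nan encodes NA
    selected_size: object                      # int or ALL sentinel
    selected_features: tuple[str, ...]
    train_sample_ids: tuple[str, ...]

    @property
    def best_inner_mcc(self) -> float:
        numeric = [m for m in self.inner_mcc if not is_na(m)]
        return max(numeric) if numeric else float("nan")


def train_rf(train: CaseDataset, feature_subset: Sequence[str] | str, cfg: RFConfig):
    """Fit a class-weighted RF on a training fold restricted to a feature subset.

    ``feature_subset`` is a list of feature ids or the ``ALL_FEATURES``
    sentinel. Returns a fitted model exposing ``predict_score``.
    """
    if isinstance(feature_subset, str):
        if feature_subset != ALL_FEATURES:
            raise ValueError("feature_subset must be a list of ids or ALL_FEATURES")
        features = train.features
    else:
        if len(feature_subset) == 0:
            raise ValueError("feature subset must be non-empty")
        features = train.features.select_features(feature_subset)
    if train.degenerate:
        raise ValueError("cannot train on a single-class fold")
    model = make_rf(cfg.backend, cfg.n_trees, cfg.class_weighting, cfg.seed)
    model.fit(features.to_numpy(), train.y())
    model.feature_ids = features.feature_ids
    return model


def loocv(
    recipe: Callable[[CaseDataset, int], object],
    case: CaseDataset,
    cfg: RFConfig,
) -> list[FoldPrediction]:
    """Generic LOOCV driver: each PDX is held out once and predicted by a model
    the ``recipe`` builds from the remaining n-1 PDXs.

    ``recipe(train, seed)`` must return an object with
    ``predict_score(X) -> array``. All per-fold computation sees only the
    training fold. A fold whose training data degenerates to one class falls
    back to the training majority class (logged).
    """
    if case.n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    preds: list[FoldPrediction] = []
    sample_ids = case.features.sample_ids
    for i, pdx in enumerate(sample_ids):
        train = case.drop_sample(pdx)
        truth = int(case.classes.loc[pdx])
        x_test = case.features.values.loc[[pdx]].to_numpy()
        if train.degenerate:
            majority = 1 if train.n_sensitive > train.n_resistant else 0
            logger.warning("fold %s degenerate; predicting training majority", pdx)
            preds.append(FoldPrediction(pdx, truth, majority, float(majority)))
            continue
        model = recipe(train, (cfg.seed + i) % _SEED_MOD)
        if hasattr(model, "feature_ids"):
            cols = [case.features.feature_ids.index(f) for f in model.feature_ids]
            x_in = x_test[:, cols]
        else:
            x_in = x_test
        score = float(model.predict_score(x_in)[0])
        preds.append(
            FoldPrediction(pdx, truth, int(score > cfg.decision_threshold), score)
        )
    return preds


def _loocv_scores(case: CaseDataset, feature_ids: Sequence[str] | str, cfg: RFConfig) -> np.ndarray:
    """LOOCV sensitivity scores for an RF on a fixed feature subset."""
    if isinstance(feature_ids, str):
        X = case.features.to_numpy()
    else:
        X = case.features.select_features(feature_ids).to_numpy()
    if cfg.backend == "native":
        return loocv_scores_native(
            X, case.y(), cfg.n_trees, cfg.seed, cfg.class_weighting
        )
    # generic per-fold loop for non-native backends
    def recipe(train: CaseDataset, seed: int):
        sub = feature_ids if isinstance(feature_ids, str) else list(feature_ids)
        return train_rf(train, sub, cfg.with_seed(seed))

    return np.array([p.score for p in loocv(recipe, case, cfg)])


def rf_all_loocv(case: CaseDataset, cfg: RFConfig) -> list[FoldPrediction]:
    """Standard LOOCV of the class-weighted RF on all features (RF-all)."""
    scores = _loocv_scores(case, ALL_FEATURES, cfg)
    return _scores_to_predictions(case, scores, cfg.decision_threshold)


def _scores_to_predictions(
    case: CaseDataset, scores: np.ndarray, threshold: float
) -> list[FoldPrediction]:
    return [
        FoldPrediction(pdx, int(t), int(s > threshold), float(s))
        for pdx, t, s in zip(case.features.sample_ids, case.y(), scores)
    ]


def _candidate_sizes(n: int, n_features: int) -> list[object]:
    sizes: list[object] = [k for k in range(2, n // 2 + 1) if k < n_features]
    sizes.append(ALL_FEATURES)
    return sizes


def rf_omc_select(
    train: CaseDataset,
    cfg: RFConfig,
    ranked: RankedFeatures | None = None,
) -> OMCModelTrace:
    """Select the optimal model complexity on a training fold.

    Features are ranked once on the full training fold and candidate subsets
    top-2 ... top-floor(n/2) plus all features are each scored by the MCC of
    an inner LOOCV of the RF restricted to that subset. The candidate with the
    highest inner MCC wins; NA is worse than any numeric value and ties go to
    the smaller subset (all-features counting as the largest). The stricter
    ``rerank_per_inner_fold`` mode re-ranks features inside every inner
    training fold before taking the top k.
    """
    if train.n < 6:
        raise ValueError("OMC selection needs a training fold of at least 6 PDXs")
    if train.degenerate:
        raise ValueError("cannot select a model on a single-class training fold")
    if ranked is None:
        ranked = rank_features(train)
    sizes = _candidate_sizes(train.n, train.features.n_features)
    inner_mccs: list[float] = []
    for k in sizes:
        if cfg.rerank_per_inner_fold and k != ALL_FEATURES:
            scores = _rerank_inner_scores(train, int(k), cfg)
        else:
            subset = ALL_FEATURES if k == ALL_FEATURES else top_k(ranked, int(k))
            scores = _loocv_scores(train, subset, cfg)
        preds = (scores > cfg.decision_threshold).astype(int)
        inner_mccs.append(mcc(confusion(preds, train.y())))

    best_idx = _select_candidate(sizes, inner_mccs, train.features.n_features)
    selected = sizes[best_idx]
    if selected == ALL_FEATURES:
        selected_features = tuple(train.features.feature_ids)
    else:
        selected_features = tuple(top_k(ranked, int(selected)))
    return OMCModelTrace(
        candidate_sizes=tuple(sizes),
        inner_mcc=tuple(inner_mccs),
        selected_size=selected,
        selected_features=selected_features,
        train_sample_ids=tuple(train.features.sample_ids),
    )


def _select_candidate(sizes: list[object], mccs: list[float], n_features: int) -> int:
    def sort_key(i: int) -> tuple:
        m = mccs[i]
        numeric = not is_na(m)
        size = n_features if sizes[i] == ALL_FEATURES else int(sizes[i])
        # maximise MCC (NA last), then prefer the smaller subset
        return (0 if numeric else 1, -(m if numeric else 0.0), size)

    return min(range(len(sizes)), key=sort_key)


def _rerank_inner_scores(train: CaseDataset, k: int, cfg: RFConfig) -> np.ndarray:
    scores = np.empty(train.n)
    for i, pdx in enumerate(train.features.sample_ids):
        inner_train = train.drop_sample(pdx)
        if inner_train.degenerate:
            scores[i] = float(inner_train.n_sensitive > inner_train.n_resistant)
            continue
        inner_ranked = rank_features(inner_train)
        subset = top_k(inner_ranked, min(k, len(inner_ranked)))
        model = train_rf(inner_train, subset, cfg.with_seed((cfg.seed + i) % _SEED_MOD))
        x = train.features.select_features(subset).values.loc[[pdx]].to_numpy()
        scores[i] = float(model.predict_score(x)[0])
    return scores


def nested_loocv_rf_omc(
    case: CaseDataset, cfg: RFConfig
) -> tuple[list[FoldPrediction], list[OMCModelTrace]]:
    """Nested LOOCV of RF-OMC: per outer fold, run the full OMC selection on
    the training fold, refit on the selected subset and predict the held-out
    PDX. Returns the outer predictions and one selection trace per fold.
    """
    if case.n < 7:
        raise ValueError("nested LOOCV needs at least 7 samples")
    preds: list[FoldPrediction] = []
    traces: list[OMCModelTrace] = []
    for i, pdx in enumerate(case.features.sample_ids):
        train = case.drop_sample(pdx)
        truth = int(case.classes.loc[pdx])
        if train.degenerate:
            majority = 1 if train.n_sensitive > train.n_resistant else 0
            logger.warning("outer fold %s degenerate; majority fallback", pdx)
            preds.append(FoldPrediction(pdx, truth, majority, float(majority)))
            traces.append(OMCModelTrace((), (), ALL_FEATURES, (),
                                        tuple(train.features.sample_ids)))
            continue
        trace = rf_omc_select(train, cfg)
        model = train_rf(
            train, list(trace.selected_features), cfg.with_seed((cfg.seed + i) % _SEED_MOD)
        )
        x = case.features.select_features(list(trace.selected_features))
        score = float(model.predict_score(x.values.loc[[pdx]].to_numpy())[0])
        preds.append(
            FoldPrediction(pdx, truth, int(score > cfg.decision_threshold), score)
        )
        traces.append(trace)
    return preds, traces


# ---------------------------------------------------------------------------
# Single-gene marker
# ---------------------------------------------------------------------------

def _best_sensitising_gene(train: CaseDataset) -> tuple[str, float, float] | None:
    """Lowest-p gene with phi > 0 in the training fold, or None."""
    ranked = rank_features(train)
    table = ranked.table
    sensitising = table[table["effect"] > 0]
    if sensitising.empty:
        return None
    row = sensitising.iloc[0]
    return str(row["feature_id"]), float(row["p_value"]), float(row["effect"])


def single_gene_marker_loocv(
    case: CaseDataset,
) -> tuple[list[FoldPrediction], list[str | None]]:
    """LOOCV of the best single-gene marker.

    Per fold, the most significant sensitising gene (lowest two-sided Fisher
    p-value among genes with phi > 0) is chosen on the training fold; the
    held-out PDX is predicted sensitive iff an SNV is detected in that gene.
    When no sensitising gene exists, the fold predicts resistant (no marker,
    no sensitivity call). Scores are hard 0/1.
    """
    if not case.profile_kind.is_binary:
        raise ValueError("single-gene markers require a binary (SNV) profile")
    preds: list[FoldPrediction] = []
    genes: list[str | None] = []
    for pdx in case.features.sample_ids:
        train = case.drop_sample(pdx)
        truth = int(case.classes.loc[pdx])
        if train.degenerate:
            preds.append(FoldPrediction(pdx, truth, 0, 0.0))
            genes.append(None)
            continue
        best = _best_sensitising_gene(train)
        if best is None:
            logger.info("fold %s: no sensitising gene; predicting resistant", pdx)
            preds.append(FoldPrediction(pdx, truth, 0, 0.0))
            genes.append(None)
            continue
        gene, _, _ = best
        mutated = case.features.values.loc[pdx, gene] == 1.0
        preds.append(FoldPrediction(pdx, truth, int(mutated), float(mutated)))
        genes.append(gene)
    return preds, genes


def final_single_gene_marker(case: CaseDataset) -> tuple[str, float, float] | None:
    """The best sensitising gene recalculated on all samples (the marker ready
    to be applied to forthcoming tumours): (gene, p_value, phi), or None when
    no gene has phi > 0."""
    if not case.profile_kind.is_binary:
        raise ValueError("single-gene markers require a binary (SNV) profile")
    return _best_sensitising_gene(case)


# ---------------------------------------------------------------------------
# Random controls
# ---------------------------------------------------------------------------

def random_prior_baseline(case: CaseDataset, seed: int) -> list[FoldPrediction]:
    """Prior-probability random model.

    Per LOOCV fold, the sensitive proportion of the training fold estimates
    the probability that the held-out PDX is sensitive; a uniform draw below
    that estimate predicts sensitive. One full pass yields one MCC.
    """
    if case.n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    rng = np.random.default_rng(seed)
    preds: list[FoldPrediction] = []
    for pdx in case.features.sample_ids:
        train = case.drop_sample(pdx)
        truth = int(case.classes.loc[pdx])
        prior = train.n_sensitive / train.n
        predicted = int(rng.random() < prior)
        preds.append(FoldPrediction(pdx, truth, predicted, float(predicted)))
    return preds


def random_feature_rf(
    case: CaseDataset,
    k: int,
    cfg: RFConfig,
    seeds: Sequence[int],
) -> list[MetricSet]:
    """LOOCV of an RF on ``k`` uniformly sampled features, one replicate per
    seed (the control for whether OMC-selected subsets beat chance subsets).
    NA metrics propagate."""
    if k > case.features.n_features:
        raise ValueError("k exceeds the number of available features")
    out: list[MetricSet] = []
    for seed in seeds:
        rng = np.random.default_rng(seed)
        chosen = list(
            rng.choice(case.features.feature_ids, size=k, replace=False)
        )
        scores = _loocv_scores(case, chosen, cfg.with_seed(seed))
        preds = _scores_to_predictions(case, scores, cfg.decision_threshold)
        out.append(predictions_to_metrics(preds))
    return out


def predictions_to_metrics(preds: Sequence[FoldPrediction]) -> MetricSet:
    """Summarise held-out predictions into the full metric set (MCC, PR, RC,
    F1, specificity and trapezoidal AUC over the score thresholds)."""
    truth = [p.truth for p in preds]
    predicted = [p.predicted for p in preds]
    scores = [p.score for p in preds]
    cc = confusion(predicted, truth)
    curve = roc_auc(scores, truth)
    return metric_set(cc, auc=curve.auc)
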