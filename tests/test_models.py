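"""Model drivers: LOOCV mechanics, OMC selection, single-gene markers and the
random controls."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import pdxomc as p
from pdxomc.models import ALL_FEATURES, _select_candidate
from pdxomc.stats import is_na


def _snv_case(values: pd.DataFrame, classes) -> p.CaseDataset:
    fm = p.FeatureMatrix(values, p.ProfileKind.SNV)
    return p.CaseDataset(
        "t", "SYNTH", fm, pd.Series(classes, index=fm.sample_ids), min_n=2
    )


# ---------------------------------------------------------------------------
# train_rf / loocv
# ---------------------------------------------------------------------------


def test_train_rf_on_subset_and_mtry(tiny_case):
    cfg = p.RFConfig(n_trees=20, seed=0)
    model = p.train_rf(tiny_case, ["PERFECT", "NOISY"], cfg)
    assert model.mtry == 1  # floor(sqrt(2))
    scores = model.predict_score(
        tiny_case.features.select_features(["PERFECT", "NOISY"]).to_numpy()
    )
    assert (scores[tiny_case.y() == 1] > 0.5).all()
    with pytest.raises(ValueError, match="non-empty"):
        p.train_rf(tiny_case, [], cfg)


def test_loocv_visits_each_pdx_exactly_once(strong_case):
    cfg = p.RFConfig(n_trees=20, seed=0)
    preds = p.rf_all_loocv(strong_case, cfg)
    assert len(preds) == strong_case.n
    assert [q.pdx_id for q in preds] == strong_case.features.sample_ids
    assert all(q.truth == int(strong_case.classes.loc[q.pdx_id]) for q in preds)


def test_loocv_reproducible_with_same_seed(strong_case):
    cfg = p.RFConfig(n_trees=20, seed=7)
    a = p.rf_all_loocv(strong_case, cfg)
    b = p.rf_all_loocv(strong_case, cfg)
    assert a == b


def test_always_sensitive_recipe_has_full_recall_no_specificity(tiny_case):
    class Always:
        def predict_score(self, X):
            return np.ones(len(X))

    preds = p.loocv(lambda train, seed: Always(), tiny_case, p.RFConfig(n_trees=10))
    ms = p.predictions_to_metrics(preds)
    assert ms.rc == 1.0
    assert ms.specificity == 0.0
    assert is_na(ms.mcc)  # never predicts resistant -> TN + FN = 0


# ---------------------------------------------------------------------------
# OMC selection
# ---------------------------------------------------------------------------


def test_omc_candidate_grid_counts():
    """A training fold of n = 38 yields 19 candidates: sizes 2..19 plus all."""
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        (rng.random((38, 60)) < 0.3).astype(float),
        index=[f"s{i}" for i in range(38)],
        columns=[f"g{j:02d}" for j in range(60)],
    )
    case = _snv_case(values, [1] * 19 + [0] * 19)
    trace = p.rf_omc_select(case, p.RFConfig(n_trees=10, seed=0))
    assert len(trace.candidate_sizes) == 19
    assert list(trace.candidate_sizes[:-1]) == list(range(2, 20))
    assert trace.candidate_sizes[-1] == ALL_FEATURES
    assert len(trace.inner_mcc) == 19


def test_omc_selection_rule_prefers_parsimony_and_drops_na():
    sizes = [2, 3, 4, ALL_FEATURES]
    # tie between sizes 3 and 4 -> smaller wins
    assert _select_candidate(sizes, [0.1, 0.5, 0.5, 0.2], 100) == 1
    # NA is worse than any numeric value
    assert _select_candidate(sizes, [float("nan"), -0.9, float("nan"), float("nan")], 100) == 1
    # tie between a size and ALL -> the size wins (ALL counts as largest)
    assert _select_candidate(sizes, [0.3, 0.1, 0.1, 0.3], 100) == 0


def test_omc_selects_informative_subset_on_planted_signal(strong_cohort, strong_case):
    trace = p.rf_omc_select(strong_case, p.RFConfig(n_trees=50, seed=1))
    assert trace.selected_size != ALL_FEATURES
    planted = set(strong_cohort.planted_ids[p.ProfileKind.SNV])
    assert len(set(trace.selected_features) & planted) >= 2
    assert trace.best_inner_mcc > 0.5


def test_omc_requires_a_viable_training_fold(tiny_case):
    with pytest.raises(ValueError, match="at least 6"):
        p.rf_omc_select(tiny_case.subset(tiny_case.features.sample_ids[:5]),
                        p.RFConfig(n_trees=10))


# ---------------------------------------------------------------------------
# Nested LOOCV
# ---------------------------------------------------------------------------


def test_nested_loocv_fold_count_and_leakage(strong_case):
    cfg = p.RFConfig(n_trees=20, seed=0)
    preds, traces = p.nested_loocv_rf_omc(strong_case, cfg)
    assert len(preds) == len(traces) == strong_case.n
    for pred, trace in zip(preds, traces):
        # the held-out PDX never enters ranking, selection or training
        assert pred.pdx_id not in trace.train_sample_ids
        assert len(trace.train_sample_ids) == strong_case.n - 1


def test_nested_close_to_plain_loocv_on_strong_signal(strong_case):
    """With unambiguous signal, the nested estimate should sit near the
    non-nested LOOCV MCC of a model using the (stable) selected subset."""
    cfg = p.RFConfig(n_trees=50, seed=2)
    preds, traces = p.nested_loocv_rf_omc(strong_case, cfg)
    nested_mcc = p.predictions_to_metrics(preds).mcc
    trace = p.rf_omc_select(strong_case, cfg)
    from pdxomc.models import _loocv_scores, _scores_to_predictions

    scores = _loocv_scores(strong_case, list(trace.selected_features), cfg)
    plain = p.predictions_to_metrics(
        _scores_to_predictions(strong_case, scores, 0.5)
    ).mcc
    assert abs(nested_mcc - plain) <= 0.15


def test_selection_bias_visible_only_in_inner_estimates(selection_bias_run):
    """On label-permuted data the inner-LOOCV maximum looks predictive while
    the nested outer estimate stays at chance -- the reason nested CV exists."""
    mean_best_inner = float(np.nanmean(selection_bias_run["best_inner"]))
    mean_outer = float(np.nanmean(selection_bias_run["outer_mcc"]))
    assert mean_best_inner > 0.15
    assert -0.15 <= mean_outer <= 0.15


def test_recovery_of_planted_features(recovery_run):
    """Most replicates recover at least 2 of the 3 planted markers in the
    union of per-fold selections."""
    assert sum(r >= 2 for r in recovery_run["n_recovered"]) >= 8


# ---------------------------------------------------------------------------
# Single-gene marker
# ---------------------------------------------------------------------------


def test_single_gene_marker_chooses_perfect_separator(tiny_case):
    preds, genes = p.single_gene_marker_loocv(tiny_case)
    assert set(g for g in genes if g) == {"PERFECT"}
    ms = p.predictions_to_metrics(preds)
    assert ms.mcc == pytest.approx(1.0)


def test_single_gene_marker_all_wild_type_predicts_resistant():
    values = pd.DataFrame(
        0.0, index=[f"s{i}" for i in range(8)], columns=["g1", "g2"]
    )
    case = _snv_case(values, [1, 1, 1, 1, 0, 0, 0, 0])
    preds, genes = p.single_gene_marker_loocv(case)
    assert all(q.predicted == 0 for q in preds)
    assert all(g is None for g in genes)
    assert p.final_single_gene_marker(case) is None


def test_single_gene_fold_choice_matches_fisher_scan_oracle():
    rng = np.random.default_rng(12)
    n = 16
    classes = np.array([1] * 8 + [0] * 8)
    values = pd.DataFrame(
        (rng.random((n, 20)) < 0.3).astype(float),
        index=[f"s{i}" for i in range(n)],
        columns=[f"g{j:02d}" for j in range(20)],
    )
    case = _snv_case(values, classes)
    _, genes = p.single_gene_marker_loocv(case)
    for i, pdx in enumerate(case.features.sample_ids):
        keep = [s for s in case.features.sample_ids if s != pdx]
        sub = values.loc[keep]
        y = classes[[case.features.sample_ids.index(s) for s in keep]]
        best = None  # exhaustive scan: (p, -phi, gene)
        for gene in values.columns:
            x = sub[gene].to_numpy()
            a = int(x[y == 1].sum())
            b = int(x[y == 0].sum())
            n1, n0 = int((y == 1).sum()), int((y == 0).sum())
            table = [[a, b], [n1 - a, n0 - b]]
            from pdxomc.stats import fisher_two_sided

            res = fisher_two_sided(table)
            if res.effect > 0:
                key = (res.p_value, -abs(res.effect), gene)
                if best is None or key < best:
                    best = key
        want = best[2] if best else None
        assert genes[i] == want, f"fold {pdx}"


def test_final_marker_tie_breaks_deterministically():
    values = pd.DataFrame(
        {
            "b_gene": [1, 1, 1, 0, 0, 0],
            "a_gene": [1, 1, 1, 0, 0, 0],  # identical association
        },
        index=[f"s{i}" for i in range(6)],
        dtype=float,
    )
    case = _snv_case(values, [1, 1, 1, 0, 0, 0])
    gene, _, phi = p.final_single_gene_marker(case)
    assert gene == "a_gene"  # equal p and |phi|: lexicographic id order
    assert phi == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Random controls
# ---------------------------------------------------------------------------


def test_random_prior_is_seed_deterministic(strong_case):
    a = p.random_prior_baseline(strong_case, seed=5)
    b = p.random_prior_baseline(strong_case, seed=5)
    c = p.random_prior_baseline(strong_case, seed=6)
    assert a == b and a != c


def test_random_prior_follows_training_fold_prior():
    # 7 sensitive, 1 resistant: when the resistant PDX is held out the
    # training fold is all-sensitive (prior 1) and must predict sensitive
    values = pd.DataFrame(
        0.0, index=[f"s{i}" for i in range(8)], columns=["g"]
    )
    case = _snv_case(values, [1] * 7 + [0])
    for seed in range(5):
        preds = p.random_prior_baseline(case, seed=seed)
        assert preds[-1].predicted == 1


def test_random_feature_rf_control(strong_case):
    cfg = p.RFConfig(n_trees=20)
    results = p.random_feature_rf(strong_case, k=3, cfg=cfg, seeds=range(3))
    assert len(results) == 3
    with pytest.raises(ValueError, match="exceeds"):
        p.random_feature_rf(strong_case, k=10_000, cfg=cfg, seeds=[0])


def test_random_features_lose_to_omc_selection(recovery_run):
    """RF on random k-feature subsets does worse than RF on OMC-selected
    subsets of the same size (paired over seeds)."""
    case = recovery_run["case"]
    k = max(2, int(np.median([
        len(t.selected_features)
        for traces in recovery_run["traces"] for t in traces
    ])))
    cfg = p.RFConfig(n_trees=100)
    random_mcc = [m.mcc for m in p.random_feature_rf(case, k, cfg, seeds=range(10))]
    assert np.nanmedian(random_mcc) < np.median(recovery_run["omc_mcc"])
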