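"""Univariate feature ranking within a training fold.

Each feature of a molecular profile is scored by how strongly it alone
discriminates sensitive from resistant PDXs in the training data: binary
features (SNV, CNA) by a two-sided Fisher's exact test on the 2x2
altered-by-class table, real-valued features (CN, GEX) by a two-sided Welch
t-test between the class-conditional value distributions. Features are ranked
by ascending p-value; ties break by descending absolute effect size, then
lexicographic feature id, so reruns are deterministic. Ranking is
sign-agnostic -- features associated with either sensitivity or resistance are
kept -- because a downstream forest can exploit both directions.

A merged profile ranks each feature with the test matching its profile prefix.
An alternative backend orders features by the permutation importance of a
random forest trained on all of them; it is exposed for comparison only and is
never the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import CaseDataset, ProfileKind
from .stats import fisher_two_sided, t_test_two_sided, is_na

__all__ = ["RankedFeatures", "rank_features", "top_k"]

_BINARY_PREFIXES = ("SNV:", "CNA:")
_REAL_PREFIXES = ("CN:", "GEX:")


@dataclass(frozen=True)
class RankedFeatures:
    """Features of one training fold ordered by univariate association.

    ``table`` has columns feature_id, p_value, effect and 1-based rank, sorted
    by rank.
    """

    table: pd.DataFrame
    method: str = "univariate"

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table["feature_id"])

    def __len__(self) -> int:
        return len(self.table)


def _is_binary_feature(feature_id: str, kind: ProfileKind) -> bool:
    if kind is ProfileKind.MERGED:
        if feature_id.startswith(_BINARY_PREFIXES):
            return True
        if feature_id.startswith(_REAL_PREFIXES):
            return False
        raise ValueError(f"merged feature {feature_id!r} lacks a profile prefix")
    return kind.is_binary


def _rank_univariate(train: CaseDataset) -> pd.DataFrame:
    X = train.features.values
    y = train.y()
    sens = y == 1
    n1 = int(sens.sum())
    n0 = len(y) - n1
    kind = train.profile_kind

    feature_ids = train.features.feature_ids
    binary_mask = np.array([_is_binary_feature(f, kind) for f in feature_ids])
    p = np.ones(len(feature_ids), dtype=float)
    effect = np.zeros(len(feature_ids), dtype=float)

    if binary_mask.any():
        Xb = X.loc[:, binary_mask].to_numpy()
        altered_sens = Xb[sens].sum(axis=0).astype(int)   # a
        altered_res = Xb[~sens].sum(axis=0).astype(int)   # b
        cols = np.where(binary_mask)[0]
        for j, a, b in zip(cols, altered_sens, altered_res):
            res = fisher_two_sided([[int(a), int(b)], [n1 - int(a), n0 - int(b)]])
            p[j] = res.p_value
            effect[j] = res.effect

    if (~binary_mask).any():
        Xr = X.loc[:, ~binary_mask].to_numpy()
        cols = np.where(~binary_mask)[0]
        if n1 < 2 or n0 < 2:
            # Welch needs >= 2 values per group: all real features degenerate
            diffs = Xr[sens].mean(axis=0) - Xr[~sens].mean(axis=0)
            p[cols] = 1.0
            effect[cols] = diffs
        else:
            a_grp = Xr[sens]
            b_grp = Xr[~sens]
            diffs = a_grp.mean(axis=0) - b_grp.mean(axis=0)
            from scipy import stats as sps

            with np.errstate(divide="ignore", invalid="ignore"):
                pv = sps.ttest_ind(a_grp, b_grp, equal_var=False, axis=0).pvalue
            pv = np.asarray(pv, dtype=float)
            const_both = (a_grp.std(axis=0) == 0) & (b_grp.std(axis=0) == 0)
            pv[const_both & (diffs == 0)] = 1.0
            pv[const_both & (diffs != 0)] = 0.0
            pv[np.isnan(pv)] = 1.0
            p[cols] = pv
            effect[cols] = diffs

    return pd.DataFrame(
        {"feature_id": feature_ids, "p_value": p, "effect": effect}
    )


def _rank_permutation_importance(train: CaseDataset, n_trees: int, seed: int) -> pd.DataFrame:
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.inspection import permutation_importance

    from .forest import class_weights

    X = train.features.to_numpy()
    y = train.y().astype(int)
    w1, w0 = class_weights(y)
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        class_weight={1: w1, 0: w0},
        random_state=seed,
        n_jobs=1,
    ).fit(X, y)
    imp = permutation_importance(clf, X, y, n_repeats=1, random_state=seed)
    return pd.DataFrame(
        {
            "feature_id": train.features.feature_ids,
            "p_value": np.nan,
            "effect": imp.importances_mean,
        }
    )


def rank_features(
    train: CaseDataset,
    method: str = "univariate",
    n_trees: int = 100,
    seed: int = 0,
) -> RankedFeatures:
    """Rank the features of a training fold by relevance to treatment response.

    ``method`` is "univariate" (the default: Fisher for binary features, Welch
    t for real-valued ones, ascending p-value) or "permutation_importance"
    (descending mean accuracy decrease of a class-weighted random forest
    trained on all features). Raises on a single-class training fold.
    """
    if train.degenerate:
        raise ValueError("cannot rank features on a single-class training fold")
    if method == "univariate":
        table = _rank_univariate(train)
        table = table.sort_values(
            by=["p_value", "effect", "feature_id"],
            key=lambda col: -col.abs() if col.name == "effect" else col,
            kind="mergesort",
        )
    elif method == "permutation_importance":
        table = _rank_permutation_importance(train, n_trees=n_trees, seed=seed)
        table = table.sort_values(
            by=["effect", "feature_id"], ascending=[False, True], kind="mergesort"
        )
    else:
        raise ValueError(f"unknown ranking method {method!r}")
    table = table.reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return RankedFeatures(table=table, method=method)


def top_k(ranked: RankedFeatures, k: int) -> list[str]:
    """The first ``k`` feature ids in rank order; ``k`` must be in [1, #features]."""
    if not 1 <= k <= len(ranked):
        raise ValueError(f"k={k} out of range 1..{len(ranked)}")
    return ranked.feature_ids[:k]
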