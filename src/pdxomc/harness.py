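"""Benchmark orchestration: replicated runs, aggregation and model comparison.

A *case* is one treatment x cancer-type x molecular-profile combination. Each
stochastic model is evaluated by 10 independent (nested) LOOCV passes sharing
a fixed seed list across model families, and every reported metric is the
median over the non-NA replicate values (all-NA stays NA). Model comparisons
are paired t-tests, either within a case over the matched replicate seeds or
across treatments over the matched per-treatment medians.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CaseDataset, ProfileKind
from .models import (
    ALL_FEATURES,
    FoldPrediction,
    OMCModelTrace,
    RFConfig,
    nested_loocv_rf_omc,
    predictions_to_metrics,
    random_prior_baseline,
    rf_all_loocv,
    single_gene_marker_loocv,
)
from .stats import MetricSet, is_na, paired_t

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "CaseResult",
    "BenchmarkGrid",
    "BenchmarkPlan",
    "run_case",
    "best_predictor_per_case",
    "compare_models",
    "compare_across_treatments",
    "plan_benchmark",
    "recall_comparison",
]

MODEL_NAMES = ("rf_all", "rf_omc", "single_gene", "random_prior")

_METRIC_FIELDS = ("mcc", "pr", "rc", "f1", "specificity", "auc")


@dataclass
class CaseResult:
    """Replicated evaluation of one model on one case."""

    treatment_id: str
    cancer_type: str
    profile_kind: ProfileKind
    model: str
    seeds: tuple[int, ...]
    replicates: tuple[MetricSet, ...]
    selected_features: tuple[tuple[str, ...], ...] = ()
    n: int = 0
    failure_reason: str | None = None

    @property
    def case_key(self) -> tuple[str, str]:
        return (self.treatment_id, self.cancer_type)

    @property
    def median(self) -> MetricSet:
        """Per-metric median over non-NA replicates (all-NA stays NA)."""
        values = {}
        for f in _METRIC_FIELDS:
            vals = np.array([getattr(m, f) for m in self.replicates], dtype=float)
            finite = vals[~np.isnan(vals)]
            values[f] = float(np.median(finite)) if finite.size else float("nan")
        return MetricSet(**values)

    @property
    def mcc_vector(self) -> np.ndarray:
        return np.array([m.mcc for m in self.replicates], dtype=float)

    @property
    def selected_size(self) -> float:
        """Median number of features the model's folds used (1 for the
        single-gene marker, #features for RF-all, nan when unknown)."""
        if self.model == "single_gene":
            return 1.0
        if self.model == "rf_all":
            return float("nan") if self.n == 0 else float("inf")
        if not self.selected_features:
            return float("nan")
        return float(np.median([len(f) for f in self.selected_features]))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for seed, m in zip(self.seeds, self.replicates):
            row = {
                "treatment": self.treatment_id,
                "cancer_type": self.cancer_type,
                "profile": self.profile_kind.value,
                "model": self.model,
                "seed": seed,
            }
            row.update(m.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)


def _run_replicate(
    case: CaseDataset, model: str, cfg: RFConfig
) -> tuple[list[FoldPrediction], tuple[tuple[str, ...], ...]]:
    if model == "rf_all":
        return rf_all_loocv(case, cfg), ()
    if model == "rf_omc":
        preds, traces = nested_loocv_rf_omc(case, cfg)
        return preds, tuple(t.selected_features for t in traces)
    if model == "single_gene":
        preds, genes = single_gene_marker_loocv(case)
        return preds, tuple((g,) if g else () for g in genes)
    if model == "random_prior":
        return random_prior_baseline(case, cfg.seed), ()
    raise ValueError(f"unknown model {model!r}; expected one of {MODEL_NAMES}")


def run_case(
    case: CaseDataset,
    model: str,
    cfg: RFConfig,
    seeds: Sequence[int],
) -> CaseResult:
    """Evaluate one model on one case with one replicate per seed.

    Stochastic models (the forests and the random baseline) vary across seeds;
    the single-gene marker is deterministic and simply repeats. A degenerate
    case (single response class) yields an all-NA result with its reason
    recorded rather than an exception, so a benchmark sweep can proceed.
    """
    seeds = tuple(int(s) for s in seeds)
    if case.degenerate:
        logger.warning("case %s/%s degenerate; all-NA result", case.treatment_id, case.cancer_type)
        na = MetricSet(*(float("nan"),) * 6)
        return CaseResult(
            treatment_id=case.treatment_id,
            cancer_type=case.cancer_type,
            profile_kind=case.profile_kind,
            model=model,
            seeds=seeds,
            replicates=tuple(na for _ in seeds),
            n=case.n,
            failure_reason="single response class",
        )
    replicates = []
    selected: list[tuple[str, ...]] = []
    for seed in seeds:
        preds, sel = _run_replicate(case, model, cfg.with_seed(seed))
        replicates.append(predictions_to_metrics(preds))
        selected.extend(sel)
    return CaseResult(
        treatment_id=case.treatment_id,
        cancer_type=case.cancer_type,
        profile_kind=case.profile_kind,
        model=model,
        seeds=seeds,
        replicates=tuple(replicates),
        selected_features=tuple(selected),
        n=case.n,
    )


_MODEL_PARSIMONY = {"single_gene": 0, "rf_omc": 1, "rf_all": 2, "random_prior": 3}


def best_predictor_per_case(
    results: Sequence[CaseResult],
) -> dict[tuple[str, str], CaseResult]:
    """Winning (model, profile) per treatment/cancer-type by median MCC.

    Exact ties resolve toward parsimony: fewer selected features first, then
    model order single-gene < RF-OMC < RF-all. Cases where every candidate is
    all-NA are reported with value None (unpredictable)."""
    winners: dict[tuple[str, str], CaseResult | None] = {}
    by_case: dict[tuple[str, str], list[CaseResult]] = {}
    for r in results:
        by_case.setdefault(r.case_key, []).append(r)
    for key, rs in by_case.items():
        candidates = [r for r in rs if not is_na(r.median.mcc)]
        if not candidates:
            winners[key] = None
            continue

        def sort_key(r: CaseResult) -> tuple:
            size = r.selected_size
            if is_na(size):
                size = float("inf")
            return (-r.median.mcc, size, _MODEL_PARSIMONY.get(r.model, 9))

        winners[key] = min(candidates, key=sort_key)
    return winners


def compare_models(a: CaseResult, b: CaseResult, sides: str = "one") -> float:
    """Paired t-test on the matched replicate MCC vectors of two models run on
    the same case with the same seed list; one-sided tests whether ``a``
    outperformed ``b``. NA replicates invalidate the pairing and raise."""
    if a.case_key != b.case_key or a.seeds != b.seeds:
        raise ValueError("results are not paired (case or seed mismatch)")
    va, vb = a.mcc_vector, b.mcc_vector
    keep = ~(np.isnan(va) | np.isnan(vb))
    if keep.sum() < 2:
        raise ValueError("fewer than 2 paired non-NA replicates")
    return paired_t(va[keep], vb[keep], sides=sides, direction="greater")


def compare_across_treatments(
    mcc_a: Mapping[str, float],
    mcc_b: Mapping[str, float],
    sides: str = "one",
) -> float:
    """Paired t-test across treatments on per-treatment MCCs (e.g. each
    model's best-profile median per treatment within one cancer type). The two
    mappings must cover identical treatment lists."""
    if set(mcc_a) != set(mcc_b):
        raise ValueError("treatment lists differ between the two models")
    keys = sorted(mcc_a)
    return paired_t(
        [mcc_a[k] for k in keys], [mcc_b[k] for k in keys],
        sides=sides, direction="greater",
    )


# ---------------------------------------------------------------------------
# Planner
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkGrid:
    """Dimensions of a benchmark sweep."""

    algorithms: tuple[str, ...] = ("rf_all", "rf_omc")
    cancer_types: tuple[str, ...] = ("BRCA", "CRC")
    treatments_per_type: int = 13
    profiles: tuple[str, ...] = ("SNV", "CNA", "CN", "GEX")
    n_replicates: int = 10
    base_seed: int = 0


@dataclass(frozen=True)
class BenchmarkPlan:
    runs: tuple[dict, ...]

    @property
    def total(self) -> int:
        return len(self.runs)


def plan_benchmark(grid: BenchmarkGrid) -> BenchmarkPlan:
    """Enumerate every planned LOOCV run in the grid with a per-run seed.

    The run count is the product of the dimension sizes: algorithms x cancer
    types x treatments per type x profiles x replicates.
    """
    if (
        not grid.algorithms
        or not grid.cancer_types
        or not grid.profiles
        or grid.treatments_per_type < 1
        or grid.n_replicates < 1
    ):
        raise ValueError("every grid dimension must be non-empty")
    runs = []
    seeds = [grid.base_seed + r for r in range(grid.n_replicates)]
    for algo, ctype, t_idx, profile, rep in itertools.product(
        grid.algorithms,
        grid.cancer_types,
        range(grid.treatments_per_type),
        grid.profiles,
        range(grid.n_replicates),
    ):
        runs.append(
            {
                "algorithm": algo,
                "cancer_type": ctype,
                "treatment_index": t_idx,
                "profile": profile,
                "replicate": rep,
                "seed": seeds[rep],
            }
        )
    return BenchmarkPlan(runs=tuple(runs))


def recall_comparison(
    multi: CaseResult, single: CaseResult
) -> tuple[float, float, str | None]:
    """Compare median recall of a multi-gene model against the single-gene
    marker on the same case: (multi recall, single recall, winner), where the
    winner is "multi", "single", None for an exact tie, or "incomplete" when
    either recall is NA."""
    if multi.case_key != single.case_key:
        raise ValueError("results describe different cases")
    rc_m, rc_s = multi.median.rc, single.median.rc
    if is_na(rc_m) or is_na(rc_s):
        return rc_m, rc_s, "incomplete"
    if rc_m > rc_s:
        return rc_m, rc_s, "multi"
    if rc_s > rc_m:
        return rc_m, rc_s, "single"
    return rc_m, rc_s, None
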