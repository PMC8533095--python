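"""Tumour-volume response classification.

Raw treatment response is a series of percentage tumour-volume changes
relative to the volume at treatment start (%dTVol), recorded every few days.
Two summary statistics drive the mRECIST-like categorisation used for PDX
cohorts:

* *BestResponse* -- the minimum %dTVol over eligible measurement days, and
* *BestAvgResponse* -- the minimum over eligible days t of the running mean of
  %dTVol from the start of the eligibility window up to t.

Eligibility means day >= ``min_day`` (default 10), which applies both to the
start of the averaging window and to the minimum search; the day-0 baseline
(0% by definition) never enters either statistic. A category is assigned by
strict threshold comparisons on the pair (BestResponse, BestAvgResponse),
falling through CR -> PR -> SD -> PD; boundary values go to the less
responsive class. CR/PR/SD tumours are responders (sensitive), PD tumours
non-responders (resistant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .datamodel import BinaryClass, Category, binarize_category

logger = logging.getLogger(__name__)

__all__ = [
    "VolumeSeries",
    "ResponseRuleSet",
    "best_response_stats",
    "categorize",
    "binarize",
    "reconcile",
    "count_discrepancies",
]


@dataclass(frozen=True)
class VolumeSeries:
    """%dTVol measurements for one PDX under one treatment.

    ``observations`` are (day, pct_delta_tvol) pairs with strictly increasing
    non-negative days and values >= -100 (a tumour cannot shrink below
    nothing). If a day-0 observation is present it must be the 0% baseline;
    statistics are always computed from post-baseline observations only.
    """

    pdx_id: str
    treatment_id: str
    observations: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        obs = tuple((int(d), float(v)) for d, v in self.observations)
        object.__setattr__(self, "observations", obs)
        days = [d for d, _ in obs]
        if any(d < 0 for d in days):
            raise ValueError("days must be non-negative")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if any(v < -100.0 for _, v in obs):
            raise ValueError("%dTVol cannot be below -100")
        if obs and obs[0][0] == 0 and obs[0][1] != 0.0:
            raise ValueError("day-0 observation must be the 0% baseline")

    def post_baseline(self) -> tuple[tuple[int, float], ...]:
        return tuple((d, v) for d, v in self.observations if d > 0)


@dataclass(frozen=True)
class ResponseRuleSet:
    """Thresholds (in % units) mapping response statistics to categories.

    The defaults follow the mRECIST-like criteria established for the PDX
    encyclopedia cohorts: CR when BestResponse < -95 and BestAvgResponse <
    -40; PR when < -50 and < -20; SD when < 35 and < 30; PD otherwise, with
    statistics taken from day >= 10. All comparisons are strict.
    """

    min_day: int = 10
    cr_best: float = -95.0
    cr_avg: float = -40.0
    pr_best: float = -50.0
    pr_avg: float = -20.0
    sd_best: float = 35.0
    sd_avg: float = 30.0

    def __post_init__(self) -> None:
        if not (self.cr_best < self.pr_best < self.sd_best):
            raise ValueError("best-response thresholds must increase CR < PR < SD")
        if not (self.cr_avg < self.pr_avg):
            raise ValueError("average-response thresholds must increase CR < PR")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ResponseRuleSet":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def best_response_stats(
    series: VolumeSeries, min_day: int = 10
) -> tuple[float, float]:
    """Compute (BestResponse, BestAvgResponse) for a volume series.

    Both statistics are restricted to post-baseline observations with
    day >= ``min_day``; the running average starts at the first eligible
    observation. Raises ``ValueError`` when no observation is eligible.
    """
    eligible = [(d, v) for d, v in series.post_baseline() if d >= min_day]
    if not eligible:
        raise ValueError(
            f"{series.pdx_id}/{series.treatment_id}: no observation at day >= {min_day}"
        )
    if len(eligible) == 1:
        logger.info(
            "%s/%s categorised from a single eligible point (low support)",
            series.pdx_id, series.treatment_id,
        )
    values = np.array([v for _, v in eligible], dtype=float)
    best_response = float(values.min())
    running_means = np.cumsum(values) / np.arange(1, len(values) + 1)
    best_avg_response = float(running_means.min())
    return best_response, best_avg_response


def categorize(series: VolumeSeries, rules: ResponseRuleSet | None = None) -> Category:
    """Assign an mRECIST-like category to a volume series.

    Falls through CR -> PR -> SD with strict ``<`` comparisons on both
    statistics; anything else is PD. A value exactly on a threshold therefore
    lands in the less responsive class.
    """
    rules = rules or ResponseRuleSet()
    best, best_avg = best_response_stats(series, rules.min_day)
    return categorize_stats(best, best_avg, rules)


def categorize_stats(
    best: float, best_avg: float, rules: ResponseRuleSet | None = None
) -> Category:
    """Category from precomputed (BestResponse, BestAvgResponse)."""
    rules = rules or ResponseRuleSet()
    if best < rules.cr_best and best_avg < rules.cr_avg:
        return Category.CR
    if best < rules.pr_best and best_avg < rules.pr_avg:
        return Category.PR
    if best < rules.sd_best and best_avg < rules.sd_avg:
        return Category.SD
    return Category.PD


def binarize(category: Category | str) -> BinaryClass:
    """CR/PR/SD -> sensitive (responder); PD -> resistant (non-responder)."""
    return binarize_category(category)


def reconcile(
    retrieved: Category | str | None,
    calculated: Category | str | None,
) -> tuple[Category, bool]:
    """Reconcile a retrieved category with one recalculated from raw data.

    When both are present the calculated category wins, so that every
    PDX-treatment pair is categorised under the same set of rules; the pair is
    flagged discrepant when they differ. A missing side falls back to the
    present one (logged).
    """
    if retrieved is None and calculated is None:
        raise ValueError("at least one category must be present")
    if calculated is None:
        logger.info("no calculated category; falling back to retrieved")
        return Category(retrieved), False
    calculated = Category(calculated)
    if retrieved is None:
        logger.info("no retrieved category; using calculated")
        return calculated, False
    return calculated, Category(retrieved) is not calculated


def count_discrepancies(
    pairs: Iterable[tuple[Category | str | None, Category | str | None]],
) -> tuple[list[Category], int]:
    """Reconcile many (retrieved, calculated) pairs; return finals and
    the number of discrepant pairs."""
    finals: list[Category] = []
    n_discrepant = 0
    for retrieved, calculated in pairs:
        final, discrepant = reconcile(retrieved, calculated)
        finals.append(final)
        n_discrepant += int(discrepant)
    return finals, n_discrepant
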