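"""Synthetic PDX-like cohorts with planted, parameterised response signal.

The generator emulates the structure of a PDX pharmacogenomic screen -- binary
mutation matrices, real-valued copy-number and expression matrices, response
categories and tumour-volume curves -- with a controlled amount of planted
association between named features and the binary response class. It exists so
that every pipeline stage (encoding, ranking, model selection, nested
cross-validation, baselines) is testable end-to-end without any external
download; it makes no attempt to simulate co-expression structure or
mutational signatures.

Binary planted effects are parameterised by the background alteration rate in
the resistant class and an odds ratio; real-valued effects by a standardised
mean shift between classes. All randomness flows from the spec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CaseDataset,
    Category,
    FeatureMatrix,
    ProfileKind,
    ResponseRecord,
)
from .response import ResponseRuleSet, VolumeSeries, best_response_stats, categorize_stats

__all__ = [
    "PlantedFeature",
    "SyntheticCohortSpec",
    "Cohort",
    "generate_cohort",
    "generate_volume_series",
    "permute_labels",
    "category_margin",
]


@dataclass(frozen=True)
class PlantedFeature:
    """One response-associated feature to plant.

    ``effect_size`` is an odds ratio for binary profiles (SNV, CNA) and a
    standardised mean shift for real-valued ones (CN, GEX); both must be > 0.
    ``direction`` +1 plants a sensitivity marker (more altered / higher in
    sensitive PDXs), -1 a resistance marker.
    """

    kind: ProfileKind = ProfileKind.SNV
    effect_size: float = 20.0
    direction: int = 1

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ProfileKind(self.kind))
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if self.direction not in (-1, 1):
            raise ValueError("direction must be +1 or -1")


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Study conditions for one synthetic cohort.

    Defaults describe a desk-scale screen: 40 PDXs at 50% response prevalence,
    500 background binary features mutating at 10% and 100 real-valued
    features, with three strong sensitivity markers (odds ratio 20) planted in
    the mutation profile -- ample signal for subset-recovery experiments at
    this cohort size.
    """

    n_samples: int = 40
    prevalence: float = 0.5
    n_binary_features: int = 500
    n_real_features: int = 100
    planted: tuple[PlantedFeature, ...] = (
        PlantedFeature(),
        PlantedFeature(),
        PlantedFeature(),
    )
    background_rate: float = 0.1
    real_shift_sd: float = 1.0
    volume_noise_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie strictly between 0 and 1")
        if not 0.0 < self.background_rate < 1.0:
            raise ValueError("background rate must lie strictly between 0 and 1")
        n_binary_planted = sum(p.kind.is_binary for p in self.planted)
        n_real_planted = len(self.planted) - n_binary_planted
        if n_binary_planted > self.n_binary_features:
            raise ValueError("more binary planted features than binary features")
        if n_real_planted > self.n_real_features:
            raise ValueError("more real planted features than real features")


@dataclass
class Cohort:
    """A generated cohort: one FeatureMatrix per profile kind, response
    records, the underlying classes and the planted feature ids."""

    profiles: dict[ProfileKind, FeatureMatrix]
    responses: list[ResponseRecord]
    classes: pd.Series  # 1 sensitive / 0 resistant, indexed by PDX id
    planted_ids: dict[ProfileKind, tuple[str, ...]]
    treatment_id: str = "DRUG-1"
    cancer_type: str = "SYNTH"

    def case(self, kind: ProfileKind, min_n: int = 35) -> CaseDataset:
        """Model-ready case dataset for one profile."""
        kind = ProfileKind(kind)
        return CaseDataset(
            treatment_id=self.treatment_id,
            cancer_type=self.cancer_type,
            features=self.profiles[kind],
            classes=self.classes.copy(),
            min_n=min_n,
        )

    def write(self, out_dir: str | Path) -> None:
        """Write the cohort as the TSV formats the readers consume."""
        from .io import write_profile_table, write_response_table

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for kind, fm in self.profiles.items():
            write_profile_table(fm.values.T, out_dir / f"{kind.value}.tsv")
        write_response_table(self.responses, out_dir / "responses.tsv")


def _planted_rates(p: PlantedFeature, background: float) -> tuple[float, float]:
    """(sensitive rate, resistant rate) realising the requested odds ratio."""
    q = background
    odds = q / (1 - q)
    if p.direction == 1:
        odds_s = odds * p.effect_size
        return odds_s / (1 + odds_s), q
    odds_s = odds / p.effect_size
    return odds_s / (1 + odds_s), q


def generate_cohort(
    spec: SyntheticCohortSpec,
    treatment_id: str = "DRUG-1",
    cancer_type: str = "SYNTH",
) -> Cohort:
    """Draw a cohort under the given conditions, deterministically per seed.

    Classes are Bernoulli(prevalence) draws (re-drawn, bounded, in the rare
    event a single class comes out -- a cohort with one class cannot exercise
    any classifier). Planted binary features use class-conditional alteration
    rates implying the requested odds ratio over the background rate; planted
    real features are class-shifted Gaussians; all other features are
    class-independent noise. Response categories are consistent with the
    class: resistant PDXs are PD, sensitive ones draw CR/PR/SD.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"PDX{i + 1:03d}" for i in range(n)]

    y = None
    for _ in range(100):
        draw = (rng.random(n) < spec.prevalence).astype(np.int8)
        if 0 < draw.sum() < n:
            y = draw
            break
    if y is None:
        raise RuntimeError("could not draw a two-class cohort; prevalence too extreme")
    sens = y == 1

    planted_binary = [p for p in spec.planted if p.kind.is_binary]
    planted_real = [p for p in spec.planted if not p.kind.is_binary]

    # --- binary profiles (SNV and CNA share the generating mechanics) -----
    def binary_matrix(kind: ProfileKind, rate: float) -> tuple[pd.DataFrame, list[str]]:
        mine = [p for p in planted_binary if p.kind is kind]
        n_total = spec.n_binary_features
        ids = [f"{kind.value}G{j + 1:04d}" for j in range(n_total)]
        mat = (rng.random((n, n_total)) < rate).astype(float)
        planted_names = []
        for j, p in enumerate(mine):
            rate_s, rate_r = _planted_rates(p, spec.background_rate)
            col = np.where(sens, rng.random(n) < rate_s, rng.random(n) < rate_r)
            mat[:, j] = col.astype(float)
            name = f"{kind.value}_PLANTED{j + 1}"
            ids[j] = name
            planted_names.append(name)
        return pd.DataFrame(mat, index=sample_ids, columns=ids), planted_names

    snv_df, snv_planted = binary_matrix(ProfileKind.SNV, spec.background_rate)
    cna_df, cna_planted = binary_matrix(ProfileKind.CNA, spec.background_rate / 2)

    # --- real-valued profiles ---------------------------------------------
    def real_matrix(kind: ProfileKind, baselines: np.ndarray, sd: float) -> tuple[pd.DataFrame, list[str]]:
        mine = [p for p in planted_real if p.kind is kind]
        n_total = spec.n_real_features
        ids = [f"{kind.value}G{j + 1:04d}" for j in range(n_total)]
        mat = baselines[None, :] + rng.normal(0.0, sd, size=(n, n_total))
        planted_names = []
        for j, p in enumerate(mine):
            shift = p.direction * p.effect_size * sd
            mat[:, j] = mat[:, j] + np.where(sens, shift, 0.0)
            name = f"{kind.value}_PLANTED{j + 1}"
            ids[j] = name
            planted_names.append(name)
        np.clip(mat, 0.0, None, out=mat)  # CN/GEX values are non-negative
        return pd.DataFrame(mat, index=sample_ids, columns=ids), planted_names

    gex_base = rng.uniform(2.0, 10.0, size=spec.n_real_features)
    gex_df, gex_planted = real_matrix(ProfileKind.GEX, gex_base, spec.real_shift_sd)
    cn_base = np.full(spec.n_real_features, 2.0)
    cn_df, cn_planted = real_matrix(ProfileKind.CN, cn_base, 0.3)

    profiles = {
        ProfileKind.SNV: FeatureMatrix(snv_df, ProfileKind.SNV),
        ProfileKind.CNA: FeatureMatrix(cna_df, ProfileKind.CNA),
        ProfileKind.GEX: FeatureMatrix(gex_df, ProfileKind.GEX),
        ProfileKind.CN: FeatureMatrix(cn_df, ProfileKind.CN),
    }

    responder_cats = np.array([Category.CR, Category.PR, Category.SD], dtype=object)
    cat_probs = np.array([0.1, 0.4, 0.5])
    responses = []
    for pdx, cls in zip(sample_ids, y):
        if cls == 1:
            cat = rng.choice(responder_cats, p=cat_probs)
        else:
            cat = Category.PD
        responses.append(ResponseRecord(pdx_id=pdx, treatment_id=treatment_id, category=cat))

    return Cohort(
        profiles=profiles,
        responses=responses,
        classes=pd.Series(y, index=sample_ids, dtype=np.int8),
        planted_ids={
            ProfileKind.SNV: tuple(snv_planted),
            ProfileKind.CNA: tuple(cna_planted),
            ProfileKind.GEX: tuple(gex_planted),
            ProfileKind.CN: tuple(cn_planted),
        },
        treatment_id=treatment_id,
        cancer_type=cancer_type,
    )


def permute_labels(cohort: Cohort, seed: int) -> Cohort:
    """Uniformly permute the class labels (and response records) across
    samples, leaving every feature untouched -- the null-model fixture in
    which no feature carries real signal."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(cohort.classes))
    sample_ids = list(cohort.classes.index)
    permuted = pd.Series(
        cohort.classes.to_numpy()[perm], index=sample_ids, dtype=np.int8
    )
    by_pdx = {r.pdx_id: r for r in cohort.responses}
    responses = [
        ResponseRecord(
            pdx_id=sample_ids[i],
            treatment_id=by_pdx[sample_ids[perm[i]]].treatment_id,
            category=by_pdx[sample_ids[perm[i]]].category,
        )
        for i in range(len(sample_ids))
    ]
    return Cohort(
        profiles=cohort.profiles,
        responses=responses,
        classes=permuted,
        planted_ids=cohort.planted_ids,
        treatment_id=cohort.treatment_id,
        cancer_type=cohort.cancer_type,
    )


# ---------------------------------------------------------------------------
# Volume curves
# ---------------------------------------------------------------------------

def category_margin(
    best: float, best_avg: float, rules: ResponseRuleSet, category: Category
) -> float:
    """How far (in percentage points) the statistics sit inside the region of
    ``category``; negative when outside.

    The margin is the smallest distance to any boundary of the region in the
    (BestResponse, BestAvgResponse) plane, including the exclusion boundary of
    the next-better category.
    """
    r = rules
    if category is Category.CR:
        return min(r.cr_best - best, r.cr_avg - best_avg)
    if category is Category.PR:
        inside = min(r.pr_best - best, r.pr_avg - best_avg)
        not_cr = max(best - r.cr_best, best_avg - r.cr_avg)
        return min(inside, not_cr)
    if category is Category.SD:
        inside = min(r.sd_best - best, r.sd_avg - best_avg)
        not_pr = max(best - r.pr_best, best_avg - r.pr_avg)
        return min(inside, not_pr)
    # PD: outside the SD box
    return max(best - r.sd_best, best_avg - r.sd_avg)


_PLATEAU = {
    Category.CR: -100.0,
    Category.PR: None,  # midway between the CR and PR best-response bounds
    Category.SD: 0.0,
    Category.PD: 80.0,
}


def _base_curve(category: Category, rules: ResponseRuleSet, days: np.ndarray) -> np.ndarray:
    if category is Category.PR:
        plateau = 0.5 * (rules.cr_best + rules.pr_best)
    else:
        plateau = _PLATEAU[category]
    ramp_days = 14.0 if category is Category.PD else float(max(rules.min_day, 1))
    frac = np.minimum(1.0, days / ramp_days)
    return plateau * frac


def generate_volume_series(
    category: Category | str,
    rules: ResponseRuleSet | None = None,
    noise_scale: float = 5.0,
    seed: int = 0,
    pdx_id: str = "PDX001",
    treatment_id: str = "DRUG-1",
    horizon: int = 42,
    margin: float = 5.0,
    max_tries: int = 200,
) -> VolumeSeries:
    """Generate a %dTVol curve that lands strictly inside the requested
    category's region (margin >= ``margin`` percentage points) under the given
    rules.

    Curves are a piecewise-linear trend (shrink, stabilise or grow, reaching
    plateau around the eligibility day) plus Gaussian noise, sampled every 3-4
    days from baseline to ``horizon``; draws violating the target region are
    rejected and resampled (bounded tries).
    """
    category = Category(category)
    rules = rules or ResponseRuleSet()
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        days = [0]
        while days[-1] < horizon:
            days.append(days[-1] + int(rng.integers(3, 5)))
        days_arr = np.array(days[1:], dtype=float)
        values = _base_curve(category, rules, days_arr)
        values = values + rng.normal(0.0, noise_scale, size=len(values))
        values = np.clip(values, -100.0, None)
        obs = ((0, 0.0),) + tuple(zip((int(d) for d in days_arr), values))
        series = VolumeSeries(pdx_id=pdx_id, treatment_id=treatment_id, observations=obs)
        try:
            best, best_avg = best_response_stats(series, rules.min_day)
        except ValueError:
            continue
        if (
            categorize_stats(best, best_avg, rules) is category
            and category_margin(best, best_avg, rules, category) >= margin
        ):
            return series
    raise RuntimeError(
        f"could not generate a {category.value} curve within margin {margin} "
        f"at noise scale {noise_scale}"
    )
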