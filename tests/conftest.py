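"""Shared fixtures.

The two expensive session fixtures (`recovery_run`, `selection_bias_run`) run
replicated nested cross-validations once and are shared between the model
property tests and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import pdxomc as p


@pytest.fixture(scope="session")
def strong_cohort() -> p.Cohort:
    """Small cohort with three strong planted mutation markers (cheap tests)."""
    spec = p.SyntheticCohortSpec(
        n_samples=24, n_binary_features=60, n_real_features=20, seed=3
    )
    return p.generate_cohort(spec)


@pytest.fixture(scope="session")
def strong_case(strong_cohort: p.Cohort) -> p.CaseDataset:
    return strong_cohort.case(p.ProfileKind.SNV)


@pytest.fixture()
def tiny_case() -> p.CaseDataset:
    """Hand-built 8-PDX SNV case with one perfectly separating gene."""
    samples = [f"PDX{i}" for i in range(8)]
    classes = pd.Series([1, 1, 1, 1, 0, 0, 0, 0], index=samples, dtype=np.int8)
    values = pd.DataFrame(
        {
            "PERFECT": [1, 1, 1, 1, 0, 0, 0, 0],
            "NOISY": [1, 0, 1, 0, 1, 0, 1, 0],
            "CONST": [0] * 8,
        },
        index=samples,
        dtype=float,
    )
    return p.CaseDataset(
        treatment_id="T1",
        cancer_type="SYNTH",
        features=p.FeatureMatrix(values, p.ProfileKind.SNV),
        classes=classes,
        min_n=5,
    )


@pytest.fixture(scope="session")
def recovery_run() -> dict:
    """Replicated nested LOOCV of RF-OMC vs standard LOOCV of RF-all on the
    default strong-signal cohort (40 PDXs, 500 binary features of which 3 are
    planted sensitivity markers at odds ratio 20, prevalence 0.5), 100-tree
    forests, 10 shared replicate seeds."""
    spec = p.SyntheticCohortSpec()
    cohort = p.generate_cohort(spec)
    case = cohort.case(p.ProfileKind.SNV)
    planted = set(cohort.planted_ids[p.ProfileKind.SNV])
    seeds = list(range(10))
    omc_mcc, rf_all_mcc, n_recovered, all_traces = [], [], [], []
    for s in seeds:
        cfg = p.RFConfig(n_trees=100, seed=s)
        preds, traces = p.nested_loocv_rf_omc(case, cfg)
        omc_mcc.append(p.predictions_to_metrics(preds).mcc)
        union = set().union(*(set(t.selected_features) for t in traces))
        n_recovered.append(len(union & planted))
        rf_all_mcc.append(p.predictions_to_metrics(p.rf_all_loocv(case, cfg)).mcc)
        all_traces.append(traces)
    return {
        "case": case,
        "cohort": cohort,
        "planted": planted,
        "seeds": seeds,
        "omc_mcc": omc_mcc,
        "rf_all_mcc": rf_all_mcc,
        "n_recovered": n_recovered,
        "traces": all_traces,
    }


@pytest.fixture(scope="session")
def selection_bias_run() -> dict:
    """Nested LOOCV of RF-OMC on label-permuted (null) cohorts: 30 PDXs, 300
    binary features, 10 permutation/replicate seeds. Records, per outer fold,
    the best inner-LOOCV MCC the selection saw and the honest outer MCC."""
    spec = p.SyntheticCohortSpec(
        n_samples=30, n_binary_features=300, n_real_features=10
    )
    cohort = p.generate_cohort(spec)
    best_inner, outer_mcc = [], []
    for s in range(10):
        null = p.permute_labels(cohort, seed=s)
        case = null.case(p.ProfileKind.SNV)
        cfg = p.RFConfig(n_trees=100, seed=s)
        preds, traces = p.nested_loocv_rf_omc(case, cfg)
        best_inner.extend(t.best_inner_mcc for t in traces if t.candidate_sizes)
        outer_mcc.append(p.predictions_to_metrics(preds).mcc)
    return {"best_inner": best_inner, "outer_mcc": outer_mcc}
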