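"""Readers, writers and profile encoders.

Input tables are delimited text (TSV by default, CSV by extension) mirroring
the layout of the public NIBR-PDXE workbook: gene x sample matrices with one
header row of PDX identifiers and one row per gene, plus long-form response
tables. A convenience reader for the original five-tab XLSX workbook is
provided but nothing in the package requires it.

The four encoders turn raw tables into model-ready :class:`FeatureMatrix`
objects:

* ``encode_snv`` -- 1 iff at least one somatic SNV was detected in the gene.
* ``encode_cna`` -- 1 iff the copy number is aberrant (Amp8, Amp5 or Del0.8).
* ``encode_cn`` / ``encode_gex`` -- real values used as provided.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    CaseDataset,
    CnaThresholds,
    FeatureMatrix,
    ProfileKind,
    ResponseRecord,
    SENSITIVE,
)

logger = logging.getLogger(__name__)

#: Tab names of the public PDX encyclopedia workbook.
WORKBOOK_TABS = (
    "RNASeq_fpkm",
    "copy_number",
    "pdxe_mut_and_cn2",
    "PCT_raw_data",
    "PCT_curve_metrics",
)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_profile_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a gene x sample table (genes as rows, samples as columns).

    The first column holds gene symbols; the header row holds sample ids
    (matched case-sensitively after whitespace trimming). Duplicate sample
    columns are an error. Duplicate gene rows are resolved by keeping the row
    whose values deviate most (in absolute terms) from the table median; the
    resolution is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = sep or _sep_for(path)
    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=sep))
    samples = [h.strip() for h in header[1:]]
    dupes = {s for s in samples if samples.count(s) > 1}
    if dupes:
        raise ValueError(f"duplicate sample columns: {sorted(dupes)}")
    table = pd.read_csv(path, sep=sep, index_col=0)
    table.columns = [str(c).strip() for c in table.columns]
    table.index = [str(g).strip() for g in table.index]
    if not np.issubdtype(table.to_numpy().dtype, np.number):
        bad = table.columns[
            [not np.issubdtype(dt, np.number) for dt in table.dtypes]
        ]
        raise ValueError(f"non-numeric values in columns: {list(bad)[:5]}")
    if not table.index.is_unique:
        table = _resolve_duplicate_genes(table)
    return table


def _resolve_duplicate_genes(table: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated gene, the row deviating most from the table median."""
    overall_median = float(np.median(table.to_numpy()))
    dev = (table - overall_median).abs().sum(axis=1).to_numpy()
    keep = np.zeros(len(table), dtype=bool)
    best: dict[str, int] = {}
    for i, gene in enumerate(table.index):
        j = best.get(gene)
        if j is None or dev[i] > dev[j]:
            best[gene] = i
    for i in best.values():
        keep[i] = True
    n_dropped = int((~keep).sum())
    logger.info("resolved %d duplicate gene rows (largest-deviation rule)", n_dropped)
    return table.loc[keep]


def write_profile_table(table: pd.DataFrame, path: str | Path, sep: str | None = None) -> None:
    """Write a gene x sample table; inverse of :func:`read_profile_table`."""
    path = Path(path)
    table.to_csv(path, sep=sep or _sep_for(path), index_label="gene")


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

def encode_snv(
    calls: pd.DataFrame,
    sample_ids: Sequence[str],
    gene_ids: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Encode somatic mutation calls as a binary gene-presence matrix.

    Parameters
    ----------
    calls : pandas.DataFrame
        Long-form mutation calls with columns ``gene`` and ``pdx_id`` (one row
        per detected SNV; a gene typically has several SNVs, all collapsing to
        the same feature value).
    sample_ids : sequence of str
        The full cohort; samples without any call are all wild-type (0).
    gene_ids : sequence of str, optional
        Feature universe. Defaults to the genes present in ``calls``.

    Returns
    -------
    FeatureMatrix
        SNV profile: value 1 iff at least one SNV was detected in that gene
        region for that PDX, 0 (wild type) otherwise.
    """
    sample_ids = [str(s).strip() for s in sample_ids]
    required = {"gene", "pdx_id"}
    if not required <= set(calls.columns):
        raise ValueError(f"mutation call table needs columns {sorted(required)}")
    unknown = set(calls["pdx_id"].astype(str).str.strip()) - set(sample_ids)
    if unknown:
        raise KeyError(f"mutation calls name unknown samples: {sorted(unknown)[:5]}")
    if gene_ids is None:
        gene_ids = sorted(calls["gene"].astype(str).str.strip().unique())
    mat = pd.DataFrame(0.0, index=sample_ids, columns=list(gene_ids))
    for gene, pdx in zip(calls["gene"].astype(str).str.strip(),
                         calls["pdx_id"].astype(str).str.strip()):
        if gene in mat.columns:
            mat.loc[pdx, gene] = 1.0
    return FeatureMatrix(mat, ProfileKind.SNV)


def encode_cna(
    cn_table: pd.DataFrame,
    thresholds: CnaThresholds | None = None,
) -> FeatureMatrix:
    """Binarise a real-valued copy-number table into aberrant / neutral.

    A gene's CNA feature is 1 for aberrant copy number -- strongly amplified
    (cn >= ``amp8_low``), moderately amplified (``amp5_low`` <= cn <
    ``amp8_low``) or deleted (cn <= ``del_high``) -- and 0 otherwise.
    ``cn_table`` is gene x sample, as read by :func:`read_profile_table`.
    """
    thresholds = thresholds or CnaThresholds()
    arr = cn_table.to_numpy(dtype=float)
    if arr.size and (not np.isfinite(arr).all() or (arr < 0).any()):
        raise ValueError("copy numbers must be finite and non-negative")
    binary = ((arr >= thresholds.amp5_low) | (arr <= thresholds.del_high)).astype(float)
    mat = pd.DataFrame(binary, index=cn_table.index, columns=cn_table.columns).T
    return FeatureMatrix(mat, ProfileKind.CNA)


def encode_cn(cn_table: pd.DataFrame) -> FeatureMatrix:
    """Real-valued copy-number profile, values used as provided."""
    return FeatureMatrix(cn_table.T, ProfileKind.CN)


def encode_gex(fpkm_table: pd.DataFrame) -> FeatureMatrix:
    """Gene-expression profile, FPKM values used as provided (no log transform)."""
    return FeatureMatrix(fpkm_table.T, ProfileKind.GEX)


# ---------------------------------------------------------------------------
# Case assembly and profile merging
# ---------------------------------------------------------------------------

def build_case_dataset(
    profile: FeatureMatrix,
    responses: Iterable[ResponseRecord],
    treatment_id: str,
    cancer_type: str,
    min_n: int = 35,
) -> CaseDataset:
    """Pair a molecular profile with treatment responses for one case.

    Only PDXs that are both profiled and treated with ``treatment_id`` enter
    the case (set intersection); the dropped ids are recorded. The case is
    flagged when its sample count falls below ``min_n`` (the default mirrors
    the smallest cohort size for which predictive modelling has been reported
    to work in this setting) or when a single response class remains.
    """
    by_pdx = {
        r.pdx_id: r for r in responses if r.treatment_id == treatment_id
    }
    profiled = set(profile.sample_ids)
    common = [s for s in profile.sample_ids if s in by_pdx]
    if not common:
        raise ValueError(
            f"no PDX is both profiled and treated with {treatment_id!r}"
        )
    dropped = sorted((profiled | set(by_pdx)) - set(common))
    if dropped:
        logger.info(
            "case %s/%s: %d PDXs dropped outside the profile/response intersection",
            treatment_id, cancer_type, len(dropped),
        )
    classes = pd.Series(
        [1 if by_pdx[s].binary_class is SENSITIVE else 0 for s in common],
        index=common,
        dtype=np.int8,
    )
    case = CaseDataset(
        treatment_id=treatment_id,
        cancer_type=cancer_type,
        features=profile.select_samples(common),
        classes=classes,
        min_n=min_n,
        dropped_samples=tuple(dropped),
    )
    if case.below_threshold:
        logger.warning("case %s/%s has n=%d < %d", treatment_id, cancer_type, case.n, min_n)
    if case.degenerate:
        logger.warning("case %s/%s is degenerate (single response class)", treatment_id, cancer_type)
    return case


def merge_profiles(profiles: Sequence[FeatureMatrix]) -> FeatureMatrix:
    """Concatenate several profiles column-wise over their common samples.

    Feature ids are prefixed with the profile kind (``SNV:TP53``) so the same
    gene appearing in two profiles yields two distinct features. Raises when
    fewer than two profiles are given or their sample sets do not overlap.
    """
    if len(profiles) < 2:
        raise ValueError("merging requires at least two profiles")
    common = list(profiles[0].sample_ids)
    for p in profiles[1:]:
        members = set(p.sample_ids)
        common = [s for s in common if s in members]
    if not common:
        raise ValueError("profiles share no samples")
    blocks = []
    for p in profiles:
        block = p.values.loc[common]
        block.columns = [f"{p.profile_kind.value}:{f}" for f in block.columns]
        blocks.append(block)
    return FeatureMatrix(pd.concat(blocks, axis=1), ProfileKind.MERGED)


# ---------------------------------------------------------------------------
# Response tables
# ---------------------------------------------------------------------------

def read_response_table(path: str | Path, sep: str | None = None) -> list[ResponseRecord]:
    """Read a curve-metrics style table with columns pdx_id, treatment, category."""
    path = Path(path)
    table = pd.read_csv(path, sep=sep or _sep_for(path))
    required = {"pdx_id", "treatment", "category"}
    if not required <= set(table.columns):
        raise ValueError(f"response table needs columns {sorted(required)}")
    source_col = table["source"] if "source" in table.columns else None
    records = []
    for i, row in table.iterrows():
        records.append(
            ResponseRecord(
                pdx_id=str(row["pdx_id"]).strip(),
                treatment_id=str(row["treatment"]).strip(),
                category=row["category"],
                source=str(source_col[i]) if source_col is not None else "retrieved",
            )
        )
    return records


def write_response_table(records: Iterable[ResponseRecord], path: str | Path,
                         sep: str | None = None) -> None:
    rows = [
        {
            "pdx_id": r.pdx_id,
            "treatment": r.treatment_id,
            "category": r.category.value,
            "binary_class": r.binary_class.value,
            "source": r.source,
        }
        for r in records
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep=sep or _sep_for(path), index=False)


def read_raw_response_table(path: str | Path, sep: str | None = None) -> pd.DataFrame:
    """Read a raw %dTVol table with columns pdx_id, treatment, day, pct_delta_tvol."""
    path = Path(path)
    table = pd.read_csv(path, sep=sep or _sep_for(path))
    required = {"pdx_id", "treatment", "day", "pct_delta_tvol"}
    if not required <= set(table.columns):
        raise ValueError(f"raw response table needs columns {sorted(required)}")
    return table


def read_pdxe_workbook(path: str | Path) -> Mapping[str, pd.DataFrame]:
    """Read the five named tabs of a PDX-encyclopedia style XLSX workbook.

    Optional convenience for working with the original download; all tests and
    pipelines operate on the delimited-text mirrors instead.
    """
    return {tab: pd.read_excel(path, sheet_name=tab) for tab in WORKBOOK_TABS}
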