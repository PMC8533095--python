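"""Core data types for PDX pharmacogenomic modelling.

The central container is :class:`FeatureMatrix`, a validated sample x feature
matrix for one molecular profile of a xenograft cohort. Four profile kinds are
supported: binary somatic mutation status (SNV), binarised copy-number
aberration (CNA), real-valued copy number (CN) and gene expression (GEX), plus
the MERGED concatenation of several profiles. Treatment response is carried by
:class:`ResponseRecord` (an mRECIST-like category and its binary collapse into
sensitive/resistant) and a modelling-ready pairing of features with classes is
a :class:`CaseDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ProfileKind",
    "Category",
    "BinaryClass",
    "CnaThresholds",
    "FeatureMatrix",
    "ResponseRecord",
    "CaseDataset",
    "SENSITIVE",
    "RESISTANT",
]


class ProfileKind(str, Enum):
    """Molecular profile kinds; SNV and CNA are binary, CN and GEX real-valued."""

    SNV = "SNV"
    CNA = "CNA"
    CN = "CN"
    GEX = "GEX"
    MERGED = "MERGED"

    @property
    def is_binary(self) -> bool:
        return self in (ProfileKind.SNV, ProfileKind.CNA)


class Category(str, Enum):
    """mRECIST-like response categories, from best to worst."""

    CR = "CR"  # complete response
    PR = "PR"  # partial response
    SD = "SD"  # stable disease
    PD = "PD"  # progressive disease


class BinaryClass(str, Enum):
    SENSITIVE = "sensitive"
    RESISTANT = "resistant"


SENSITIVE = BinaryClass.SENSITIVE
RESISTANT = BinaryClass.RESISTANT

#: Categories collapsing to the sensitive (responder) class.
RESPONDER_CATEGORIES = frozenset({Category.CR, Category.PR, Category.SD})


@dataclass(frozen=True)
class CnaThresholds:
    """Copy-number bands defining an aberrant gene.

    A gene is moderately amplified (Amp5) when its copy number is >= ``amp5_low``
    and < ``amp8_low``, strongly amplified (Amp8) when >= ``amp8_low``, and
    deleted (Del0.8) when <= ``del_high``. Values in the open band
    (``del_high``, ``amp5_low``) are copy-number neutral.
    """

    amp5_low: float = 5.0
    amp8_low: float = 8.0
    del_high: float = 0.8

    def __post_init__(self) -> None:
        if not (self.del_high < self.amp5_low < self.amp8_low):
            raise ValueError(
                "CnaThresholds require del_high < amp5_low < amp8_low, got "
                f"{self.del_high}, {self.amp5_low}, {self.amp8_low}"
            )

    def is_aberrant(self, cn: float) -> bool:
        return cn >= self.amp5_low or cn <= self.del_high


class FeatureMatrix:
    """A validated sample x feature matrix for one molecular profile.

    Parameters
    ----------
    values : pandas.DataFrame
        Samples as rows (index = PDX identifiers), gene-level features as
        columns. Must contain no missing values. Binary profiles (SNV, CNA)
        must be 0/1; real-valued profiles (CN, GEX) must be finite and >= 0.
    profile_kind : ProfileKind
        The profile the matrix encodes.
    """

    def __init__(self, values: pd.DataFrame, profile_kind: ProfileKind) -> None:
        profile_kind = ProfileKind(profile_kind)
        if not values.index.is_unique:
            raise ValueError("duplicate sample identifiers")
        if not values.columns.is_unique:
            raise ValueError("duplicate feature identifiers")
        arr = values.to_numpy(dtype=float)
        if arr.size and not np.isfinite(arr).all():
            raise ValueError("feature matrix contains missing or non-finite values")
        if profile_kind.is_binary:
            if arr.size and not np.isin(arr, (0.0, 1.0)).all():
                raise ValueError(f"{profile_kind.value} profile must be binary 0/1")
        elif profile_kind in (ProfileKind.CN, ProfileKind.GEX):
            if arr.size and (arr < 0).any():
                raise ValueError(f"{profile_kind.value} profile must be non-negative")
        self._values = values.astype(float)
        self.profile_kind = profile_kind

    # -- accessors ---------------------------------------------------------
    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def sample_ids(self) -> list[str]:
        return list(self._values.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self._values.columns)

    @property
    def n_samples(self) -> int:
        return self._values.shape[0]

    @property
    def n_features(self) -> int:
        return self._values.shape[1]

    def to_numpy(self) -> np.ndarray:
        return self._values.to_numpy(dtype=np.float64)

    # -- subsetting --------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "FeatureMatrix":
        missing = [s for s in sample_ids if s not in self._values.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return FeatureMatrix(self._values.loc[list(sample_ids)], self.profile_kind)

    def select_features(self, feature_ids: Sequence[str]) -> "FeatureMatrix":
        missing = [f for f in feature_ids if f not in self._values.columns]
        if missing:
            raise KeyError(f"unknown feature ids: {missing[:5]}")
        return FeatureMatrix(self._values[list(feature_ids)], self.profile_kind)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"FeatureMatrix({self.profile_kind.value}, "
            f"{self.n_samples} samples x {self.n_features} features)"
        )


def binarize_category(category: Category | str) -> BinaryClass:
    """Collapse an mRECIST-like category into sensitive/resistant.

    CR, PR and SD tumours showed some level of sensitivity and are responders
    (sensitive); PD tumours are non-responders (resistant).
    """
    category = Category(category)
    return SENSITIVE if category in RESPONDER_CATEGORIES else RESISTANT


@dataclass(frozen=True)
class ResponseRecord:
    """Response of one PDX to one treatment."""

    pdx_id: str
    treatment_id: str
    category: Category
    source: str = "calculated"  # "retrieved" or "calculated"

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", Category(self.category))
        if self.source not in ("retrieved", "calculated"):
            raise ValueError(f"unknown response source {self.source!r}")

    @property
    def binary_class(self) -> BinaryClass:
        return binarize_category(self.category)


@dataclass
class CaseDataset:
    """Paired feature vectors and binary response classes for one case.

    A case is one treatment x cancer-type x molecular-profile combination.
    ``classes`` is indexed by PDX id with values 1 (sensitive) / 0 (resistant)
    and covers exactly ``features.sample_ids`` in the same order.
    """

    treatment_id: str
    cancer_type: str
    features: FeatureMatrix
    classes: pd.Series
    min_n: int = 35
    dropped_samples: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if list(self.classes.index) != self.features.sample_ids:
            raise ValueError("classes must cover exactly the feature samples, in order")
        if self.n < 2:
            raise ValueError("a case needs at least 2 PDXs")
        vals = set(self.classes.astype(int))
        if not vals <= {0, 1}:
            raise ValueError("classes must be binary 0 (resistant) / 1 (sensitive)")
        self.classes = self.classes.astype(np.int8)

    @property
    def profile_kind(self) -> ProfileKind:
        return self.features.profile_kind

    @property
    def n(self) -> int:
        return self.features.n_samples

    @property
    def n_sensitive(self) -> int:
        return int(self.classes.sum())

    @property
    def n_resistant(self) -> int:
        return self.n - self.n_sensitive

    @property
    def degenerate(self) -> bool:
        """True when only one response class is present (unmodelable)."""
        return self.n_sensitive == 0 or self.n_resistant == 0

    @property
    def below_threshold(self) -> bool:
        """True when the case has fewer PDXs than the inclusion threshold."""
        return self.n < self.min_n

    def y(self) -> np.ndarray:
        return self.classes.to_numpy(dtype=np.int8)

    def subset(self, sample_ids: Sequence[str]) -> "CaseDataset":
        """Restrict the case to the given PDXs (used to form CV training folds)."""
        return CaseDataset(
            treatment_id=self.treatment_id,
            cancer_type=self.cancer_type,
            features=self.features.select_samples(sample_ids),
            classes=self.classes.loc[list(sample_ids)],
            min_n=self.min_n,
        )

    def drop_sample(self, sample_id: str) -> "CaseDataset":
        keep = [s for s in self.features.sample_ids if s != sample_id]
        if len(keep) == self.n:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return self.subset(keep)
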