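"""Percentile-band point allocation and weighted case scores.

Points are allocated to a case value by its position relative to the
drug phenotype's empirical distribution:

=====================================  =========  ======
Value within                           fraction   points
=====================================  =========  ======
IQR (p25 to p75)                        100%        20
p15-p25 or p75-p85                       50%        10
p10-p15 or p85-p90                       25%         5
min-p10 or p90-max                        0%         0
below min / above max (not an outlier)  -25%        -5
outlier within the observed range       -25%        -5
both outside the range and an outlier   -50%       -10
=====================================  =========  ======

All band boundaries are closed toward the centre: a value exactly at a
knot takes the more central (more favourable) band.  An "outlier" is a
value strictly beyond a fence; with the default range +/- k*IQR fences an
outlier is necessarily also outside the range, so the -10 row applies.

A case's weighted total doubles the subscore of one designated feature
(the feature that best discriminates the two drugs under comparison, see
:mod:`dilicat.stats`), giving a theoretical range of [-40, 80].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .phenotype import (
    FEATURES,
    CaseRecord,
    DrugPhenotype,
    FeaturePhenotype,
    ValidationError,
)

__all__ = [
    "Band",
    "CaseScore",
    "CohortSummary",
    "allocate_points",
    "score_case",
    "score_cohort",
    "theoretical_bounds",
    "MAX_SUBSCORE",
]

#: Full-credit subscore for a value inside the IQR.
MAX_SUBSCORE = 20


class Band(Enum):
    """Scoring band, with its fraction of the full 20 points."""

    CORE = ("core", 1.0)
    NEAR = ("near", 0.5)
    FAR = ("far", 0.25)
    TAIL = ("tail", 0.0)
    OUTSIDE = ("outside", -0.25)
    OUTLIER_WITHIN = ("outlier_within", -0.25)
    OUTSIDE_OUTLIER = ("outside_outlier", -0.5)

    @property
    def fraction(self) -> float:
        return self.value[1]

    @property
    def points(self) -> int:
        return int(MAX_SUBSCORE * self.fraction)


def allocate_points(value: float, fp: FeaturePhenotype) -> Band:
    """Classify a feature value into its scoring band.

    Bands are closed toward the centre; outlier status means strictly
    beyond a fence.  Every finite value maps to exactly one band.
    """
    if value is None or not math.isfinite(float(value)):
        raise ValidationError(f"cannot allocate points for value {value!r}")
    v = float(value)
    is_outlier = v < fp.lower_fence or v > fp.upper_fence
    if v < fp.minimum or v > fp.maximum:
        return Band.OUTSIDE_OUTLIER if is_outlier else Band.OUTSIDE
    if is_outlier:
        # possible only with fences configured tighter than the range
        return Band.OUTLIER_WITHIN
    if fp.p25 <= v <= fp.p75:
        return Band.CORE
    if fp.p15 <= v <= fp.p85:
        return Band.NEAR
    if fp.p10 <= v <= fp.p90:
        return Band.FAR
    return Band.TAIL


@dataclass(frozen=True)
class CaseScore:
    """Per-feature subscores and totals for one scored case."""

    case_id: str
    subscores: dict[str, int]
    bands: dict[str, str]
    weighted_feature: str | None
    unweighted_total: int
    weighted_total: int

    def __post_init__(self) -> None:
        assert set(self.subscores) == set(FEATURES)


def score_case(case: CaseRecord, phenotype: DrugPhenotype,
               weighted_feature: str | None = None) -> CaseScore:
    """Score one case against a drug phenotype.

    The weighted total doubles the subscore of ``weighted_feature``
    (``None`` leaves the total unweighted).
    """
    if weighted_feature is not None and weighted_feature not in FEATURES:
        raise ValidationError(
            f"unknown weighted_feature {weighted_feature!r}; "
            f"expected one of {FEATURES} or None")
    subscores: dict[str, int] = {}
    bands: dict[str, str] = {}
    for f in FEATURES:
        band = allocate_points(case.feature(f), phenotype.feature_phenotype(f))
        subscores[f] = band.points
        bands[f] = band.name
    unweighted = sum(subscores.values())
    weighted = unweighted
    if weighted_feature is not None:
        weighted += subscores[weighted_feature]
    return CaseScore(case_id=case.case_id, subscores=subscores, bands=bands,
                     weighted_feature=weighted_feature,
                     unweighted_total=unweighted, weighted_total=weighted)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort-level medians of subscores and totals."""

    n: int
    median_subscores: dict[str, float]
    median_unweighted: float
    median_weighted: float
    weighted_feature: str | None


def score_cohort(cases: Sequence[CaseRecord], phenotype: DrugPhenotype,
                 weighted_feature: str | None = None,
                 ) -> tuple[list[CaseScore], CohortSummary]:
    """Score a cohort and summarise with medians.

    Medians use the same convention as phenotype construction (the
    ordinary sample median, which all supported percentile estimators
    share at p = 0.5).
    """
    cases = list(cases)
    if not cases:
        raise ValidationError("cannot score an empty cohort")
    scores = [score_case(c, phenotype, weighted_feature) for c in cases]
    med_sub = {
        f: float(np.median([s.subscores[f] for s in scores])) for f in FEATURES
    }
    summary = CohortSummary(
        n=len(scores),
        median_subscores=med_sub,
        median_unweighted=float(np.median([s.unweighted_total for s in scores])),
        median_weighted=float(np.median([s.weighted_total for s in scores])),
        weighted_feature=weighted_feature,
    )
    return scores, summary


def theoretical_bounds(config=None) -> tuple[int, int]:
    """Extreme achievable totals for a configuration.

    The weighted case score alone spans [-40, 80] (four subscores of
    -10 or 20 once one feature is doubled).  Enabled adjudication
    extensions shift the bounds by the extremes of their rubrics.
    """
    lo = 4 * Band.OUTSIDE_OUTLIER.points
    hi = 4 * MAX_SUBSCORE
    if config is not None:
        if config.enable_competing_causes:
            pts = config.competing_rubric.values()
            lo += min(pts)
            hi += max(pts)
        if config.enable_hepatotoxicity:
            pts = config.hepatotoxicity_rubric.values()
            lo += min(pts)
            hi += max(pts)
    return lo, hi
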