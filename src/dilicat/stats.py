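"""Feature-weighting selection and score-distribution comparison.

Two drugs' phenotypes are compared feature by feature with the
Mann-Whitney rank test; the reported U is ``min(U1, U2)``, so the
*smaller* the U the greater the separation (U = 0 means the two samples
do not overlap at all).  The feature with the smallest U receives
two-fold weight in the case score.

DILI-CAT score distributions are compared with the Mantel-Haenszel
(linear-by-linear) test for trend on 5-point ordinal score bins:
``chi2 = (N - 1) * r**2`` with 1 degree of freedom, where ``r`` is the
Pearson correlation between group membership and ordinal bin score over
all N cases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .phenotype import (
    FEATURES,
    CaseRecord,
    PhenotypeConfig,
    ValidationError,
    build_phenotype,
    feature_values,
)
from .scoring import CohortSummary, score_cohort

__all__ = [
    "RankTestResult",
    "TrendTestResult",
    "PairwiseComparison",
    "mann_whitney_u",
    "select_weighted_feature",
    "mh_trend_test",
    "compare_drugs",
]

# exact U distribution is used up to this product of sample sizes (no ties)
_EXACT_LIMIT = 400


@dataclass(frozen=True)
class RankTestResult:
    """Mann-Whitney result; ``u_value`` is min(U1, U2)."""

    u_value: float
    n1: int
    n2: int
    p_value: float
    method: str  # "exact" or "asymptotic"

    def __post_init__(self) -> None:
        assert 0 <= self.u_value <= self.n1 * self.n2


@dataclass(frozen=True)
class TrendTestResult:
    """Linear-by-linear trend chi-square (1 df) on ordinal score bins."""

    statistic: float
    p_value: float
    n_categories: int
    degenerate: bool = False


@dataclass(frozen=True)
class PairwiseComparison:
    """Full drug-vs-drug comparison under one drug's scoring."""

    drug_a: str
    drug_b: str
    per_feature: dict[str, RankTestResult]
    weighted_feature: str
    trend: TrendTestResult
    summary_a: CohortSummary
    summary_b: CohortSummary


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   method: str = "auto") -> RankTestResult:
    """Two-sided Mann-Whitney rank test reporting U = min(U1, U2).

    Ties get midranks; the p-value uses the tie-corrected normal
    approximation, or the exact null distribution when ``n1*n2 <= 400``
    and there are no ties (``method`` may force ``"exact"`` or
    ``"asymptotic"``).
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("mann_whitney_u requires two non-empty samples")
    if method == "auto":
        use_exact = x.size * y.size <= _EXACT_LIMIT and not _has_ties(x, y)
    elif method in ("exact", "asymptotic"):
        use_exact = method == "exact"
        if use_exact and _has_ties(x, y):
            raise ValidationError("exact method is not defined with ties")
    else:
        raise ValidationError("method must be 'auto', 'exact' or 'asymptotic'")
    res = sps.mannwhitneyu(x, y, alternative="two-sided",
                           method="exact" if use_exact else "asymptotic")
    u1 = float(res.statistic)
    u2 = x.size * y.size - u1
    p = float(res.pvalue)
    if math.isnan(p):
        # zero rank variance (all pooled values tied): no evidence of shift
        p = 1.0
    return RankTestResult(u_value=min(u1, u2), n1=int(x.size), n2=int(y.size),
                          p_value=p,
                          method="exact" if use_exact else "asymptotic")


def select_weighted_feature(cases_a: Sequence[CaseRecord],
                            cases_b: Sequence[CaseRecord],
                            ) -> tuple[str, dict[str, RankTestResult]]:
    """Pick the feature that best separates two cohorts (smallest U).

    Ties on U are broken by the fixed priority latency > r_value >
    ast_alt_ratio, making the choice deterministic.
    """
    if not cases_a or not cases_b:
        raise ValidationError("both cohorts must be non-empty")
    results = {
        f: mann_whitney_u(feature_values(cases_a, f), feature_values(cases_b, f))
        for f in FEATURES
    }
    # FEATURES order is the tie-break priority; min() keeps the first minimum
    best = min(FEATURES, key=lambda f: results[f].u_value)
    return best, results


def mh_trend_test(scores_a: Sequence[float],
                  scores_b: Sequence[float]) -> TrendTestResult:
    """Trend test on 5-point score bins between two score lists.

    Scores are binned at fixed global edges (bin index = floor(score/5));
    the statistic is ``(N-1) * r**2`` for the Pearson correlation ``r``
    between group indicator and bin score, referred to chi-square with
    1 df.  The statistic is invariant under positive affine transforms of
    the bin scores.  If all cases fall in a single bin the trend is
    undefined; a degenerate result (statistic 0, p 1) is returned.
    """
    a = np.asarray(list(scores_a), dtype=float)
    b = np.asarray(list(scores_b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("mh_trend_test requires two non-empty score lists")
    bins = np.floor(np.concatenate([a, b]) / 5.0)
    group = np.concatenate([np.zeros(a.size), np.ones(b.size)])
    n_cat = int(np.unique(bins).size)
    n = bins.size
    if n_cat < 2 or np.var(group) == 0 or n < 2:
        return TrendTestResult(statistic=0.0, p_value=1.0,
                               n_categories=n_cat, degenerate=True)
    r = float(np.corrcoef(group, bins)[0, 1])
    statistic = (n - 1) * r * r
    p = float(sps.chi2.sf(statistic, df=1))
    return TrendTestResult(statistic=float(statistic), p_value=p,
                           n_categories=n_cat)


def compare_drugs(cases_a: Sequence[CaseRecord],
                  cases_b: Sequence[CaseRecord],
                  config: PhenotypeConfig | None = None) -> PairwiseComparison:
    """Compare drug B against drug A under drug A's DILI-CAT scoring.

    Builds the phenotype from cohort A, selects the weighted feature from
    the A-vs-B rank tests, scores both cohorts against the A phenotype
    with that weighting, and tests the two weighted-score distributions
    for trend.
    """
    cases_a, cases_b = list(cases_a), list(cases_b)
    if not cases_a or not cases_b:
        raise ValidationError("both cohorts must be non-empty")
    phenotype = build_phenotype(cases_a, config)
    weighted, per_feature = select_weighted_feature(cases_a, cases_b)
    scores_a, summary_a = score_cohort(cases_a, phenotype, weighted)
    scores_b, summary_b = score_cohort(cases_b, phenotype, weighted)
    trend = mh_trend_test([s.weighted_total for s in scores_a],
                          [s.weighted_total for s in scores_b])
    return PairwiseComparison(
        drug_a=cases_a[0].drug, drug_b=cases_b[0].drug,
        per_feature=per_feature, weighted_feature=weighted, trend=trend,
        summary_a=summary_a, summary_b=summary_b)
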