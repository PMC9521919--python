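"""Case-level DILI features and drug-specific phenotype construction.

A drug's DILI phenotype is the empirical distribution of three clinical
features over bona fide cases attributed to that drug:

* **latency** — days from drug start to liver-injury onset;
* **R-value** — (ALT/ULN_ALT) / (ALP/ULN_ALP) at onset, the standard
  injury-pattern ratio (>5 hepatocellular, <2 cholestatic, 2-5 mixed);
* **AST/ALT ratio** — the De Ritis ratio at onset.

The phenotype for one feature is summarised by a 9-knot empirical quantile
profile (min, p10, p15, p25, median, p75, p85, p90, max) plus outlier
fences.  The knots delimit the scoring bands of the point-allocation
engine in :mod:`dilicat.scoring`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FEATURES",
    "KNOT_NAMES",
    "KNOT_PROBS",
    "ValidationError",
    "CaseRecord",
    "RawLabs",
    "FeaturePhenotype",
    "DrugPhenotype",
    "PhenotypeConfig",
    "derive_features",
    "build_phenotype",
    "feature_values",
]

#: Clinical features making up a phenotype, in fixed priority order
#: (used for deterministic tie-breaking when selecting a weighting).
FEATURES: tuple[str, ...] = ("latency", "r_value", "ast_alt_ratio")

#: Quantile probabilities of the 9 phenotype knots.
KNOT_PROBS: tuple[float, ...] = (0.0, 0.10, 0.15, 0.25, 0.50, 0.75, 0.85, 0.90, 1.0)
KNOT_NAMES: tuple[str, ...] = (
    "min", "p10", "p15", "p25", "median", "p75", "p85", "p90", "max",
)

# numpy.quantile method names for the two supported estimator conventions
_QUANTILE_METHODS = {"type7": "linear", "type6": "weibull"}


class ValidationError(ValueError):
    """Invalid input data or configuration."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


@dataclass(frozen=True)
class CaseRecord:
    """One DILI case: identifying labels plus the three onset features."""

    case_id: str
    drug: str
    latency_days: float
    r_value: float
    ast_alt_ratio: float

    def __post_init__(self) -> None:
        for name in ("latency_days", "r_value", "ast_alt_ratio"):
            v = getattr(self, name)
            _require(v is not None and math.isfinite(float(v)),
                     f"case {self.case_id!r}: {name} must be a finite number")
        _require(self.latency_days > 0,
                 f"case {self.case_id!r}: latency_days must be > 0")
        _require(self.r_value >= 0,
                 f"case {self.case_id!r}: r_value must be >= 0")
        _require(self.ast_alt_ratio > 0,
                 f"case {self.case_id!r}: ast_alt_ratio must be > 0")

    def feature(self, name: str) -> float:
        if name == "latency":
            return float(self.latency_days)
        if name in ("r_value", "ast_alt_ratio"):
            return float(getattr(self, name))
        raise ValidationError(f"unknown feature {name!r}; expected one of {FEATURES}")


@dataclass(frozen=True)
class RawLabs:
    """Onset laboratory values from which R-value and AST/ALT are derived.

    All activities are in U/L; ULNs are the assay's upper limits of normal.
    """

    alt: float
    alt_uln: float
    alp: float
    alp_uln: float
    ast: float
    ast_uln: float | None = None  # only needed for ULN-normalised AST/ALT

    def __post_init__(self) -> None:
        names = ["alt", "alt_uln", "alp", "alp_uln", "ast"]
        if self.ast_uln is not None:
            names.append("ast_uln")
        for name in names:
            v = getattr(self, name)
            _require(v is not None and math.isfinite(float(v)) and v > 0,
                     f"lab value {name!r} must be a finite positive number")


@dataclass(frozen=True)
class PhenotypeConfig:
    """Settings controlling phenotype construction.

    Parameters
    ----------
    percentile_convention:
        ``"type7"`` (linear interpolation at ``p*(n-1)+1``; default) or
        ``"type6"`` (at ``p*(n+1)``).
    outlier_k:
        Fence multiplier: fences sit at ``min - k*IQR`` and
        ``max + k*IQR``.  1.5 is the conventional robust margin.
    degenerate_epsilon:
        Absolute fence margin used when the IQR is zero (all knots equal);
        0 means a degenerate phenotype never flags outliers.
    ast_alt_uln_normalized:
        If True, the AST/ALT ratio is computed on ULN-normalised
        activities instead of raw activities.  Off by default (the
        conventional De Ritis ratio).
    round_latency:
        Round latencies to whole days at ingest.  Off by default.
    """

    percentile_convention: str = "type7"
    outlier_k: float = 1.5
    degenerate_epsilon: float = 0.0
    ast_alt_uln_normalized: bool = False
    round_latency: bool = False

    def __post_init__(self) -> None:
        _require(self.percentile_convention in _QUANTILE_METHODS,
                 f"percentile_convention must be one of {sorted(_QUANTILE_METHODS)}")
        _require(self.outlier_k > 0, "outlier_k must be positive")
        _require(self.degenerate_epsilon >= 0, "degenerate_epsilon must be >= 0")

    @property
    def quantile_method(self) -> str:
        return _QUANTILE_METHODS[self.percentile_convention]


@dataclass(frozen=True)
class FeaturePhenotype:
    """9-knot empirical quantile profile plus outlier fences for one feature."""

    feature: str
    knots: tuple[float, ...]
    lower_fence: float
    upper_fence: float
    n: int
    interpolated_knots: tuple[str, ...] = ()
    notes: str = ""

    def __post_init__(self) -> None:
        _require(self.feature in FEATURES,
                 f"feature must be one of {FEATURES}, got {self.feature!r}")
        _require(len(self.knots) == len(KNOT_PROBS),
                 f"expected {len(KNOT_PROBS)} knots, got {len(self.knots)}")
        ks = [float(k) for k in self.knots]
        _require(all(math.isfinite(k) for k in ks), "knots must be finite")
        _require(all(a <= b for a, b in zip(ks, ks[1:])),
                 f"knots must be non-decreasing: {ks}")
        _require(self.upper_fence >= self.lower_fence,
                 "upper_fence must be >= lower_fence")
        _require(self.n >= 2, "a phenotype requires at least 2 cases")
        object.__setattr__(self, "knots", tuple(ks))

    def knot(self, name: str) -> float:
        return self.knots[KNOT_NAMES.index(name)]

    # Convenience accessors for the named knots
    @property
    def minimum(self) -> float: return self.knots[0]
    @property
    def p10(self) -> float: return self.knots[1]
    @property
    def p15(self) -> float: return self.knots[2]
    @property
    def p25(self) -> float: return self.knots[3]
    @property
    def median(self) -> float: return self.knots[4]
    @property
    def p75(self) -> float: return self.knots[5]
    @property
    def p85(self) -> float: return self.knots[6]
    @property
    def p90(self) -> float: return self.knots[7]
    @property
    def maximum(self) -> float: return self.knots[8]
    @property
    def iqr(self) -> float: return self.p75 - self.p25


@dataclass(frozen=True)
class DrugPhenotype:
    """The three feature phenotypes for one drug, with provenance."""

    drug: str
    latency: FeaturePhenotype
    r_value: FeaturePhenotype
    ast_alt_ratio: FeaturePhenotype
    n_cases: int
    provenance: str = ""

    def __post_init__(self) -> None:
        for name in FEATURES:
            fp = self.feature_phenotype(name)
            _require(fp.feature == name,
                     f"feature phenotype in slot {name!r} is labelled {fp.feature!r}")
            _require(fp.n == self.n_cases,
                     "all feature phenotypes must share the drug's case count")

    def feature_phenotype(self, name: str) -> FeaturePhenotype:
        if name not in FEATURES:
            raise ValidationError(
                f"unknown feature {name!r}; expected one of {FEATURES}")
        return getattr(self, name)


def derive_features(labs: RawLabs, latency_days: float, *,
                    case_id: str = "", drug: str = "",
                    config: PhenotypeConfig | None = None) -> CaseRecord:
    """Derive R-value and AST/ALT ratio from raw onset labs.

    ``r_value = (ALT/ULN_ALT) / (ALP/ULN_ALP)``; the AST/ALT ratio is
    ``AST/ALT`` on raw activities unless ``config.ast_alt_uln_normalized``
    is set.  Latency passes through unchanged (optionally rounded).
    """
    config = config or PhenotypeConfig()
    r_value = (labs.alt / labs.alt_uln) / (labs.alp / labs.alp_uln)
    if config.ast_alt_uln_normalized:
        if labs.ast_uln is None:
            raise ValidationError(
                "ast_uln is required when ast_alt_uln_normalized is enabled")
        ast_alt = (labs.ast / labs.ast_uln) / (labs.alt / labs.alt_uln)
    else:
        ast_alt = labs.ast / labs.alt
    latency = float(latency_days)
    if config.round_latency:
        latency = float(round(latency))
    return CaseRecord(case_id=case_id, drug=drug, latency_days=latency,
                      r_value=r_value, ast_alt_ratio=ast_alt)


def feature_values(cases: Sequence[CaseRecord], feature: str) -> np.ndarray:
    """Extract one feature from a cohort as a float array."""
    return np.asarray([c.feature(feature) for c in cases], dtype=float)


def _build_feature(feature: str, values: np.ndarray,
                   config: PhenotypeConfig) -> FeaturePhenotype:
    knots = np.quantile(values, KNOT_PROBS, method=config.quantile_method)
    lo, hi, iqr = knots[0], knots[-1], knots[5] - knots[3]
    if iqr > 0:
        lower, upper = lo - config.outlier_k * iqr, hi + config.outlier_k * iqr
    elif config.degenerate_epsilon > 0:
        eps = config.degenerate_epsilon
        lower, upper = lo - eps, hi + eps
    else:
        # zero IQR and no epsilon margin: nothing ever counts as an outlier
        lower, upper = -math.inf, math.inf
    return FeaturePhenotype(feature=feature, knots=tuple(knots),
                            lower_fence=float(lower), upper_fence=float(upper),
                            n=int(values.size))


def build_phenotype(cases: Iterable[CaseRecord],
                    config: PhenotypeConfig | None = None,
                    provenance: str = "") -> DrugPhenotype:
    """Build a drug phenotype from a case series.

    Requires at least two cases, all with the same drug label.  Knots are
    the empirical quantiles at the 9 knot probabilities under the
    configured estimator; fences follow the configured outlier rule.
    """
    config = config or PhenotypeConfig()
    cases = list(cases)
    _require(len(cases) >= 2, "a phenotype requires at least 2 cases")
    drugs = sorted({c.drug for c in cases})
    _require(len(drugs) == 1,
             f"all cases must share one drug label, found {drugs}")
    parts = {
        f: _build_feature(f, feature_values(cases, f), config) for f in FEATURES
    }
    return DrugPhenotype(drug=drugs[0], latency=parts["latency"],
                         r_value=parts["r_value"],
                         ast_alt_ratio=parts["ast_alt_ratio"],
                         n_cases=len(cases), provenance=provenance)
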