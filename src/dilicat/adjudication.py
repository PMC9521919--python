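"""Optional add-on scores for a complete causality adjudication.

Beyond the phenotype-proximity score, a full adjudication may credit the
absence of competing causes (-25 to 25 points: a thorough negative
workup adds points, a definite alternative cause subtracts them) and the
drug's intrinsic hepatotoxicity propensity (0 to 20 points).

The point *ranges* are fixed; the category ladders inside them are
configuration-supplied.  The defaults below are this package's own
ladders spanning those ranges — replace them with a clinically validated
rubric for real adjudication.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .phenotype import ValidationError
from .scoring import CaseScore, theoretical_bounds

__all__ = [
    "AdjudicationConfig",
    "DEFAULT_COMPETING_RUBRIC",
    "DEFAULT_HEPATOTOXICITY_RUBRIC",
    "competing_cause_points",
    "hepatotoxicity_points",
    "total_adjudication_score",
]

COMPETING_RANGE = (-25, 25)
HEPATOTOXICITY_RANGE = (0, 20)

#: Default 5-level competing-cause ladder spanning -25..25.
DEFAULT_COMPETING_RUBRIC: dict[str, int] = {
    "none identified, workup complete": 25,
    "none identified, workup incomplete": 12,
    "possible alternative cause": 0,
    "probable alternative cause": -12,
    "definite alternative cause": -25,
}

#: Default 3-level hepatotoxicity-propensity ladder spanning 0..20.
DEFAULT_HEPATOTOXICITY_RUBRIC: dict[str, int] = {
    "low propensity": 0,
    "intermediate propensity": 10,
    "high propensity": 20,
}


@dataclass(frozen=True)
class AdjudicationConfig:
    """Extension flags, rubrics, and shared scoring conventions."""

    enable_competing_causes: bool = False
    enable_hepatotoxicity: bool = False
    competing_rubric: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_COMPETING_RUBRIC))
    hepatotoxicity_rubric: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_HEPATOTOXICITY_RUBRIC))
    outlier_k: float = 1.5
    percentile_convention: str = "type7"

    def __post_init__(self) -> None:
        lo, hi = COMPETING_RANGE
        for label, pts in self.competing_rubric.items():
            if not lo <= pts <= hi:
                raise ValidationError(
                    f"competing rubric {label!r}: {pts} outside [{lo}, {hi}]")
        if max(self.competing_rubric.values()) != hi or \
           min(self.competing_rubric.values()) != lo:
            raise ValidationError(
                "competing rubric must span the full range: a top "
                f"'no competing cause' category at {hi} and a bottom "
                f"'definite alternative cause' category at {lo}")
        lo, hi = HEPATOTOXICITY_RANGE
        for label, pts in self.hepatotoxicity_rubric.items():
            if not lo <= pts <= hi:
                raise ValidationError(
                    f"hepatotoxicity rubric {label!r}: {pts} outside [{lo}, {hi}]")


def competing_cause_points(label: str, config: AdjudicationConfig) -> int:
    """Points for a competing-cause assessment label."""
    try:
        return config.competing_rubric[label]
    except KeyError:
        raise ValidationError(
            f"unknown competing-cause label {label!r}; valid labels: "
            f"{sorted(config.competing_rubric)}") from None


def hepatotoxicity_points(label: str, config: AdjudicationConfig) -> int:
    """Points for a drug's hepatotoxicity-propensity category."""
    try:
        return config.hepatotoxicity_rubric[label]
    except KeyError:
        raise ValidationError(
            f"unknown hepatotoxicity label {label!r}; valid labels: "
            f"{sorted(config.hepatotoxicity_rubric)}") from None


def total_adjudication_score(case_score: CaseScore,
                             competing: int | None = None,
                             hepatotox: int | None = None,
                             config: AdjudicationConfig | None = None) -> int:
    """Combine the weighted case score with enabled extension points.

    The result always lies within ``theoretical_bounds`` for the active
    configuration.
    """
    config = config or AdjudicationConfig(
        enable_competing_causes=competing is not None,
        enable_hepatotoxicity=hepatotox is not None)
    total = case_score.weighted_total
    if config.enable_competing_causes:
        if competing is None:
            raise ValidationError(
                "competing-cause points required when the extension is enabled")
        lo, hi = COMPETING_RANGE
        if not lo <= competing <= hi:
            raise ValidationError(
                f"competing-cause points {competing} outside [{lo}, {hi}]")
        total += competing
    if config.enable_hepatotoxicity:
        if hepatotox is None:
            raise ValidationError(
                "hepatotoxicity points required when the extension is enabled")
        lo, hi = HEPATOTOXICITY_RANGE
        if not lo <= hepatotox <= hi:
            raise ValidationError(
                f"hepatotoxicity points {hepatotox} outside [{lo}, {hi}]")
        total += hepatotox
    lo, hi = theoretical_bounds(config)
    assert lo <= total <= hi
    return total
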