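"""Band allocation engine and weighted case scores."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dilicat import (
    AdjudicationConfig,
    Band,
    CaseRecord,
    FeaturePhenotype,
    ValidationError,
    allocate_points,
    build_phenotype,
    score_case,
    score_cohort,
    theoretical_bounds,
)
from dilicat.phenotype import FEATURES

from conftest import make_cases


def band_oracle(value, fp):
    """Independent nested-interval classifier for the band scheme.

    Works from the centre outward over closed intervals, so knot ties
    resolve to the more central band by construction.
    """
    outlier = value < fp.lower_fence or value > fp.upper_fence
    in_range = fp.minimum <= value <= fp.maximum
    if not in_range:
        return -10 if outlier else -5
    if outlier:
        return -5
    if fp.p25 <= value <= fp.p75:
        return 20
    if fp.p15 <= value <= fp.p85:
        return 10
    if fp.p10 <= value <= fp.p90:
        return 5
    return 0


def fp_from_ints(vals):
    return build_phenotype(make_cases([float(v) for v in vals])).latency


class TestAllocatePoints:
    def test_table_bands_on_1_to_100(self, phenotype_1_to_100):
        fp = phenotype_1_to_100.latency  # knots 1,10.9,15.85,25.75,50.5,75.25,...
        assert allocate_points(fp.median, fp) is Band.CORE
        assert allocate_points(20.0, fp) is Band.NEAR          # p15..p25
        assert allocate_points(80.0, fp) is Band.NEAR          # p75..p85
        assert allocate_points(12.0, fp) is Band.FAR           # p10..p15
        assert allocate_points(88.0, fp) is Band.FAR           # p85..p90
        assert allocate_points(5.0, fp) is Band.TAIL           # min..p10
        assert allocate_points(95.0, fp) is Band.TAIL          # p90..max
        assert allocate_points(0.5, fp) is Band.OUTSIDE        # below min, in fence
        assert allocate_points(150.0, fp) is Band.OUTSIDE      # above max, in fence
        assert allocate_points(1e6, fp) is Band.OUTSIDE_OUTLIER
        assert allocate_points(-1e6, fp) is Band.OUTSIDE_OUTLIER

    def test_knot_boundaries_take_central_band(self, phenotype_1_to_100):
        fp = phenotype_1_to_100.latency
        assert allocate_points(fp.p25, fp) is Band.CORE
        assert allocate_points(fp.p75, fp) is Band.CORE
        assert allocate_points(fp.p15, fp) is Band.NEAR
        assert allocate_points(fp.p85, fp) is Band.NEAR
        assert allocate_points(fp.p10, fp) is Band.FAR
        assert allocate_points(fp.p90, fp) is Band.FAR
        assert allocate_points(fp.minimum, fp) is Band.TAIL
        assert allocate_points(fp.maximum, fp) is Band.TAIL

    def test_fence_boundary_is_not_outlier(self, phenotype_1_to_100):
        fp = phenotype_1_to_100.latency
        assert allocate_points(fp.upper_fence, fp) is Band.OUTSIDE
        assert allocate_points(np.nextafter(fp.upper_fence, np.inf),
                               fp) is Band.OUTSIDE_OUTLIER

    def test_degenerate_phenotype_collapses_to_core(self):
        fp = build_phenotype(make_cases([3.0] * 6)).latency
        assert allocate_points(3.0, fp) is Band.CORE
        # default epsilon 0: off-centre values are outside-range, never outliers
        assert allocate_points(3.1, fp) is Band.OUTSIDE
        assert allocate_points(1e9, fp) is Band.OUTSIDE

    def test_fences_inside_range_give_outlier_within(self):
        fp = FeaturePhenotype(feature="latency",
                              knots=(0, 10, 15, 25, 50, 75, 85, 90, 100),
                              lower_fence=5, upper_fence=95, n=10)
        assert allocate_points(2.0, fp) is Band.OUTLIER_WITHIN
        assert allocate_points(2.0, fp).points == -5
        assert allocate_points(98.0, fp) is Band.OUTLIER_WITHIN

    @pytest.mark.parametrize("bad", [float("nan"), float("inf"), None])
    def test_nonfinite_value_rejected(self, bad, phenotype_1_to_100):
        with pytest.raises(ValidationError):
            allocate_points(bad, phenotype_1_to_100.latency)

    def test_points_are_20_times_fraction(self):
        for band in Band:
            assert band.points == 20 * band.fraction

    @given(st.lists(st.integers(1, 30), min_size=2, max_size=12),
           st.floats(min_value=-100, max_value=100))
    def test_matches_nested_interval_oracle(self, vals, value):
        fp = fp_from_ints(vals)
        assert allocate_points(value, fp).points == band_oracle(value, fp)

    @given(st.lists(st.floats(1, 1000), min_size=3, max_size=30),
           st.floats(min_value=-1e4, max_value=1e4))
    def test_every_finite_value_maps_to_one_band(self, vals, value):
        fp = build_phenotype(make_cases(vals)).latency
        assert allocate_points(value, fp) in Band

    @given(st.lists(st.floats(1, 1000), min_size=4, max_size=30,
                    unique=True))
    def test_points_nonincreasing_away_from_iqr(self, vals):
        fp = build_phenotype(make_cases(vals)).latency
        lo, hi = min(vals), max(vals)
        span = hi - lo
        probes = np.linspace(fp.p75, hi + 3 * span + 1, 40)
        pts = [allocate_points(v, fp).points for v in probes]
        assert all(a >= b for a, b in zip(pts, pts[1:]))
        probes = np.linspace(fp.p25, lo - 3 * span - 1, 40)
        pts = [allocate_points(v, fp).points for v in probes]
        assert all(a >= b for a, b in zip(pts, pts[1:]))


class TestScoreCase:
    def _case(self, lat, r, ratio):
        return CaseRecord("c1", "drugX", lat, r, ratio)

    def test_case_at_all_medians_scores_80_weighted(self, phenotype_1_to_100):
        ph = phenotype_1_to_100
        case = self._case(ph.latency.median, ph.r_value.median,
                          ph.ast_alt_ratio.median)
        for f in FEATURES:
            s = score_case(case, ph, weighted_feature=f)
            assert s.subscores == {k: 20 for k in FEATURES}
            assert s.weighted_total == 80
            assert s.unweighted_total == 60

    def test_case_past_all_fences_scores_minus_40(self, phenotype_1_to_100):
        case = self._case(1e9, 1e9, 1e9)  # far beyond every upper fence
        s = score_case(case, phenotype_1_to_100, weighted_feature="r_value")
        assert all(v == -10 for v in s.subscores.values())
        assert s.weighted_total == -40

    def test_no_weighting_identity(self, phenotype_1_to_100):
        ph = phenotype_1_to_100
        case = self._case(ph.latency.median, 12.0, 95.0)
        s = score_case(case, ph, weighted_feature=None)
        assert s.weighted_total == s.unweighted_total == sum(s.subscores.values())

    def test_unknown_weighted_feature_rejected(self, phenotype_1_to_100):
        case = self._case(50, 50, 50)
        with pytest.raises(ValidationError, match="weighted_feature"):
            score_case(case, phenotype_1_to_100, weighted_feature="alp")

    @given(st.lists(st.floats(1, 500), min_size=2, max_size=25),
           st.floats(1, 500), st.floats(1, 500), st.floats(1, 500))
    def test_totals_obey_invariants(self, vals, lat, r, ratio):
        ph = build_phenotype(make_cases(vals))
        s = score_case(CaseRecord("c", "drugX", lat, r, ratio),
                       ph, weighted_feature="latency")
        assert s.unweighted_total == sum(s.subscores.values())
        assert s.weighted_total == s.unweighted_total + s.subscores["latency"]
        assert -40 <= s.weighted_total <= 80


class TestScoreCohort:
    def test_empty_cohort_rejected(self, phenotype_1_to_100):
        with pytest.raises(ValidationError, match="empty"):
            score_cohort([], phenotype_1_to_100)

    def test_repeated_case_median_is_case_score(self, phenotype_1_to_100):
        case = CaseRecord("c", "drugX", 50.5, 50.5, 50.5)
        scores, summary = score_cohort([case] * 7, phenotype_1_to_100,
                                       weighted_feature="latency")
        assert summary.median_weighted == scores[0].weighted_total == 80

    def test_median_matches_bruteforce_over_individual_scores(self):
        rng = np.random.default_rng(11)
        vals = rng.uniform(1, 200, size=30)
        cases = make_cases(vals)
        ph = build_phenotype(cases)
        scores, summary = score_cohort(cases, ph, weighted_feature="r_value")
        assert summary.median_weighted == np.median(
            [score_case(c, ph, "r_value").weighted_total for c in cases])

    def test_self_scoring_yields_median_subscore_20(self):
        rng = np.random.default_rng(5)
        for n in (10, 19, 22, 35):
            cases = make_cases(rng.uniform(1, 365, size=n))
            ph = build_phenotype(cases)
            _, summary = score_cohort(cases, ph)
            for f in FEATURES:
                vals = [c.feature(f) for c in cases]
                fp = ph.feature_phenotype(f)
                in_iqr = sum(fp.p25 <= v <= fp.p75 for v in vals)
                if in_iqr > n / 2:
                    assert summary.median_subscores[f] == 20


class TestTheoreticalBounds:
    def test_no_extensions(self):
        assert theoretical_bounds() == (-40, 80)

    def test_both_extensions(self):
        cfg = AdjudicationConfig(enable_competing_causes=True,
                                 enable_hepatotoxicity=True)
        assert theoretical_bounds(cfg) == (-65, 125)

    def test_competing_only(self):
        cfg = AdjudicationConfig(enable_competing_causes=True)
        assert theoretical_bounds(cfg) == (-65, 105)

    def test_hepatotoxicity_only(self):
        cfg = AdjudicationConfig(enable_hepatotoxicity=True)
        assert theoretical_bounds(cfg) == (-40, 100)
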