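"""Welch tests, Fisher combination, thresholds and two-stage hit calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import httscreen as hs
from httscreen.errors import (
    InsufficientDataError,
    UndefinedRatioError,
    ValidationError,
)
from httscreen.stats import (
    P_FLOOR,
    FeatureTestResult,
    MorphologyBaseline,
    Stage1Rule,
    display_p,
)

samples = st.lists(st.floats(-100, 100, allow_nan=False), min_size=2,
                   max_size=12)


def welch_oracle(a, b):
    """Welch two-sided p computed from first principles (independent of
    the implementation under test)."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va ** 2 / (a.size - 1) + vb ** 2 / (b.size - 1))
    return 2 * sps.t.sf(abs(t), df), t, df


class TestTwoSampleT:
    def test_identical_samples_give_p_one(self):
        assert hs.two_sample_t([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0

    def test_against_first_principles(self):
        p_oracle, t, df = welch_oracle([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.6742346, abs=1e-6)
        assert df == pytest.approx(4.0)
        assert p_oracle == pytest.approx(0.0213116, abs=1e-6)
        assert hs.two_sample_t([1, 2, 3], [4, 5, 6]) == \
            pytest.approx(p_oracle, abs=1e-12)

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            hs.two_sample_t([1.0], [1.0, 2.0])

    def test_zero_variance_unequal_means_floored(self):
        assert hs.two_sample_t([1, 1, 1], [2, 2, 2]) == P_FLOOR

    @given(a=samples, b=samples)
    @settings(max_examples=50, deadline=None)
    def test_symmetric_in_arguments(self, a, b):
        assert hs.two_sample_t(a, b) == pytest.approx(hs.two_sample_t(b, a))

    def test_null_type_one_error_calibrated(self):
        """Monte-Carlo type-I error at alpha = 0.05 under N(0,1), n = 10."""
        rng = np.random.default_rng(3)
        x = rng.normal(size=(10000, 10))
        y = rng.normal(size=(10000, 10))
        rej = np.mean([hs.two_sample_t(x[i], y[i]) < 0.05
                       for i in range(10000)])
        assert 0.045 <= rej <= 0.055


class TestFisherCombine:
    def test_all_ones(self):
        res = hs.fisher_combine([1.0] * 8)
        assert res.fisher_statistic == 0.0
        assert res.df == 16
        assert res.combined_p == 1.0

    def test_closed_form_chi2_df4(self):
        # k = 2: survival of chi2_4 at X is exp(-X/2) (1 + X/2)
        res = hs.fisher_combine([0.05, 0.05])
        x = -2 * (np.log(0.05) + np.log(0.05))
        assert res.fisher_statistic == pytest.approx(x, abs=1e-12)
        assert res.combined_p == \
            pytest.approx(np.exp(-x / 2) * (1 + x / 2), abs=1e-12)

    def test_statistic_is_bruteforce_sum(self):
        p = [0.3, 0.07, 0.9, 0.5]
        res = hs.fisher_combine(p)
        assert res.fisher_statistic == -2 * sum(np.log(p))
        assert res.df == 8

    @pytest.mark.parametrize("bad", [[0.0, 0.5], [-0.1], [1.2]])
    def test_invalid_p_rejected(self, bad):
        with pytest.raises(ValidationError):
            hs.fisher_combine(bad)

    @given(p=st.lists(st.floats(1e-10, 1.0, exclude_min=False), min_size=2,
                      max_size=8), idx=st.integers(0, 7),
           factor=st.floats(0.05, 0.99))
    @settings(max_examples=50, deadline=None)
    def test_monotone_when_any_p_decreases(self, p, idx, factor):
        idx = idx % len(p)
        lowered = list(p)
        lowered[idx] = p[idx] * factor
        assert hs.fisher_combine(lowered).combined_p <= \
            hs.fisher_combine(p).combined_p + 1e-15

    def test_from_combined_p_round_trip(self):
        for p in (0.7, 0.05, 1e-4):
            rec = FeatureTestResult.from_combined_p(p, k=8)
            assert sps.chi2.sf(rec.fisher_statistic, 16) == \
                pytest.approx(p, rel=1e-9)


class TestMorphologyTest:
    def test_self_comparison_is_one(self, control_features):
        res = hs.morphology_rescue_test(control_features, control_features)
        assert res.combined_p == 1.0
        assert all(p == 1.0 for p in res.per_feature_p)

    def test_error_names_failing_feature(self, control_features):
        with pytest.raises(InsufficientDataError, match="pct_small"):
            hs.morphology_rescue_test(control_features[:1], control_features)

    def test_mutant_clearly_separated(self, control_pool, mutant_pool):
        """Untreated mutant vs control morphology: the combined p is
        essentially zero (12+ fields per group)."""
        segs, am, lm = control_pool
        ctrl = [hs.compute_features(s, am, lm) for s in segs[:20]]
        mut = [hs.compute_features(s, am, lm) for s in mutant_pool[:12]]
        res = hs.morphology_rescue_test(mut, ctrl)
        assert res.combined_p < 1e-6
        assert display_p(res.combined_p) in (0.0, res.combined_p)


class TestAggregationTest:
    def test_self_comparison(self):
        res = hs.aggregation_suppression_test([5, 9, 7, 6], [5, 9, 7, 6])
        assert res.log2_ratio == 0.0
        assert res.p_value == 1.0

    def test_halving_gives_minus_one(self):
        res = hs.aggregation_suppression_test([500, 500], [1000, 1000])
        assert res.log2_ratio == pytest.approx(-1.0)
        assert res.direction == -1

    def test_forced_arithmetic(self):
        res = hs.aggregation_suppression_test([300, 300, 300],
                                              [1200, 1200, 1201])
        assert res.log2_ratio == pytest.approx(-2.0, abs=1e-3)
        assert res.direction == -1

    def test_zero_reference_mean_rejected(self):
        with pytest.raises(UndefinedRatioError):
            hs.aggregation_suppression_test([1, 2], [0, 0])

    @given(a=st.lists(st.integers(1, 5000), min_size=2, max_size=10),
           b=st.lists(st.integers(1, 5000), min_size=2, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_log2_ratio_antisymmetric(self, a, b):
        fwd = hs.aggregation_suppression_test(a, b).log2_ratio
        rev = hs.aggregation_suppression_test(b, a).log2_ratio
        assert fwd == pytest.approx(-rev, abs=1e-9)


class TestScreenThreshold:
    def test_constant_ratios(self):
        t = hs.screen_threshold([0.5, 0.5, 0.5])
        assert t.sd_log2 == 0.0
        assert t.cutoff == t.mean_log2 == 0.5

    def test_simple_case(self):
        t = hs.screen_threshold([-1.0, 0.0, 1.0])
        assert (t.mean_log2, t.sd_log2, t.cutoff) == (0.0, 1.0, -2.0)

    def test_too_few_rejected(self):
        with pytest.raises(InsufficientDataError):
            hs.screen_threshold([0.1, np.inf, 0.2])

    def test_null_screen_tail_fraction(self):
        """352 null ratios ~ N(0, 0.5^2): the fraction below mean - 2 sd
        sits near the 2.3% normal tail."""
        rng = np.random.default_rng(2)
        ratios = rng.normal(0.0, 0.5, 352)
        t = hs.screen_threshold(ratios)
        frac = (ratios < t.cutoff).mean()
        assert 0.008 <= frac <= 0.045


def agg(log2, p, direction=-1):
    return hs.AggregateTestResult(log2_ratio=log2, p_value=p,
                                  direction=direction, n_treated=6,
                                  n_reference=24)


THRESHOLD = hs.ScreenThreshold(mean_log2=0.0, sd_log2=0.4, multiplier=2.0)


class TestCallHits:
    def test_stage_one_gate(self):
        calls = hs.call_hits({"t": agg(-2.0, 0.5)},
                             {"t": FeatureTestResult.from_combined_p(0.9)},
                             THRESHOLD)
        assert calls[0].classification is hs.Classification.INACTIVE

    def test_suppressed_but_not_rescued(self):
        calls = hs.call_hits({"t": agg(-3.0, 9.17e-66)},
                             {"t": FeatureTestResult.from_combined_p(0.0)},
                             THRESHOLD)
        call = calls[0]
        assert call.classification is hs.Classification.AGG_SUPPRESSOR_ONLY
        assert call.aggregation_suppressed and not call.morphology_rescued
        assert not call.partial_rescue

    def test_dual_hit(self):
        calls = hs.call_hits(
            {"t": agg(-1.637238, 3.65e-6)},
            {"t": FeatureTestResult.from_combined_p(0.151249)}, THRESHOLD)
        assert calls[0].classification is hs.Classification.DUAL_HIT
        assert calls[0].morphology_rescued

    def test_partial_rescue_flag(self):
        calls = hs.call_hits({"t": agg(-2.0, 1e-8)},
                             {"t": FeatureTestResult.from_combined_p(0.002)},
                             THRESHOLD)
        assert calls[0].classification is hs.Classification.AGG_SUPPRESSOR_ONLY
        assert calls[0].partial_rescue

    def test_positive_direction_never_suppresses(self):
        calls = hs.call_hits({"t": agg(-2.0, 1e-8, direction=+1)},
                             {"t": FeatureTestResult.from_combined_p(0.5)},
                             THRESHOLD)
        assert calls[0].classification is hs.Classification.INACTIVE

    def test_or_rule_admits_significant_only(self):
        # significant p but ratio above the cutoff: OR admits, AND does not
        a = {"t": agg(-0.5, 1e-4)}
        m = {"t": FeatureTestResult.from_combined_p(0.5)}
        and_call = hs.call_hits(a, m, THRESHOLD,
                                stage1_rule=Stage1Rule.AND)[0]
        or_call = hs.call_hits(a, m, THRESHOLD, stage1_rule=Stage1Rule.OR)[0]
        assert and_call.classification is hs.Classification.INACTIVE
        assert or_call.classification is hs.Classification.DUAL_HIT

    def test_missing_morphology_excluded(self):
        calls = hs.call_hits({"t": agg(-2.0, 1e-8)}, {}, THRESHOLD)
        assert calls[0].classification is hs.Classification.EXCLUDED
        assert "morphology" in calls[0].reason

    def test_explicit_exclusion_carried_through(self):
        calls = hs.call_hits({}, {}, THRESHOLD,
                             excluded={"t": "only 3 usable fields"})
        assert calls[0].classification is hs.Classification.EXCLUDED
        assert calls[0].reason == "only 3 usable fields"

    def test_exacerbating_requires_worse_than_baseline(self):
        baseline = MorphologyBaseline(fisher_statistic=80.0,
                                      mean_neurite_length=20.0)
        worse = FeatureTestResult.from_combined_p(1e-12)
        assert worse.fisher_statistic > 80.0
        calls = hs.call_hits(
            {"t": agg(-2.0, 1e-8)}, {"t": worse}, THRESHOLD,
            baseline=baseline, treated_mean_neurite_length={"t": 12.0})
        assert calls[0].classification is hs.Classification.EXACERBATING
        # same divergence but longer neurites than the mutant: not toxic
        calls = hs.call_hits(
            {"t": agg(-2.0, 1e-8)}, {"t": worse}, THRESHOLD,
            baseline=baseline, treated_mean_neurite_length={"t": 25.0})
        assert calls[0].classification is \
            hs.Classification.AGG_SUPPRESSOR_ONLY


def test_display_p_zero_convention():
    assert display_p(1e-20) == 0.0
    assert display_p(0.02) == 0.02
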