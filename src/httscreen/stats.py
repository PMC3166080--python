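"""Statistical engine for two-stage hit calling.

Stage 1 (aggregation suppression): per-field aggregate pixel counts of a
treatment are compared with the in-plate DMSO-treated mutant wells by a
two-sided Welch t-test, together with the log2 ratio of group means; a
screen-wide cutoff at ``mean - 2 sd`` of all log2 ratios flags strong
suppressors.

Stage 2 (morphology reversion): only treatments that suppress aggregation
are re-evaluated. Each of the eight morphology features of the treated
mutant fields is tested against the non-pathogenic control vehicle fields
(two-sided Welch), and the eight p-values are combined by Fisher's method:

    X = -2 * sum(ln p_i)   ~   chi2 with 2k degrees of freedom (k = 8)

A high combined p means the treated morphology is statistically
indistinguishable from the healthy control — a reversion.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import InsufficientDataError, UndefinedRatioError, ValidationError
from .morphometry import FEATURE_NAMES, FeatureVector

#: lower clip for p-values entering logs; keeps Fisher's statistic finite.
P_FLOOR = 1e-300

#: p-values below this display as 0 in reports (stored at full precision).
P_DISPLAY_ZERO = 1e-15


def two_sample_t(sample_a, sample_b) -> float:
    """Two-sided Welch (unequal-variance) t-test p-value.

    Identical samples give p = 1; two zero-variance samples with unequal
    means give the floor p (certain difference, no within-group spread).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"Welch t-test needs n >= 2 per group (got {a.size}, {b.size})")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return 1.0 if a.mean() == b.mean() else P_FLOOR
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return 1.0  # identical samples: t = 0 exactly
    with warnings.catch_warnings():
        # near-identical samples trip scipy's moment-precision warning;
        # the degenerate cases are handled explicitly above
        warnings.simplefilter("ignore", RuntimeWarning)
        p = float(sps.ttest_ind(a, b, equal_var=False).pvalue)
    if np.isnan(p):
        p = 1.0
    return min(max(p, P_FLOOR), 1.0)


@dataclass(frozen=True)
class FeatureTestResult:
    """Fisher combination of k per-feature p-values (df = 2k)."""

    per_feature_p: tuple[float, ...]
    fisher_statistic: float
    df: int
    combined_p: float

    @classmethod
    def from_combined_p(cls, combined_p: float,
                        k: int = len(FEATURE_NAMES)) -> "FeatureTestResult":
        """Reconstruct a result from a reported combined p alone (e.g. when
        re-analysing a published hit table without per-feature values)."""
        if not 0.0 <= combined_p <= 1.0:
            raise ValidationError("combined_p must lie in [0, 1]")
        x = float(sps.chi2.isf(max(combined_p, P_FLOOR), 2 * k))
        return cls(per_feature_p=(), fisher_statistic=x, df=2 * k,
                   combined_p=max(combined_p, P_FLOOR))


def fisher_combine(per_feature_p) -> FeatureTestResult:
    """Combine independent per-feature p-values by Fisher's method."""
    p = np.asarray(per_feature_p, dtype=float)
    if p.size < 1:
        raise ValidationError("need at least one p-value")
    if np.any(p > 1.0) or np.any(p <= 0.0):
        raise ValidationError("p-values must lie in (0, 1]")
    p = np.maximum(p, P_FLOOR)
    x = float(-2.0 * np.log(p).sum())
    combined = float(sps.chi2.sf(x, 2 * p.size))
    return FeatureTestResult(per_feature_p=tuple(p), fisher_statistic=x,
                             df=2 * p.size,
                             combined_p=min(max(combined, P_FLOOR), 1.0))


def morphology_rescue_test(treated: list[FeatureVector],
                           reference: list[FeatureVector]) -> FeatureTestResult:
    """Per-feature Welch tests of treated mutant fields against control
    vehicle fields, Fisher-combined. High combined p = similar to control."""
    t_mat = np.array([fv.as_array() for fv in treated])
    r_mat = np.array([fv.as_array() for fv in reference])
    pvals = []
    for j, name in enumerate(FEATURE_NAMES):
        try:
            pvals.append(two_sample_t(t_mat[:, j], r_mat[:, j]))
        except InsufficientDataError as exc:
            raise InsufficientDataError(f"feature {name!r}: {exc}") from exc
    return fisher_combine(pvals)


@dataclass(frozen=True)
class AggregateTestResult:
    """Plate-normalised aggregation comparison for one treatment."""

    log2_ratio: float
    p_value: float
    direction: int  # sign of (treated mean - DMSO mean)
    n_treated: int = 0
    n_reference: int = 0


def aggregation_suppression_test(treated_counts,
                                 dmso_counts) -> AggregateTestResult:
    """log2 ratio of mean aggregate pixels (treated / in-plate DMSO mutant)
    plus a two-sided Welch p-value."""
    t = np.asarray(treated_counts, dtype=float)
    d = np.asarray(dmso_counts, dtype=float)
    if t.size == 0 or d.size == 0:
        raise InsufficientDataError("both groups must be nonempty")
    if d.mean() <= 0:
        raise UndefinedRatioError(
            "DMSO mean aggregate count is 0 — aggregate threshold is "
            "miscalibrated for the mutant vehicle wells")
    if t.mean() <= 0:
        ratio = -np.inf
    else:
        ratio = float(np.log2(t.mean() / d.mean()))
    p = two_sample_t(t, d)
    diff = t.mean() - d.mean()
    return AggregateTestResult(log2_ratio=ratio, p_value=p,
                               direction=int(np.sign(diff)),
                               n_treated=t.size, n_reference=d.size)


@dataclass(frozen=True)
class ScreenThreshold:
    """Screen-wide log2-ratio cutoff at ``mean - m * sd``."""

    mean_log2: float
    sd_log2: float
    multiplier: float = 2.0

    @property
    def cutoff(self) -> float:
        return self.mean_log2 - self.multiplier * self.sd_log2


def screen_threshold(log2_ratios, m: float = 2.0) -> ScreenThreshold:
    """Sample mean and sd (n-1 denominator) of all finite log2 ratios in
    the screen; requires at least 3."""
    r = np.asarray(log2_ratios, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 3:
        raise InsufficientDataError(
            f"need >= 3 finite log2 ratios (got {r.size})")
    return ScreenThreshold(mean_log2=float(r.mean()),
                           sd_log2=float(r.std(ddof=1)), multiplier=m)


class Classification(str, enum.Enum):
    INACTIVE = "INACTIVE"
    AGG_SUPPRESSOR_ONLY = "AGG_SUPPRESSOR_ONLY"
    DUAL_HIT = "DUAL_HIT"
    EXACERBATING = "EXACERBATING"
    EXCLUDED = "EXCLUDED"


class Stage1Rule(str, enum.Enum):
    """How the p < alpha criterion and the 2-SD ratio rule combine."""

    AND = "AND"
    OR = "OR"


@dataclass(frozen=True)
class HitCall:
    treatment_id: str
    classification: Classification
    aggregation_suppressed: bool = False
    log2_ratio: float = float("nan")
    aggregation_p: float = float("nan")
    morphology_combined_p: float = float("nan")
    morphology_rescued: bool = False
    partial_rescue: bool = False
    reason: str = ""


@dataclass
class MorphologyBaseline:
    """Untreated-mutant reference used to recognise exacerbating
    treatments: the vehicle mutant's divergence from control and its mean
    neurite length."""

    fisher_statistic: float
    mean_neurite_length: float


def call_hits(
    agg_tests: dict[str, AggregateTestResult],
    morph_tests: dict[str, FeatureTestResult],
    threshold: ScreenThreshold,
    alpha: float = 0.05,
    rescue_floor: float = 1e-6,
    stage1_rule: Stage1Rule = Stage1Rule.AND,
    baseline: MorphologyBaseline | None = None,
    treated_mean_neurite_length: dict[str, float] | None = None,
    excluded: dict[str, str] = {},
) -> list[HitCall]:
    """Two-stage hit classification over all treatments.

    Stage 1: a treatment suppresses aggregation when its Welch p < alpha,
    its mean difference is negative, and its log2 ratio lies at or below
    the screen cutoff (AND rule; OR combines the two criteria
    disjunctively). Stage 2 is evaluated only for suppressed treatments:
    morphology is rescued when the Fisher-combined p exceeds alpha;
    combined p in (rescue_floor, alpha] is flagged as a partial reversion.
    A suppressed treatment whose morphology diverges from control even
    more than the untreated mutant baseline — larger Fisher statistic and
    a shorter mean neurite length — is classified EXACERBATING.
    """
    calls: list[HitCall] = []
    treatments = list(dict.fromkeys([*agg_tests, *morph_tests, *excluded]))
    for tid in treatments:
        if tid in excluded:
            calls.append(HitCall(tid, Classification.EXCLUDED,
                                 reason=excluded[tid]))
            continue
        agg = agg_tests.get(tid)
        if agg is None:
            calls.append(HitCall(tid, Classification.EXCLUDED,
                                 reason="missing aggregation test"))
            continue
        significant = agg.p_value < alpha and agg.direction < 0
        below_cutoff = agg.log2_ratio <= threshold.cutoff
        if stage1_rule is Stage1Rule.AND:
            suppressed = significant and below_cutoff
        else:
            suppressed = significant or (below_cutoff and agg.direction < 0)
        if not suppressed:
            calls.append(HitCall(tid, Classification.INACTIVE,
                                 log2_ratio=agg.log2_ratio,
                                 aggregation_p=agg.p_value))
            continue
        morph = morph_tests.get(tid)
        if morph is None:
            calls.append(HitCall(
                tid, Classification.EXCLUDED, aggregation_suppressed=True,
                log2_ratio=agg.log2_ratio, aggregation_p=agg.p_value,
                reason="missing morphology test"))
            continue
        rescued = morph.combined_p > alpha
        partial = rescue_floor < morph.combined_p <= alpha
        if rescued:
            cls = Classification.DUAL_HIT
        else:
            cls = Classification.AGG_SUPPRESSOR_ONLY
            if baseline is not None and treated_mean_neurite_length is not None:
                worse_p = morph.fisher_statistic > baseline.fisher_statistic
                mean_len = treated_mean_neurite_length.get(tid)
                worse_len = (mean_len is not None
                             and mean_len < baseline.mean_neurite_length)
                if worse_p and worse_len:
                    cls = Classification.EXACERBATING
        calls.append(HitCall(
            tid, cls, aggregation_suppressed=True,
            log2_ratio=agg.log2_ratio, aggregation_p=agg.p_value,
            morphology_combined_p=morph.combined_p,
            morphology_rescued=rescued, partial_rescue=partial))
    return calls


def display_p(p: float) -> float:
    """Report-facing p-value: values below 1e-15 display as 0."""
    return 0.0 if p < P_DISPLAY_ZERO else p
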