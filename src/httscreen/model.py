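"""Model/Results interface over a quantified screen.

:class:`ScreenModel` is built from the per-field feature table (one row
per usable image: well, site, eight morphology features, aggregate pixel
count) and the plate layout; ``fit()`` runs the whole statistical
procedure — per-treatment aggregation tests against the in-plate mutant
vehicle, the screen-wide 2-SD log2-ratio cutoff, per-feature morphology
tests against the non-pathogenic control, Fisher combination, and
two-stage hit classification — and returns a :class:`ScreenResults`
carrying the hit table, the threshold and a ``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InsufficientDataError, UndefinedRatioError
from .morphometry import FEATURE_NAMES, FeatureVector
from .plate_io import Genotype, PlateLayout
from .stats import (
    AggregateTestResult,
    Classification,
    FeatureTestResult,
    HitCall,
    MorphologyBaseline,
    ScreenThreshold,
    Stage1Rule,
    aggregation_suppression_test,
    call_hits,
    display_p,
    morphology_rescue_test,
    screen_threshold,
)

FIELD_COLUMNS = ["plate", "well", "site", *FEATURE_NAMES,
                 "aggregate_pixels", "zero_neurites"]


def _vectors(df: pd.DataFrame) -> list[FeatureVector]:
    return [FeatureVector(**{n: float(row[n]) for n in FEATURE_NAMES},
                          zero_neurites=bool(row.get("zero_neurites", False)))
            for _, row in df.iterrows()]


class ScreenModel:
    """Two-stage hit-calling model for one quantified screen.

    Parameters
    ----------
    fields : DataFrame
        One row per usable field with columns ``plate, well, site``, the
        eight feature columns, and ``aggregate_pixels``.
    layout : PlateLayout
        Genotype/treatment assignment of every well.
    alpha : float
        Significance level of both stages (default 0.05).
    threshold_multiplier : float
        The ``m`` of the screen-wide ``mean - m*sd`` log2-ratio cutoff.
    stage1_rule : Stage1Rule
        Whether the p-value criterion and the ratio cutoff combine by AND
        (default) or OR.
    rescue_floor : float
        Combined-p floor distinguishing partial from absent reversion.
    """

    def __init__(self, fields: pd.DataFrame, layout: PlateLayout,
                 alpha: float = 0.05, threshold_multiplier: float = 2.0,
                 stage1_rule: Stage1Rule = Stage1Rule.AND,
                 rescue_floor: float = 1e-6):
        missing = [c for c in ("well", "site", "aggregate_pixels")
                   if c not in fields.columns]
        missing += [c for c in FEATURE_NAMES if c not in fields.columns]
        if missing:
            raise ConfigurationError(f"field table lacks columns {missing}")
        if not 0 < alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if threshold_multiplier <= 0:
            raise ConfigurationError("threshold multiplier must be > 0")
        unknown = set(fields["well"]) - set(layout.wells)
        if unknown:
            raise ConfigurationError(
                f"field table wells absent from layout: {sorted(unknown)[:5]}")
        self.fields = fields.reset_index(drop=True)
        self.layout = layout
        self.alpha = alpha
        self.threshold_multiplier = threshold_multiplier
        self.stage1_rule = stage1_rule
        self.rescue_floor = rescue_floor

    @classmethod
    def from_field_table(cls, path, layout: PlateLayout,
                         **kwargs) -> "ScreenModel":
        return cls(pd.read_csv(path, sep="\t"), layout, **kwargs)

    # -- group extraction ---------------------------------------------------

    def _rows_for_wells(self, wells: list[str]) -> pd.DataFrame:
        return self.fields[self.fields["well"].isin(wells)]

    def _treatment_wells(self) -> dict[str, list[str]]:
        groups: dict[str, list[str]] = {}
        for wid, cond in self.layout.wells.items():
            if not cond.is_vehicle and cond.genotype is Genotype.HTT138Q:
                groups.setdefault(cond.treatment_id, []).append(wid)
        return groups

    # -- fitting ------------------------------------------------------------

    def fit(self) -> "ScreenResults":
        layout = self.layout
        dmso_wells = layout.vehicle_wells(Genotype.HTT138Q)
        ctrl_wells = layout.vehicle_wells(Genotype.HTT15Q)
        if len(dmso_wells) < 2 or len(ctrl_wells) < 2:
            raise ConfigurationError(
                "need >= 2 vehicle wells per genotype for reference "
                "distributions")
        dmso_counts = self._rows_for_wells(dmso_wells)["aggregate_pixels"] \
            .to_numpy(dtype=float)
        ctrl_rows = self._rows_for_wells(ctrl_wells)
        ctrl_vectors = _vectors(ctrl_rows)

        agg_tests: dict[str, AggregateTestResult] = {}
        morph_tests: dict[str, FeatureTestResult] = {}
        mean_neurite: dict[str, float] = {}
        excluded: dict[str, str] = {}
        for tid, wells in self._treatment_wells().items():
            rows = self._rows_for_wells(wells)
            if len(rows) < 2:
                excluded[tid] = f"only {len(rows)} usable fields"
                continue
            try:
                agg_tests[tid] = aggregation_suppression_test(
                    rows["aggregate_pixels"].to_numpy(dtype=float),
                    dmso_counts)
            except (InsufficientDataError, UndefinedRatioError) as exc:
                excluded[tid] = f"aggregation test failed: {exc}"
                continue
            try:
                morph_tests[tid] = morphology_rescue_test(
                    _vectors(rows), ctrl_vectors)
            except InsufficientDataError as exc:
                excluded[tid] = f"morphology test failed: {exc}"
                agg_tests.pop(tid, None)
                continue
            mean_neurite[tid] = float(rows["mean_neurite_length"].mean())

        # the vehicle mutant's own divergence from control anchors the
        # EXACERBATING comparison
        baseline = None
        if len(dmso_wells) >= 2:
            dmso_rows = self._rows_for_wells(dmso_wells)
            try:
                base_test = morphology_rescue_test(_vectors(dmso_rows),
                                                   ctrl_vectors)
                baseline = MorphologyBaseline(
                    fisher_statistic=base_test.fisher_statistic,
                    mean_neurite_length=float(
                        dmso_rows["mean_neurite_length"].mean()))
            except InsufficientDataError:
                baseline = None

        ratios = [t.log2_ratio for t in agg_tests.values()]
        threshold = screen_threshold(ratios, m=self.threshold_multiplier)
        calls = call_hits(agg_tests, morph_tests, threshold,
                          alpha=self.alpha, rescue_floor=self.rescue_floor,
                          stage1_rule=self.stage1_rule, baseline=baseline,
                          treated_mean_neurite_length=mean_neurite,
                          excluded=excluded)
        return ScreenResults(model=self, threshold=threshold, calls=calls,
                             agg_tests=agg_tests, morph_tests=morph_tests,
                             baseline=baseline)


@dataclass
class ScreenResults:
    """Fitted screen statistics: threshold, per-treatment tests, hit calls."""

    model: ScreenModel
    threshold: ScreenThreshold
    calls: list[HitCall]
    agg_tests: dict[str, AggregateTestResult] = field(default_factory=dict)
    morph_tests: dict[str, FeatureTestResult] = field(default_factory=dict)
    baseline: MorphologyBaseline | None = None

    @property
    def hit_table(self) -> pd.DataFrame:
        rows = []
        for c in self.calls:
            agg = self.agg_tests.get(c.treatment_id)
            morph = self.morph_tests.get(c.treatment_id)
            row = {
                "treatment_id": c.treatment_id,
                "n_fields": agg.n_treated if agg else 0,
                "log2_ratio": c.log2_ratio,
                "agg_p": display_p(c.aggregation_p)
                if np.isfinite(c.aggregation_p) else np.nan,
                "morph_combined_p": display_p(c.morphology_combined_p)
                if np.isfinite(c.morphology_combined_p) else np.nan,
                "classification": c.classification.value,
                "partial_rescue": c.partial_rescue,
                "reason": c.reason,
            }
            for j, name in enumerate(FEATURE_NAMES):
                key = f"p_{name}"
                row[key] = (display_p(morph.per_feature_p[j])
                            if morph and morph.per_feature_p else np.nan)
            rows.append(row)
        df = pd.DataFrame(rows)
        # optional extra, not part of the original analysis: BH-adjusted
        # aggregation p-values across treatments
        mask = df["agg_p"].notna()
        df["agg_p_bh_extra"] = np.nan
        if mask.sum() > 1:
            df.loc[mask, "agg_p_bh_extra"] = _benjamini_hochberg(
                df.loc[mask, "agg_p"].to_numpy(dtype=float))
        return df

    @property
    def class_counts(self) -> dict[str, int]:
        counts = {c.value: 0 for c in Classification}
        for call in self.calls:
            counts[call.classification.value] += 1
        return counts

    def scatter_data(self) -> pd.DataFrame:
        """Per-treatment log2 ratios plus the cutoff, for the screen-wide
        aggregation scatter plot."""
        return pd.DataFrame(
            [{"treatment_id": t, "log2_ratio": r.log2_ratio,
              "cutoff": self.threshold.cutoff}
             for t, r in self.agg_tests.items()])

    def plot_aggregation(self, ax=None):
        """Scatter of per-treatment log2 aggregate ratios with the
        mean - m*sd cutoff line."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        data = self.scatter_data()
        ax.scatter(range(len(data)), data["log2_ratio"], s=12, c="#444444")
        ax.axhline(self.threshold.cutoff, color="red",
                   label=f"cutoff = {self.threshold.cutoff:.3f}")
        ax.set_xlabel("treatment index")
        ax.set_ylabel("log2 aggregate ratio (treated / DMSO)")
        ax.legend(frameon=False)
        return ax

    def summary(self) -> str:
        """Human-readable run summary with ranked hits and class counts."""
        lines = [
            "Screen hit-calling summary",
            "==========================",
            f"treatments tested: {len(self.agg_tests)}   "
            f"excluded: {self.class_counts['EXCLUDED']}",
            f"log2-ratio mean {self.threshold.mean_log2:+.4f}, "
            f"sd {self.threshold.sd_log2:.4f}, "
            f"cutoff (mean - {self.threshold.multiplier:g} sd) = "
            f"{self.threshold.cutoff:+.4f}",
            "",
            "class counts: " + ", ".join(
                f"{k}={v}" for k, v in self.class_counts.items() if v),
            "",
            f"{'treatment':<22}{'log2':>9}{'agg_p':>12}"
            f"{'morph_p':>12}  class",
        ]
        ranked = sorted(
            (c for c in self.calls
             if c.classification is not Classification.EXCLUDED),
            key=lambda c: (c.log2_ratio if np.isfinite(c.log2_ratio)
                           else -np.inf))
        for c in ranked[:25]:
            morph = ("." if not np.isfinite(c.morphology_combined_p)
                     else f"{display_p(c.morphology_combined_p):.6g}")
            lines.append(
                f"{c.treatment_id:<22}{c.log2_ratio:>9.3f}"
                f"{display_p(c.aggregation_p):>12.3g}{morph:>12}"
                f"  {c.classification.value}"
                + (" (partial)" if c.partial_rescue else ""))
        return "\n".join(lines)


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = p.size
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj
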