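# httscreen

High-content screening analysis for *Drosophila* primary-neuron
Huntington's disease cultures: fluorescent-aggregate quantification,
eight-metric neurite morphometry, and two-stage statistical hit calling,
together with a fully ground-truthed synthetic-culture generator.

## The problem

In the underlying assay, primary neurons expressing a pathogenic
polyglutamine-expanded Huntingtin fragment (Htt138Q, RFP-tagged) form
bright cytoplasmic aggregates and grow dysmorphic neurites — smaller
cell-body clusters (*neuromeres*), shorter and more branched processes —
compared with the non-pathogenic Htt15Q control. Cultures are plated in
multiwell format, treated with compounds or dsRNAs, and imaged in two
channels (membrane GFP for morphology, Htt-RFP for the reporter) at
three sites per well, in duplicate. A candidate therapeutic must do two
things: suppress aggregation, **and** revert the morphology profile
toward the healthy control. This package implements that entire readout
for people building or re-analysing such screens; because the original
images are not deposited, a synthetic generator with known ground truth
stands in for them.

## The analysis in brief

Per field image:

- **aggregation** = #{reporter pixels with intensity > τ}, with τ the
  0.999-quantile of pooled Htt15Q-vehicle reporter pixels;
- **morphology**: neuromeres and neurites are segmented
  (median-background subtraction, Otsu, opening, skeleton split at
  junctions); log2 neuromere areas are binned small/medium/large by a
  3-component Gaussian mixture (EM), neurite segment lengths grouped
  short/medium/long by k-means; bin/group percentages plus the two means
  give exactly **eight features** per field.

Per treatment (pooled duplicate wells, ≥ 6 usable images):

- **stage 1**: log2 ratio of mean aggregate pixels vs in-plate DMSO
  mutant wells, Welch two-sided p; suppression requires p < α, a
  negative direction, and log2 ratio ≤ mean − 2·SD of the screen;
- **stage 2** (suppressors only): per-feature Welch tests against the
  Htt15Q vehicle reference, combined by Fisher's method,
  X = −2 Σᵢ ln pᵢ ~ χ²₂ₖ (k = 8); combined p > α means the morphology is
  statistically indistinguishable from control → **DUAL_HIT**; combined
  p ∈ (10⁻⁶, α] is a flagged partial reversion.

See `docs/methods.md` for assumptions, parameter defaults and known
limitations (notably the behaviour of Fisher's combination on these
dependent features).

## Worked example

Simulate a 26-well screen (8 inactive compounds plus one strong
aggregation suppressor that does *not* fix morphology, duplicate wells,
3 sites/well) and call hits:

```python
from httscreen import Classification
from httscreen.pipeline import ScreenConfig, analyze_screen_data
from httscreen.synthetic import (EffectLabel, EffectSpec,
                                 build_screen_layout, generate_screen)

tids = [f"null{i:02d}" for i in range(1, 9)] + ["supp01"]
effects = {"supp01": EffectSpec(EffectLabel.AGG_SUPPRESSOR,
                                suppression_factor=0.05)}
layout = build_screen_layout(tids, wells_per_treatment=2,
                             vehicle_wells_per_genotype=4)
data = generate_screen(layout, effects, seed=42)
features, results, manifest = analyze_screen_data(data, ScreenConfig())
print(results.summary())
```

prints

```
Screen hit-calling summary
==========================
treatments tested: 9   excluded: 0
log2-ratio mean -0.4294, sd 1.4698, cutoff (mean - 2 sd) = -3.3689

class counts: INACTIVE=8, AGG_SUPPRESSOR_ONLY=1

treatment                  log2       agg_p     morph_p  class
supp01                   -4.324    7.62e-08  0.00841973  AGG_SUPPRESSOR_ONLY (partial)
null04                   -0.163       0.234           .  INACTIVE
null01                   -0.039       0.814           .  INACTIVE
...
```

Reading it: the planted suppressor cuts aggregation ~20-fold
(log2 ratio −4.3, far below the −3.37 screen cutoff, Welch p ≈ 8·10⁻⁸)
but its morphology still differs from the healthy control (Fisher
combined p ≈ 0.008 < 0.05), so it is an aggregation suppressor with only
a partial morphology reversion — not a dual hit. The eight inactive
compounds scatter around log2 ratio 0. `results.hit_table` holds the
full per-treatment table (per-feature p-values included) and
`results.plot_aggregation()` draws the screen-wide scatter with the
2-SD cutoff line.

The same pipeline runs from the shell on TIFFs + a plate-layout CSV:

```sh
hcs simulate --config sim.yaml --out screen/ --seed 7
hcs run --config run.yaml --out results/        # or: segment / features / stats
hcs report --out results/
```

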