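# Methods

`httscreen` re-creates, as tested reusable code, the image-analysis and
statistics pipeline of a high-content screen on *Drosophila* primary
neuronal cultures expressing human Huntingtin fragments: a non-pathogenic
Htt15Q control and a pathogenic, aggregate-forming Htt138Q mutant, each
co-expressing membrane GFP (morphology channel) alongside the Htt-RFP
reporter. Because no raw screen images are publicly deposited, the package
ships a synthetic-culture generator with full ground truth; every claim
the test suite makes is a claim about this generator's output, not about
real micrographs.

## Image quantification

**Aggregation.** Htt aggregates are far brighter than soluble Htt-RFP, so
per-field aggregation is the count of reporter pixels strictly above an
empirically calibrated intensity threshold. The original screen set this
threshold empirically without documenting a rule; here it is the
q-quantile (default q = 0.999) of pooled pixel intensities from the
Htt15Q vehicle wells of the screen. By construction this leaves ~0.1% of
reference pixels above threshold (≈65 px on a 256×256 field), which is
the baseline "near-zero" count; mutant vehicle fields sit far above it.
Pixels saturated at the bit-depth maximum always count as aggregate.

**Morphology.** The morphology channel is background-subtracted with a
wide median filter (window 101 px, computed on a 4×-decimated grid and
bilinearly interpolated back — accurate because the synthetic background
varies on scales much larger than the window, and an order of magnitude
faster than the full-resolution filter). The window must exceed the
largest soma diameter (~40 px here); smaller windows hollow out soma
interiors. Binarisation is Otsu by default (a fixed threshold is
available), which makes segmentation invariant to uniform intensity
scaling. A morphological opening (disc radius 4 px) separates thick
somata from thin (~2 px) neurites; opened components of ≥ 50 px are
neuromeres. Because opening erodes boundaries, each neuromere's *area* is
measured from the original-mask pixels within the opening radius of its
component (sub-1% error on synthetic blobs), while the neuromere *mask*
(used for the reporter-distribution ratio and neurite exclusion) remains
the opened component. The neurite mask is the binary mask minus the
1 px-dilated neuromeres; it is skeletonised and split at junction pixels
(≥ 3 skeleton neighbours). Segment length sums adjacency steps
(orthogonal 1, diagonal √2, × pixel size); edges incident to a junction
pixel are credited to the adjoining segment so splitting does not shorten
paths. Segments under 5 px are discarded.

Pixel coordinates are 0-based, row-major; areas are reported in µm²
(pixel count × pixel\_size²) and lengths in µm, with the screen's
acquisition calibration (897/1392 ≈ 0.644 µm/px) as the default.

**Quality control.** Fields lacking any segmented neuromere are excluded
("no cell profiles"), as are out-of-focus fields. Focus is scored by the
variance of the discrete Laplacian of the min–max-normalised image — a
standard, parameter-light proxy, since the original exclusion was manual
— with the cutoff defaulting to 0.25 × the median focus score of the
plate's vehicle wells. A treatment (its duplicate wells pooled; 2 wells ×
3 sites = 6 images in the screen design) enters the analysis only with at
least `min_images = 6` usable images.

## The eight-feature morphology profile

Neuromere areas are log2-transformed and pooled across the screen's
vehicle wells (both genotypes); a three-component univariate Gaussian
mixture is fitted by EM and frozen, defining small/medium/large bins by
maximum posterior (ties to the smaller bin). EM is deterministic: means
initialised at the 1/6, 3/6, 5/6 sample quantiles, equal weights, common
sample SD, stopping when the log-likelihood improves by < 1e-8 or at 500
iterations; variances are floored at 1e-12 and the log-likelihood trace
is exposed (and tested) as nondecreasing. Neurite segment lengths are
grouped short/medium/long by k-means (k = 3, Lloyd's algorithm behind
scikit-learn, deterministically initialised at the 10th/50th/90th
percentiles, tol 1e-6); assignment is nearest-centre with midpoint ties
to the shorter group. Fitting once per screen keeps bin boundaries
comparable across treatments; a per-plate scope is available in the run
configuration.

Each field then yields exactly eight metrics: the three neuromere-bin
percentages, mean neuromere area, the three neurite-group percentages and
mean neurite length. Percentages are of that field's own object totals,
which cancels well-to-well variation in plated cell number (duplicating
every object leaves the vector unchanged — a tested invariant). Fields
with neuromeres but no measurable neurite contribute zero-valued neurite
features and are flagged `zero_neurites` rather than dropped; dropping
them would bias treated groups toward their healthiest fields.

## Statistics and hit calling

All tests take the field image as the sampling unit. Group comparisons
use the two-sided Welch (unequal-variance) t-test; identical samples give
p = 1 exactly, and p-values are floored at 1e-300 for log-safety
(reported values below 1e-15 display as 0, mirroring the screen tables'
"0" entries, but are stored at full precision).

**Stage 1 — aggregation suppression.** Each treatment's per-field
aggregate counts are compared with the in-plate DMSO-treated mutant
wells: the log2 ratio of group means and a Welch p. The screen-wide
cutoff is mean − 2 SD (sample SD, n−1) of all treatments' log2 ratios. A
treatment suppresses aggregation when p < α (0.05), the mean difference
is negative, and the ratio lies at or below the cutoff (the AND of the
two published rules; OR is available). Two-sided testing plus an explicit
direction check reproduces the vehicle self-comparison identity
(aggregation p = 1), which a one-sided test would report as 0.5.

**Stage 2 — morphology reversion.** Only suppressing treatments are
re-evaluated: each of the eight features of the treated mutant fields is
tested against the Htt15Q vehicle reference, and the eight p-values are
combined by Fisher's method, X = −2 Σ ln pᵢ referred to χ² with 2k = 16
degrees of freedom. Combined p > α is a full reversion (DUAL_HIT);
combined p in (1e-6, α] is flagged as partial reversion — the validated
hits of the original screen include both regimes — and a suppressed
treatment whose profile diverges from control *more* than the untreated
mutant baseline (larger Fisher statistic and shorter mean neurites) is
classed EXACERBATING. No multiple-testing correction is applied across
treatments, matching the original analysis; a Benjamini–Hochberg column
is emitted as clearly-labelled extra output.

**Known limitation — Fisher under dependence.** The eight features are
strongly correlated (each percentage triple sums to 100; means correlate
with bins; |r| up to ~0.95), and Fisher's χ²₂ₖ reference assumes
independence. Under the null (treated ≡ reference) the combined p is
therefore mildly anti-conservative: by permutation at the screen's group
sizes (6 treated vs 24 reference fields), P(combined p > 0.05) ≈ 0.89
rather than 0.95. Consequently roughly one fully rescued treatment in
ten is expected to land below the full-reversion line and be reported as
a partial rescue. This is a property of the published procedure itself;
the package reports it rather than silently correcting for it.

## The synthetic-culture generator

Each two-channel field (default 256×256 px for desk-scale runs; the
acquisition geometry 1392×1040 is one parameter away) contains:

- **Neuromeres** — quasi-circular (mildly elliptical, rotated) blobs,
  count ~ Poisson(rate 5/field), placed without overlap (bounded retries,
  skips logged). Log2 areas (µm²) are drawn from the three-component
  mixture the binning stage assumes — control means (6.0, 7.5, 9.0), SDs
  0.35, weights (0.5, 0.3, 0.2); the mutant shifts means down 0.8.
  Ground truth records both the drawn value and the rendered pixel area.
- **Neurites** — 8-connected persistent random walks (angular jitter SD
  0.08/step) from stratified points on blob boundaries, widened to ~2 px
  with a 2×2 dilation (which keeps diagonal runs skeletonisable at full
  length). Total path length per neurite ~ gamma(shape 3, scale 12 µm
  control / 7 µm mutant); walks fork with per-step probability 0.03
  (control) / 0.08 (mutant) and terminate at the field border, a soma, or
  an already-drawn neurite pixel, so the recorded per-segment arc lengths
  (diagonal steps √2) match the rendered geometry exactly.
- **Reporter** — diffuse soluble signal over the neuronal mask (3000
  counts control, 800 mutant above a 200-count background) plus, in the
  mutant, Poisson(25)/field aggregate discs (radius 2 px) at intensities
  12000–18000, ≥ 4× the soluble band so a quantile threshold can separate
  them. Both channels receive Gaussian PSF blur (σ 1 px) and read noise
  (SD 50), then quantise to uint16.

A `rescue` parameter interpolates every mutant parameter linearly toward
the control set; planted screen effects are NULL, AGG_SUPPRESSOR (scales
only the aggregate rate), DUAL_RESCUER (applies rescue to everything) and
TOXIC (shrinks areas and lengths below mutant levels). Each well/site
draws an independent RNG substream from a stable hash of (seed, plate,
well, site), so outputs are bit-reproducible and order-independent. The
phenotype effect sizes are free parameters of the simulator, not claims
about the biology — the source screen reports no quantitative effect
sizes — and the generator omits glia, uneven illumination, vignetting and
focus drift; passing tests therefore demonstrate correctness of the
*analysis* under the stated model, not performance on real micrographs.

Numbers quoted above (calibration leftovers, permutation calibration of
the combined test, recovery rates) are computed by the test suite and
`scripts/acceptance.py` at the problem sizes stated there: 20-seed
noiseless recovery runs, 96-well null screens over 20 seeds, and one
288-well planted screen — sizes chosen to keep a full desk run in
minutes while leaving every rate estimate's Monte-Carlo error well inside
the asserted bands.
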