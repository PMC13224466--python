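# Methods

## Tracer kinetics

The tracer model is deliberately minimal: after intrathecal injection the
ROI-mean signal intensity is treated as piecewise linear — a rise at slope
`v_in` from the baseline to a peak at `T1`, then a decline at slope `v_out`
until the end of the observation window (default 5 h). Under this model the
influx rate `V1 = (peak − initial)/T1` and the clearance rate
`V2 = (peak − final)/(window − T1)` are not approximations but the exact
slopes, which is what makes noiseless round-trip recovery a meaningful
test. No compartmental pharmacokinetics is attempted: the observable is a
single ROI mean at nine scan times (0, 5 min, 15 min, 30 min, 1 h, 1.5 h,
2 h, 2.5 h, 5 h), far too sparse to constrain a mechanistic model.

The peak is located by discrete argmax over the sampled curve, with ties
broken to the earliest timepoint (favouring the influx phase). `T2` is
always derived as `window − T1`, never read from input. The SIPH
rate-of-change statistic `(peak − final)/(c − T1)` keeps its conventional
constant `c = 6`; the constant is configurable, and setting it to the
window length makes SIPH coincide with `V2` (checked as an identity test).
The final-scan SI is used for the statistic's endpoint term, since
scanning stops at the window end.

When replicate ROI measurements are supplied per timepoint, they are
averaged before the curve is assembled, matching the usual
three-measurements-per-scan protocol.

### Synthetic curves

`KineticSimParams` defaults place the baseline near 6,700 SI units, the
peak at 1.5 h, and the window at 5 h — the regime the real curves occupy
(baselines ≈ 6,000–7,000, peaks at 1.5–2.2 h). Noise is independent
Gaussian per timepoint; this exercises estimator robustness but does not
emulate scanner drift, motion artefacts, or heteroscedastic Rician noise,
so passing recovery tests shows correctness of the estimator, not
robustness to every MRI artefact. The cohort presets for the three study
groups reuse the published group means and ± spreads for the rates and
baselines; per-animal time-to-peak is drawn from scan-grid values so the
discrete peak is identifiable. Between-animal rate draws are truncated at
10% of the group mean to keep every curve physiological (rising then
falling).

A discretization caveat: when the true peak time falls between scan
times, the estimated `T1` snaps to the nearest sampled maximum and both
rates inherit a small bias. This is a property of the sampling design, not
of the estimator, and is why the recovery tests place peaks on the grid.

## AQP4 polarization

The pipeline substitutes a reproducible, automated construction for what
is manually delineated in practice:

1. **Background subtraction** — the 1st-percentile intensity is subtracted
   as a constant and negatives are clamped to 0. A constant-percentile
   rule was chosen over rolling-ball because it is deterministic,
   idempotent once the floor is at zero, and trivially testable. It is
   applied before any intensity comparison.
2. **Vessel segmentation** — Otsu threshold on the CD31 channel (or a
   fixed threshold), keeping connected components of at least
   `min_vessel_area_px` (default 20 px). A constant plane with automatic
   thresholding is an error, not an empty mask.
3. **Perivascular ROIs** — the vessel mask dilated by a disk of
   `ring_width_px` (default 3 px) minus the vessels themselves.
   Overlapping rings merge by union so no pixel is counted twice. Users
   can instead supply their own vessel/ring masks to mirror a manual
   protocol exactly.
4. **Index** — the percentage of analysed pixels *strictly* below the mean
   ring intensity `M_pv`. Strictness follows the definition's wording
   ("lower than"); boundary pixels equal to `M_pv` do not count, which is
   what makes a perfectly uniform image score 0 rather than being
   ill-defined.

Two genuinely open design points are resolved as options rather than
guesses: a batch-wide global threshold on the AQP4 channel (off by
default; `otsu` pools the background-corrected histograms of the whole
batch and reuses one value verbatim per image) restricts the analysis
mask when enabled, and vessel lumens can optionally be excluded from the
denominator (`exclude_vessel_lumen`, default off, i.e. "total image area"
means all pixels). All math is floating point regardless of input bit
depth; no rescaling to [0, 1] is done because the index is scale-free —
affine invariance under `I → aI + b` (a > 0) is a tested property.

An image with no detectable vessel yields a result flagged `valid=False`
with a NaN index, never a silent 0.

### Synthetic images

Vessels are circular disks (2-D cross-sections) placed by rejection
sampling with a 1,000-attempt cap so non-overlap failures surface as
errors naming the constraint. The noiseless AQP4 plane is a uniform
parenchymal level multiplied by an enrichment factor inside the
perivascular ring; the ground-truth index is counted brute-force on that
noiseless plane. Gaussian pixel noise is added only to the emitted
channels and clamped at 0 (detector floor). The simulator does not emulate
autofluorescence gradients, astrocyte morphology, out-of-focus light, or
non-circular vessels, so ground-truth recovery demonstrates the
pipeline's correctness, not segmentation performance on real tissue. A
consequence of the uniform parenchyma is that the noiseless index
saturates at `100 × (1 − ring fraction)` for any enrichment above 1; the
enrichment–index relationship is therefore tested as non-decreasing, with
zero exactly at enrichment 1.

## Histology scoring

The rubric is encoded as a validated data model: seven ordinal features
with fixed ranges (inflammation depth 0–4, infiltration 0–3, crypt damage
0–4, crypt abscess 0–2, submucosal edema 0–3, goblet-cell loss 0–3, crypt
hyperplasia 0–3). "Combining" the infiltration and epithelial-injury
components is read as plain addition of all seven subscores (composite
range 0–22, consistent with reported group means spanning roughly 2–14);
both subtotals are emitted alongside the composite so either component can
be reported separately, and no weighted variant is implemented. Grades
come from a human rater — automated lesion detection is out of scope.

Synthetic cohorts draw each subscore from `Binomial(max_f, mean/max_f)`:
bounded, integer-valued, with mean exactly the requested value, and
degenerate (constant) at either end of the range — so a cohort specified
at the rubric maximum scores exactly 22 everywhere. The binomial's
variance is tied to its mean, which is adequate for generating test
cohorts but does not model inter-rater variability.

## Reporting

Summaries are mean ± sample SD (n − 1); a single-animal group reports SD
as missing, never zero, and rates are summarised as mean-of-rates (each
animal's rates computed first, then averaged). Omnibus comparisons
delegate to scipy (one-way ANOVA, Kruskal–Wallis) and statsmodels
(Tukey HSD). Dunn's post hoc test is computed in-package from pooled
ranks with tie correction and Bonferroni adjustment, as no installed
dependency provides it; for two groups its z statistic squares to the
Kruskal–Wallis H, which is used as a cross-check in the tests.
Repeated-measures ANOVA is not implemented: the package consumes derived
per-animal metrics, not per-timepoint raw data.

## Problem sizes and determinism

Every generator is a pure function of its parameters including the seed
(NumPy `default_rng`). The test suite uses 160×160 px images with 3–6
vessels, 200-animal recovery simulations, and 200–1,000-replicate null or
power simulations for the statistics layer; these sizes give stable
pass/fail behaviour at sub-percent Monte-Carlo error while keeping the
suite quick. Acceptance-level checks assert exact arithmetic on published
group-mean anchors and 1e-6/1e-9-tolerance recovery on noiseless inputs.
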