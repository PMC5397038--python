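# Methods

## Contact model and units

Force curves are analysed with the Hertz/Sneddon relation for a pyramidal
indenter,

    F(h) = C(α, ν) · E · h²,      C(α, ν) = 4 tan α / (π^{3/2} (1 − ν²)),

where `α` is the effective half-angle of the pyramid, `ν` the sample
Poisson ratio and `E` the Young's modulus. The typeset form of this
prefactor varies across the contact-mechanics literature; the reading
adopted here gives a tip-geometry factor 4/π^{3/2} ≈ 0.719 multiplying
tan α, consistent with published pyramidal-indenter constants. Alternative conventions
(Bilodeau's 0.7453·tan α, the conical 2/π·tan α) are selectable through
`Probe.geometry_constant_override`, which replaces only the tip-geometry
factor — the 1/(1−ν²) material factor always applies.

Units are fixed internally: lengths in nm, forces in nN, moduli in kPa
(1 kPa·nm² = 10⁻⁶ nN). Spring constants are in N/m, so Hooke's law F = k·d
needs no numeric conversion (N/m × nm = nN). Converters live only at I/O
boundaries.

The half-angle has no universal default: it is a property of the mounted
tip and must be supplied. 35° is a typical manufacturer value for
soft-sample pyramidal probes and is used by the presets together with a
thermally calibrated spring constant of 0.034 N/m and ν = 0.5
(incompressible cytoplasm).

## Per-curve pipeline

1. **Baseline.** A straight line is fitted to the earliest 30% of approach
   samples (noise SD from its residuals). The line removes offset and tilt.
2. **Contact point.** Contact is the first sustained (3-sample) excursion
   of deflection above 3 baseline-SDs, refined by fitting a straight line
   to √(deflection−baseline) just past the crossing and taking its zero
   crossing: for a parabolic rise, √F is linear in z, so this linearization
   is far better conditioned under noise than locating the parabola's
   (double) root, which degenerates into a complex pair at any noise level.
3. **Window.** Only samples with 0 ≤ h ≤ 300 nm are fitted — the parabolic
   contact regime. Beyond that depth, thin cell regions press onto the
   stiff support and the response turns linear (substrate effect); including
   it inflates the modulus (verified as a property test). Depths are
   referenced to the first retained sample; this ≤ one-sample shift leaves
   the fitted curvature, hence E, unchanged.
4. **Fit.** An unconstrained second-order polynomial F = a₂h² + a₁h + a₀.
   Not forcing the fit through the origin lets the linear/constant terms
   absorb residual baseline offset and contact-point error without biasing
   a₂, which alone carries E. r² is the squared Pearson correlation between
   observed and fitted force (an R²-of-regression variant would be
   monotonically related for these fits).
5. **QC.** Curves are rejected for: no detected contact; fewer than 8
   samples in the window ("insufficient indentation"); non-positive or
   vanishing curvature (a₂ ≤ 0, or an implied E below `min_modulus`,
   default 10⁻³ kPa — an exactly linear force otherwise "passes" with
   curvature at rounding-error level); or r² < 0.99. Rejection reasons
   partition the rejected set and are reported.

Retraction segments, adhesion, viscoelasticity, drift and tilt correction
are out of scope; `k` is an input (no thermal-tune implementation).

## Group aggregation and tests

Accepted moduli are summarized per group by: density-normalized histogram
(Freedman–Diaconis by default; any numpy bin rule or a fixed count can be
configured for reproducibility), least-squares fit of a two-parameter
Gaussian density to bin centres/heights initialized at the sample
mean/SD, removal of values outside mean ± 2 fitted SDs, and a single
rebuild-and-refit. Both pre- and post-trim parameters are reported; the
post-trim fitted mean/SD are the group summary (the ± reported with group
moduli is the fitted SD, not a standard error). If the optimizer fails, the
sample mean/SD are used with a logged warning; all-identical values skip
trimming entirely. Monte Carlo measurement puts the histogram-fit
estimator's sampling SD at ≈1.3× the naive σ/√n for n = 2000 Gaussian
values; tests use that factor. For Gaussian data the ±2σ trim removes
≈ 4.6% of values.

Two groups are compared with a pooled-variance Student's t-test on the
trimmed per-curve values (Welch by flag); three or more groups with one-way
fixed-effects ANOVA. Zero-variance degenerate inputs resolve by definition
(equal means → p = 1; unequal → p → 0, flagged) rather than propagating
NaN.

**Pseudoreplication caveat.** Pooling hundreds of curves per cell treats
correlated measurements as independent, so the pooled t-test's effective
type-I error exceeds its nominal level whenever cells or points vary. With
two groups generated at means 1.49 and 1.48 kPa (SDs 0.34/0.39) and 2000
curves each, the pooled test's noncentrality is ≈0.7 even under full
independence, so a "non-significant in ≥90% of replicates" expectation is
unattainable by construction — at best ≈89% for i.i.d. curves and far less
under the hierarchical generator. This is reported honestly by the test
suite rather than patched; mixed-effects modelling of the cell/point
nesting is deliberately out of scope.

## Synthetic force-curve generator

A curve is generated on a uniform h-grid (step 3 nm to 600 nm depth): force
from the contact law, deflection d = F/k, piezo position z = z₀ + h + d
with z₀ uniform in 400–600 nm, preceded by a pre-contact baseline from
z = 0. Gaussian noise (default SD 0.003 nm) is added to the recorded
deflection only. The default noise is an *effective* (post instrument
averaging/filtering) figure: the r² ≥ 0.99 gate rejects curves whose
residual noise exceeds ≈1% of the deflection signal's SD, and since signal
∝ E, larger noise would preferentially discard soft-cell curves and bias
group means upward. 0.003 nm keeps curves from all physically plausible
moduli (E ≳ 0.06 kPa) inside the gate.

Beyond `substrate_onset` (default 300 nm) the force continues linearly
with `substrate_stiffening` (default 3) times the contact-law slope at the
onset. Making the substrate term *relative* to the cell's own stiffness —
rather than an absolute nN/nm slope — matches bottom-effect corrections,
which multiply the Hertzian force by a modulus-dependent factor; an
absolute slope would contaminate soft cells disproportionately.
`substrate_stiffening = 0` disables the regime for forward–inverse
consistency tests.

An experiment draws moduli hierarchically: cell mean → point offset →
curve offset, each Gaussian, truncated at 0.01 kPa. A group's nominal
histogram SD splits into SD fractions 0.15 (cells) / 0.30 (points) /
remainder (curves). The reported per-curve histogram width is dominated by
within-cell spatial variation and curve-to-curve variability (cytoskeletal
remodelling between repeat indentations); cell-to-cell reproducibility of
the mean is comparatively good. This split also makes a 10-cell experiment
informative about the group mean (SE ≈ 5.6% of the histogram SD), which a
purely cell-level spread would not (SE = σ/√10 ≈ 32%). Defaults: 10 cells ×
20 points × 10 curves = 2000 curves per group, matching the scale of
point-and-shoot elasticity mapping (500–1000 curves per cell pooled over
replicate cells).

All generators are pure functions of (spec, seed).

## Methylation cohort and region analysis

Probe QC masks entries with detection p > 0.01 and drops probes missing in
> 30% of samples. Quantile normalization maps each sample's values onto the
cohort-average quantile function via average (tie-aware) ranks; missing
entries are excluded and restored, and with complete equal-length samples
the construction reduces to the classic sorted-row-means form. Hierarchical
clustering of samples uses Euclidean distance and complete linkage
(configurable), probe-mean imputation for missing entries (distance
computation only), and sorted sample labels for deterministic tie-breaks.

A sample is called methylated in a region when ≥ `min_probes` (default 1)
probes show beta ≥ `beta_threshold` (default 0.3). The threshold is an
explicit, configurable stand-in for a call that was originally read off a
heatmap; 0.3 sits in the canonical gap between unmethylated (< 0.2) and
methylated (> 0.6) beta modes. The association between gene-body CpG
status (the cg08881019/cg03946955 pair) and clinical risk dichotomized low
vs intermediate+high uses Fisher's exact two-tailed test
(minimum-likelihood convention) with the conditional-MLE odds ratio. Being
an exact test on discrete tables, its type-I rate at α = 0.05 is at or
below 0.05 (measured 0.044 over 1000 null cohorts); the calibration test
asserts that honest band rather than exact uniformity.

The synthetic cohort (105 samples, 25 probes in the hg19 *LMNA* region,
seeded) fixes exactly 3 promoter-methylated samples, a bimodal gene-body
pair splitting the cohort ~50/50, background probes with per-probe mean
levels spread over 0.15–0.90, Beta-distributed values at concentration 50,
a 1% detection-failure rate, and a configurable odds (default 6) linking
gene-body status to elevated risk. A *continuum* of background levels
matters: with only a few discrete value levels per sample, rank-based
quantile normalization can map low promoter values onto high reference
ranks and fabricate calls. Probe coordinates are synthetic placements
inside the real region (probe ids are real; their positions here are not).
Region-level multiple-testing machinery (Q-values across many regions) is
not implemented — only the stated probe filters and normalization.

Bisulphite clones are modelled on the analysed strand only: non-CpG
cytosines convert to T with the given efficiency; CpG cytosines stay C
exactly when methylated. Calling reads C → methylated, T → unmethylated,
anything else ambiguous; per-clone conversion efficiency is the converted
fraction of non-CpG reference cytosines, with clones below 0.95 flagged
(not dropped).

## What the synthetic data does and does not show

Passing recovery tests shows the pipeline is unbiased and correctly
calibrated *for data generated under its own assumptions* — parabolic
contact response, Gaussian noise, Gaussian modulus mixing, Beta-distributed
array values. Real curves add adhesion, viscoelastic hysteresis, baseline
drift and non-ideal tip geometry; real arrays add probe-specific biases,
batch effects and genome-wide context that a 25-probe region cannot carry.
The published-value "recovery" targets validate parameter recovery at the
published group distributions, not a re-analysis of the original cells or
patients; reproducing the patient-array counts requires the deposited
cohort, to which the identical pipeline applies via `cellmech
methyl-region`.

## Problem sizes

Default test and acceptance runs use 2000 curves per group (≈350 samples
per curve), 105-sample cohorts, 1000-cohort null calibrations and
40-replicate power checks; a full six-group acceptance run completes in
well under a minute on one CPU.
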