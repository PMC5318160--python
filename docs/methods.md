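# Methods

## Phase representation and circular arithmetic

Circadian phase is measured in degrees on [0, 360), 0° at dim-light
melatonin onset (DLMO), 360° = 24 h, 1° = 4 min. Conversions between angles
and the unit circle use the arctangent with explicit quadrant offsets (0 in
quadrant I, +180 in II/III, +360 in IV). The directional mean is the angle
of the averaged unit vectors; it is undefined (an error, not a NaN) when the
resultant length falls below 1e−9, e.g. for antipodal pairs.

The signed difference δ between angles θ and β keeps the raw difference when
it lies in (−180, 180), subtracts 360 above +180 and adds 360 below −180. A
raw difference of exactly ±180 maps to +180, making the operation total and
deterministic on the half-open interval (−180, 180].

Note that the directional mean minimizes the summed 1 − cos distance, not
the summed squared angular distance; the two minimizers coincide only in the
small-dispersion limit (within ±10° spread they agree to better than 0.1°,
but for widely dispersed sets they can differ by tens of degrees). The test
suite checks the least-squares equivalence only in its domain of validity
and checks the defining vector construction everywhere.

### Circular R²

R² = 1 − RSS/TSS, where residuals (observed − predicted) and deviations
(observed − directional mean of observed) are signed circular differences in
degrees. R² ≤ 1 and may be negative (worse than predicting the constant
mean). A switch computes the residuals instead as Euclidean distances
between unit-circle embeddings; the two agree closely for small errors and
"degrees" is the default. When all observed phases coincide (TSS = 0) or
their directional mean is undefined, R² is undefined — except that exact
predictions still report R² = 1. Error summaries report the mean and sample
(n−1) SD of signed errors in minutes, a histogram in half-open bins centred
on 0°, the proportion of samples with |error| ≤ 120 min (inclusive), and the
cumulative |error| curve whose terminal value is exactly 1.

## DLMO and phase assignment

From an hourly melatonin series, threshold = baseline + 0.25·(amplitude −
baseline), with amplitude the maximum observed concentration and baseline
(by default) the mean of the lowest quartile of concentrations — robust to
assay noise at the floor; "minimum" and fixed-window alternatives are
exposed. DLMO is the first ascending crossing of the threshold, linearly
interpolated between the bracketing samples; a profile that never crosses
raises a no-onset error. Samples are assigned phase ((t − DLMO) mod 24)·15°,
i.e. a fixed 24.0-h period: the data model has no per-individual period
estimate, and one cycle spans exactly 360°.

## Preprocessing

Quantile normalization uses a *frozen reference*: the element-wise mean of
the sorted training-sample vectors. Any later sample — validation or a
single clinical draw — is normalized by rank replacement against that stored
reference, so new data never influence it. Tied values receive the mean of
the reference values at the tied ranks. Flag filtering drops samples with
strictly more than 30% of features flagged, then features flagged in
strictly more than 10% of the remaining samples, in that fixed order.
Technical replicate probes are averaged; their flags are averaged and
binarized at ≥ 0.5. Z-scoring statistics (per-feature mean and n−1 SD) are
fit on training data only and stored with every model, because deployment on
a single sample has no population to standardize against; constant features
are excluded with a warning. Batch correction is deliberately a pass-through
hook for an externally corrected matrix: validation/clinical data arrive in
batches unrelated to training and are never batch-corrected.

## Circular-response PLSR

The response phase y is embedded as (cos y, sin y) and regressed on z-scored
abundance by PLS2. Fitting is the two-call protocol: (1) a T-factor fit on
all features; (2) features ranked by the sum over the T factors of absolute
predictor loadings (sum is the default aggregation; max is exposed); (3) a
second T-factor fit on the top-n features. The deployed model is the final
fit's linear coefficients and intercepts for both response coordinates, so a
prediction is two dot products plus the quadrant rule — reproducible
bit-for-bit from the serialized JSON (mode, feature list, scaler statistics,
T, wc/wc0/ws/ws0). The PLS implementation is scikit-learn's deterministic
NIPALS `PLSRegression` with the inner tolerance tightened to 1e−12: the
fitted subspace is then stable to numerical precision, which also preserves
the model's rotation symmetry (rotating all training phases by Δ rotates all
predictions by Δ) to ~1e−6 rather than the ~0.1° drift seen at the default
tolerance. Coefficients from other PLS variants (e.g. SIMPLS) differ
slightly; the deployment contract is the linear form, not the internal
scores.

### Differential mode

For each participant × condition, every ordered pair of samples separated by
12 h (± 0.5 h tolerance; overlapping pairs allowed) becomes one observation:
delta = values(sample1) − values(sample2), response = phase of sample 1 (the
natural anchor — the first clinic draw). Z-score statistics are fit on the
delta vectors themselves. Any per-participant constant expression offset
cancels in the subtraction *before* scaling; this is exact arithmetic
(bit-identical whenever the offset additions incur no floating-point
rounding, e.g. integer-valued data, and within ~1 ulp otherwise). This is
the mechanism that removes trait-like inter-individual differences, the
motivating failure mode of single-sample predictors.

### Consecutive mode

Repeated use of a one-sample model on 2–3 consecutive draws: the prediction
is the directional mean of per-sample predictions, compared against the
directional mean of the observed phases.

## Molecular timetable

Per feature, five closed-form cosinor fits (abundance regressed on cos θ and
sin θ; acrophase from the coefficient vector; r = Pearson correlation of
abundance with the best-phase cosine): one per sleep condition plus the
pooled series. Features with r ≥ 0.3 (default) in all five survive; within a
gene the feature with the highest pooled r represents it. The look-up table
stores pooled-fit peak phases; templates are unit cosines (fitted amplitudes
discarded — the comparator correlates shapes, and z-scoring already makes
features commensurate). Prediction scans a 1° grid and returns the
best-correlating phase, ties to the smallest; sub-degree precision would be
far below biological noise. The two-sample variant correlates the z-scored
sample difference against template differences with a 180° lapse. Pearson
correlation is undefined for a model with fewer than three features (any
centred 2-vector correlates ±1 with everything); building such a model
warns, and predicting with a constant sample vector raises. The original
timetable method's coefficient-of-variation filter is omitted: with only a
small rhythmic fraction under all conditions it adds nothing here.

## Model selection

Leave-one-participant-out cross-validation: one fold per participant, all of
their observations held out together (differential observations inherit the
participant of their source pair). The entire pipeline — scaling, screening
or loading-based ranking, fitting — runs inside each fold on training
observations only, so each fold may select different features. Pooled
held-out predictions give one cross-validated circular R² per parameter
setting. The grid marks cells with n < T invalid and records per-cell
failures without aborting. Default axes: one-sample T ∈ {5,…,40 step 5} × 17
feature counts from 100 to 5000 (136 cells); differential T ∈ {4,…,8} × 20
feature counts from 50 to 1000 (100 cells); both config-exposed, and the
acceptance script uses a compact {5,10} × {50,100,200,500} grid to keep the
desk-scale run under a minute. Selection: among cells with R² ≥ 0.70, the
smallest feature count wins, ties broken by the smallest T — feature count
binds first because assay size is the clinical constraint. If nothing
reaches the floor, the argmax-R² cell is returned with a logged warning
rather than an error, keeping pipelines runnable on hard regimes.

## Evaluation battery

Per-sample rows (observed, predicted, signed error in degrees and minutes)
plus: the circular R²; a 15° error histogram; mean error per 30° bin of
*observed* phase with normal-approximation 95% CIs (mean ± 1.96·SE; the CI
method is a package choice); one-way fixed-effects ANOVA of signed error on
observed-phase bin (small p ⇒ accuracy depends on sampling time; a
degenerate zero-within-variance layout reports p = 0 with a warning); and,
across sleep conditions, one-way ANOVA with Tukey HSD pairwise comparisons
(statsmodels' studentized-range implementation). Participant is not a factor
in either ANOVA — they are one-way analyses on bin or condition labels.

## Synthetic cohort generator

value(g, s) = mesor_g + trait_{p,g} + batch_{b,g} + A_{g,c}·cos(θ_s − φ_g) + ε,
ε ~ N(0, noise_sd), with θ_s the sample's true phase from the participant's
DLMO. Defaults emulate the study design at desk scale: 20 participants, 1000
features; each participant follows one protocol — mistimed sleep (in-phase /
out-of-phase conditions, 8 samples every 3 h) or sleep deprivation (no-debt
/ debt, 7 samples every 4 h); rhythmic fractions 8% / 1% / 6% / 6% with
*nested* rhythmic sets (out-of-phase ⊂ sleep-deprivation ⊂ in-phase), so a
core of features stays rhythmic everywhere, as observed in blood, and the
out-of-phase collapse is implemented by zeroing amplitudes rather than
shifting acrophases (simpler ground truth, matching the observation that
rhythmicity largely disappears rather than moves). Amplitudes are U(0.5,
1.5) log2 units; noise_sd defaults to 1.0 (the mean amplitude); trait_sd
defaults to 1.5 — trait variance ~1.5× the rhythmic signal, the
trait-dominated regime that motivates the differential model, and the
regime in which the default cohort reproduces the qualitative ordering
one-sample R² ≈ 0.7–0.8 < differential R² ≈ 0.83–0.92 under
leave-one-participant-out CV. Melatonin profiles are 13 hourly points:
baseline 3 pg/ml plus a 50 pg/ml logistic rise (steepness 0.75 h) whose
25%-of-range crossing sits at the participant's configured DLMO (drawn
N(21.5 h, 1 h)); only that crossing is contractual, and the round-trip
through the DLMO estimator recovers it to < 0.01 h on the default grid.
DLMOs, traits, batches and noise all flow from one seeded generator; the
seed fully determines every output.

What the generator does *not* emulate: probe-level microarray noise and dye
effects, correlated co-expression modules, per-individual circadian period
differences, sleep-stage physiology, or realistic flag structure (flags are
sprinkled i.i.d.). Passing tests therefore demonstrate correctness of the
algorithms and the qualitative trait/state mechanics — not clinical
performance on real cohorts, whose headline numbers require the original
microarray data.

## Numerical choices and degenerate inputs

- Phase grids: 1° for timetable look-up (the grid *is* the estimator), 0.1°
  for brute-force test oracles; ties always break to the smallest phase.
- Directional-mean resultant tolerance 1e−9; below it the mean is an error.
- Undefined-phase, no-onset, empty-model, degenerate-variance and
  undefined-correlation conditions raise typed exceptions rather than
  returning sentinels.
- Model JSON stores phases and peaks rounded to 4 decimals (0.36 s of
  time); scaler statistics and coefficients at full precision.
- Serialization schema is versioned (`schema_version: 1`).

## Problem sizes

The test suite and the acceptance script run the default 20-participant ×
1000-feature cohort for the headline cross-validations, an 8 × 200 cohort
for mechanism tests (trait invariance, degradation trends), and toy matrices
for all worked examples; the full suite completes in well under a minute on
one CPU.
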