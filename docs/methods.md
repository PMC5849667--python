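# Methods

This note records the statistical procedures `dbsval` implements, the
defaults it ships, the design choices that were genuinely open, and what
the synthetic-data tests do and do not demonstrate about real data.

## Setting

A cross-validation study of dried blood spot (DBS) sampling for everolimus
asks, per patient: do the capillary-spot concentration, a venous-blood-spot
concentration (DBS_wb, isolating the blood-source effect from the
paper-matrix effect), and the venous whole-blood (WB) concentration agree
well enough that the spot could drive dosing decisions? Inputs are one row
per patient: duplicate DBS spots with validity flags, DBS_wb, WB (µg/L),
hematocrit (L/L), daily dose (mg) and time after dose (h). Units are fixed
package-wide; configurable units invite silent errors in a safety-relevant
pipeline.

## Sample handling and QC

Duplicate spots both valid → arithmetic mean; exactly one valid → that
value with a `single_spot` flag (the single-spot rule is our choice — the
obvious alternatives are using or discarding such samples, and using them
with a flag maximises data while staying transparent); both invalid → the
patient is excluded from DBS comparisons but still contributes DBS_wb/WB
pairs. Hematocrit ≤ 0.20 L/L earns a hard warning and hematocrit < 0.25
combined with a spot concentration > 20 µg/L a caution flag, because spot
assays under-recover at low hematocrit, worst at high concentrations.
Every row is accounted for exactly once: analysed, flagged-and-analysed,
or rejected/excluded with a recorded reason.

## Passing-Bablok regression

For comparator x and reference y, all pairwise slopes
S_ij = (y_j − y_i)/(x_j − x_i) (i < j) are formed; pairs with equal x are
undefined and dropped, slopes exactly −1 are discarded, and
K = #{S_ij < −1}. The slope estimate is the median of the sorted slopes
with its index offset by K — equivalently the median in the angle domain
where a slope of −∞ ≡ +∞ — which makes the estimator invariant to
exchanging the roles of the two methods. The intercept is
median(y − b·x). Confidence intervals use the rank-based order-statistic
construction: C = z₁₋α/₂·√(n(n−1)(2n+5)/18), M₁ = round((N − C)/2),
M₂ = N − M₁ + 1, slope bounds at order statistics M₁+K and M₂+K, and
intercept bounds re-derived from the slope bounds as median residuals.

Numerical conventions: even slope counts average the two central order
statistics; sorting is stable so tied slopes resolve deterministically;
the analytic CI is only computed for n ≥ 10 (below that the order-statistic
indices degenerate and the fit is returned without intervals, with a
warning; a seeded 2000-resample percentile bootstrap is available as the
small-n alternative). Negatively correlated inputs warn — the construction
targets two methods measuring the same quantity — and data whose slopes all
lie at or below −1 cannot be fitted at all.

Bias reading: proportional bias ⇔ slope CI excludes 1; constant bias ⇔
intercept CI excludes 0. Pearson r and r² are reported alongside.

### Known limitation: error geometry

The estimator's consistency argument assumes comparable measurement error
on both axes. The test suite verifies nominal 95% CI coverage under that
model (exact linear relation, equal additive errors both axes, n = 200).
When essentially all scatter sits on the reference axis — as in our
generator, which applies the between-method noise to WB — the K-shift
wraps steep negative slopes from near-degenerate pairs to the high side
and biases the slope upward by O(cv²), and the heteroscedastic,
log-uniform concentration design leaves the Kendall-variance interval
slightly narrow; the coverage experiment in the test suite measures a few
percentage points below nominal under those conditions. This is a property
of the method under that error geometry, not an implementation artefact
(the implementation is checked exactly against exhaustive enumeration on
1000 small instances). At the study's n = 20 the CI is wide relative to
this bias and the effect is immaterial; it matters for large-n simulation
studies.

## Ratio-scale Bland-Altman agreement

Per-patient ratios r_i (reference over comparator, WB/DBS, by default; the
direction is configurable and always labelled, since published comparisons
are not always consistent about numerator and denominator). Summary: mean
ratio, SD (n−1 denominator), 95% limits of agreement mean ± 1.96·SD — the
classic multiplier, not a t quantile — and counts outside the LoA and
outside the limits of clinical relevance. The clinical band defaults to
(0.75, 1.25) on the ratio, i.e. ±25% around unity, because everolimus is
dose-adjusted in 25% steps; centring the band on the observed mean ratio
instead is a configuration option, as the definition "±25% around the
ratio" is ambiguous. Ratios are analysed on the raw scale (not
log-transformed), matching how such plots are reported.

## Limits-of-agreement power and sample size

Design question: how many paired samples demonstrate that both estimated
95% LoA of the relative difference lie within ±δ? With expected mean
relative difference μ, SD σ, and

    SE² = σ²·(1/n + 1.96²/(2(n−1))),

the power is the two-one-sided normal approximation
Φ((δ−μ−1.96σ)/SE − z₁₋α) + Φ((δ+μ−1.96σ)/SE − z₁₋α) − 1, monotone in n and
δ and decreasing in σ and |μ|. `ba_sample_size` bisects for the smallest n
reaching the target and reports infeasibility when δ ≤ |μ| + 1.96σ (the
true limit itself lies outside the allowed band, so no n can succeed).

`ba_power_mc` simulates the demonstration procedure directly. Two variants:
`se_mode="design"` evaluates the confidence step's SE at the design σ —
this is exactly the quantity the analytic formula approximates, and the
two agree closely (the test suite checks |analytic − MC| at n = 20 within
0.02); `se_mode="plug_in"` re-estimates the SE from each simulated cohort,
as a practitioner must, and runs a few points below the analytic value at
small n — the normal approximation's known anti-conservatism. At the
reference design (μ = 9%, σ = 5%, δ = 25%, α = 0.05, n = 20) both variants
and the analytic value exceed the 0.80 target.

## Leave-one-out predictive performance

For each patient i, a Passing-Bablok fit on all j ≠ i (point estimates
only; no CI needed inside the loop) gives (a_i, b_i) and the prediction
a_i + b_i·x_i. Splits come from scikit-learn's `LeaveOneOut`; a degenerate
reduced fit excludes that patient with a warning rather than aborting the
run. Requires n ≥ 4 so every reduced fit keeps 3 points.

Error summaries are the Sheiner-Beal median statistics (bias: MPE µg/L,
MPPE %; imprecision: RMSE µg/L, MAPE %). RMSE here is read as the
root-*median*-square √median((pred−obs)²) — consistent with its name and
µg/L scale in this literature; for odd counts it equals the median absolute
error exactly, and the conventional root-mean-square is reported alongside,
clearly labelled. The verdict passes when |MPPE| < 15%, MAPE < 15% (strict)
and ≥ 67% of patients have |percentage prediction error| < 20% (strict
inequality on 20, percentage errors relative to observed WB); failed
criteria are listed individually.

## Trough extrapolation and therapeutic window

A measured concentration at time t after dosing is extrapolated to the end
of the dosing interval assuming first-order elimination:
C_trough = C·exp(−ln2·(τ−t)/t½). Defaults: τ = 24 h (once-daily dosing),
population half-life 30 h (a representative elimination half-life for
everolimus in adults; the exact extrapolation used in any given clinic is
not standardised, so the half-life and the equation's inputs are
configuration, not constants). Samples drawn before the absorption phase
ends (default cutoff 2 h) are flagged unreliable; t > τ is an error.
Troughs are classified against the window 11.9–26.3 µg/L (bounds
inclusive; both bounds configurable, as the window itself is provisional).
Cohort percentages are computed in exact rational arithmetic before any
rounding, so below + within + above is exactly 100%.

## Synthetic cohorts

The generator emulates the study conditions: 20 patients; latent capillary
concentration log-uniform on 3.7–33.3 µg/L (spreading points over the
observed range without asserting a population-PK model); duplicate spots =
latent × independent lognormal noise (CV 3%, a typical within-card
replicate spread); DBS_wb = latent × lognormal noise (CV 5%); WB =
(0.02 + 0.89·latent) × lognormal noise with CV 9.4% — slope and intercept
from the fitted between-matrix relationship, and the ratio CV
back-calculated from the printed LoA width (1.08 − 0.71)/(2·1.96); each
spot independently invalid with probability 0.025; hematocrit uniform on
0.25–0.45 L/L, dose from the 5–17.5 mg set, sampling time uniform on
20–24 h (trough visits). All noise factors are lognormal with **unit
mean** (µ = −σ²/2), so measurements are positive, relative spread is
constant, and the expected measurement sits on the model line. Replicate
streams derive integer sub-seeds from (master seed, replicate index), so
replicate k regenerated alone equals replicate k of the stream.

What this does *not* emulate: hematocrit-dependent chromatographic
recovery, assay calibration drift, patient self-sampling quality, or any
correlation between concentration and hematocrit/dose. Passing tests on
synthetic cohorts therefore demonstrate the statistical machinery — not
that any particular assay is valid; and because the generator puts the
between-method scatter on WB, large-n Passing-Bablok simulations on it
inherit the error-geometry caveat above.

A zero-noise, zero-intercept configuration is an exact fixed point of the
whole pipeline (slope recovered exactly, all prediction errors zero,
verdict pass, nothing outside the clinical limits) — used as an end-to-end
closure test.

## Reporting

`run_validation` chains QC → pairing → agreement (all three comparisons) →
leave-one-out prediction (principal pair, DBS-vs-WB by default) → trough
summary, deterministically; stage failures are re-raised with the stage
name. JSON output keeps full precision; the text rendering rounds
concentrations and ratios to two decimals and percentages to one, and
rounded values never feed back into computation. Problem sizes used by the
test suite (500 replicate cohorts at n = 200 for CI coverage, 10⁵
Monte-Carlo replicates for power, 1000 enumeration instances at n ≤ 8)
keep each suite comfortably within a desk-scale run while holding the
Monte-Carlo error well below the tolerances being asserted.
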