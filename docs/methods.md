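# Methods

This note documents the models, numerical choices and known limits of
the package; it states nothing the tests or `scripts/acceptance.py` do
not themselves compute.

## Bilinear model and MCR-ALS

A photodegradation experiment is modelled as `D = C Sᵀ + E`, with `D`
the time × wavelength absorbance matrix, `C` (time × species) the
concentration profiles, `S` (wavelength × species) the pure spectra and
`E` noise. The analysis window is 215–450 nm at 1 nm: shorter
wavelengths are dominated by solvent cut-off and are dropped on load.

**Rank estimation.** The chemical rank is the number of leading singular
values that are (i) within a factor 25 of the largest and (ii) above a
noise floor of 3× the median of the trailing half of the singular-value
spectrum. The trailing values sample the noise plateau, so the floor
adapts to the data; the ratio test alone would count noise components on
nearly noise-free data.

**Initialization.** Purest-variable (SIMPLISMA-style) selection:
wavelengths are ranked by purity `sd/(mean + α)` of their time profile,
with offset `α` = 1% of the largest channel mean to stabilize
low-signal channels; after each pick, candidate purities are deflated by
their squared-sine angle to the span of the chosen profiles. Because a
column of the time × wavelength matrix at a pure wavelength is a
*concentration* profile, the chosen columns are mapped to spectral
estimates by one least-squares step, clipped non-negative and scaled to
unit maximum. Selection is deterministic.

**ALS iteration.** Given `S`, `C = argmin‖D − C Sᵀ‖` by SVD-based least
squares, then constraints in order: non-negativity (clip to 0),
unimodality (walking outward from each column's maximum, values above
the running minimum are replaced by it — applied uniformly, since a
monotone parent decay is unimodal with its peak at t=0), closure (each
row rescaled to the t=0 row total; the t=0 total is the natural closure
constant for a unimolecular scheme starting from pure parent). Then `S`
is re-solved with non-negativity only. Convergence is declared when the
relative change of lof between iterations falls below `tol` (default
1e-3, i.e. 0.1%) or lof < 1e-7% (machine-precision floor — relative
jitter below that level is meaningless); `max_iter` defaults to 500 and
the best iterate seen is returned if the cap is hit, so the returned lof
is never worse than the first iterate's. A rank-deficient least-squares
step (collinear spectra or profiles) raises with guidance rather than
silently proceeding.

**Identifiability.** When closure is on it fixes the scale of `C`;
without closure the scale indeterminacy is resolved by unit-maximum,
non-negative spectra with the scale absorbed into `C`. Components are
reported parent-first (profile maximum at t=0), then by time of maximum.
Rotational ambiguity is not otherwise analysed (band boundaries are out
of scope); with the default well-separated synthetic bands each species
has spectral regions where the others are negligible and the constrained
factorization is essentially unique, which is why noiseless recovery in
the tests is exact. Strongly overlapping bands can leave a genuine
ambiguity set within which ALS has no preference; results there inherit
the initialization.

## Synthetic data

The generator emulates the study conditions the pipeline assumes:
Gaussian absorption bands (parent at 360 nm, width 20 nm; aromatized
photoproduct at 270 nm, width 20 nm, amplitude 0.9; optional trace
second product at 300 nm, amplitude 0.1 — a tenth of the parent, since
it is observed only in traces), first-order kinetics on the 23-point
exposure grid (t=0 plus 1, 2, 3, 4, 5, 10, 15, 20, 25, 30, 40, 50, 60,
80, 100, 120, 150, 180, 210, 240, 270, 300 min, stored in seconds), and
homoscedastic Gaussian noise with SD expressed as a fraction of the
global signal maximum — the simplest model of instrumental noise; no
baseline drift, stray light or wavelength-dependent variance is
simulated. Both a single-step scheme A → P1 and a sequential
A → P1 → P2 (two-step consecutive first-order solution) are provided;
whether the trace product forms from the parent or from the first
photoproduct is not identifiable from the source data, and the
sequential form is the default. The degenerate case k₂ = k₁ makes the
analytic solution singular and is rejected. Every stochastic operation
takes an explicit seed.

Passing tests on these synthetics show the algebra and the estimation
chain are correct at realistic noise; they do not show robustness to the
features real spectra add (baseline drift, band shifts, heteroscedastic
noise, more than three species).

The QSPR generator draws descriptor columns standard-normal, or
uniformly within named per-descriptor ranges (e.g. the observed ranges
of the packaged table), and builds the response from a known sparse
linear model plus Gaussian noise, so selection and recovery can be
tested against ground truth.

## Kinetics

`k₁` is minus the slope of the OLS line through `(t, ln %parent)`.
Points at or below 1% residual are excluded by default (the log of a
near-zero resolved concentration is numerically explosive); the
threshold is a parameter. The intercept is *estimated*, not fixed:
ideal first-order data give ln 100 = 4.605, and forcing a different
constant would bias the slope; a fixed-intercept mode exists for
compatibility experiments. The reported `k1_sd` is the single-fit
standard error of the slope — replicate-based SDs cannot be reproduced
without the replicates.

`t₀.₁` has two conventions. Exact first-order algebra gives
`t₀.₁ = ln(10/9)/k₁ = 0.10536/k₁`. The packaged kinetics table is
instead internally consistent with `0.1100/k₁` (equivalent to an
intercept of ≈4.61): the `table_compat` mode uses that constant and
reproduces the tabulated `t₀.₁` within 0.5% for all 22 non-DHP
compounds. The 8 DHP-series rows are inconsistent with their own rates
by a factor of ≈25 (a unit slip in the source tables); they are shipped
verbatim, flagged by the audit, and never corrected. Which convention is
"right" is not decidable from the tables, so both are exposed and
neither is silently preferred.

The two-step fit minimizes the joint residual of all three concentration
columns against the consecutive-first-order solution over (log k₁,
log k₂), initialized from the log-linear parent fit with a small
multi-start on k₂ (factors 0.1–10) because the secondary rate is weakly
identified when the second product stays near trace level.

## QSPR

The response unit throughout is k ×10⁻³ s⁻¹ (the unit of the packaged
validation table; the kinetics table's ×10⁻⁴ values are converted at
load). OLS is solved by SVD (`lstsq`); a rank-deficient design returns
the minimum-norm solution with a loud warning instead of failing,
because near-saturated calibrations (17 descriptors, 20 samples) are the
normal regime here. Standardized coefficients `Bw = coef × column SD`
rank descriptor influence on a common scale. PCR autoscales, regresses
on the first m principal-component scores, and back-transforms the
coefficients to descriptor units; with full rank it reproduces OLS
exactly, which the tests assert.

Leave-one-out CV refits the cloned estimator per fold, so any in-model
scaling is re-estimated inside the loop. Forward selection enters first
the variable with the largest absolute Pearson correlation with the
response, then greedily adds the candidate minimizing LOO RMSECV,
stopping when the improvement falls below `min_improvement` (default
1e-6 response units) or `max_vars` is reached; ties break toward the
lower column index, making the procedure fully deterministic. Validation
reports per-compound error % = 100·(pred − exp)/exp, RMSEC/RMSECV/RMSEP,
and three relative-error aggregates (mean absolute, mean signed, RMS)
because the convention behind a single published aggregate is often
unstated.

The published model equation is shipped as data and can be evaluated
under two intercept variants: as printed (1.216×10³) and corrected
(1.216×10⁻³). The printed intercept is six orders of magnitude above
every observed rate and is presumed a typo, but since it is also unclear
whether the printed coefficients apply to raw or autoscaled descriptors,
the package evaluates both variants and asserts agreement for neither.
The final published model itself is ambiguous (an explicit OLS equation
next to an "eight PC" validation), so the reproduction run fits both OLS
and PCR-8 side by side and reports both.

## PCA exploration

PCA runs on the autoscaled (mean 0, SD 1, n−1 denominator) descriptor
block; explained variance is 100·σᵢ²/Σσ² over all non-trivial
components, so it sums to 100. The sign of each loading column is fixed
by making its largest-magnitude entry positive. Because the sample set
behind the published score plot is not stated, both candidates are
computed: the 20-compound calibration block reproduces the published
EV (28.45% / 21.95% vs 28.45% / 21.94%), the 30-compound set does not,
so the calibration block is the default. Biplot coordinates scale
loadings by the component's singular value; no plotting is done in the
core. The correlation matrix stores signed Pearson r (the published
heatmap's values range over [−0.4, 0.4] and are signed, whatever its
label suggests).

## Fixture audits and printed-precision limits

All packaged values are transcribed exactly as printed and checksummed.
Audits are rounding-aware: a printed value carries an uncertainty of
half its last printed digit, so cross-table checks (rate unit
conversion; validation-table error %) test whether the printed numbers
are *consistent for some unrounded values* inside those half-ULP boxes.
Under that criterion every row passes. Point comparisons tighter than
the printed precision cannot pass in general: the validation table's
predictions are printed to 3 decimals, which at rates near 0.1×10⁻³
injects ~0.5 percentage points into a recomputed error %, and the
descriptor table's rounding shifts the PC2 explained variance by ~0.01
points. The tests that assert those tighter point tolerances document
this in place.

## Problem sizes

The shipped analyses are desk-scale by construction: 23 × 236 spectral
matrices, 20–30 × 17 descriptor blocks, and synthetic selection problems
up to 40 × 50. The full test suite and the acceptance script each run in
a few seconds on one CPU.
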