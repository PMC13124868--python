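# Methods

This note records the models, assumptions and numerical choices behind
`ramanscreen`, in the spirit of a statistics package's model documentation.

## The screening procedure

The unit of analysis is a *filter combination*: one level from each of four
preprocessing categories (smoothing, baseline correction, normalization,
other), applied in that fixed order.  The category order is a convention —
the four stages are not commutative — and is documented rather than
claimed optimal.  Enumerating all levels gives 6 × 5 × 4 × 4 = 480
combinations; the raw (all-none) cell is additionally refit 10 times so the
factorial stage has replicate rows for pure-error estimation, giving 490
screen rows per (parameter, technique).

One calibration/validation split (80/20, stratified by run so every run
contributes calibration samples) is drawn per seed and reused across all
490 rows: metric differences between rows then reflect preprocessing
alone.  A combination whose preprocessing degenerates (e.g. SNV of a
constant spectrum) is recorded as a failed row and skipped downstream; the
screen never aborts.

Metrics are computed on the validation split.  SD_AE is the sample
standard deviation of the absolute errors (ddof = 1; a population variant
is selectable).  Relative errors are undefined at y_obs = 0; such samples
are excluded with a warning.

## Filter operators

Savitzky-Golay smoothing uses a quadratic local fit over 15 points with
polynomial edge extrapolation, so polynomials up to order 2 are reproduced
exactly.  The derivative operators are Savitzky-Golay derivatives (first
derivative with a quadratic, second with a cubic), scaled by the axis step.

"Symmetric EWMA" is implemented as the mean of a forward and a backward
exponential pass (α = 0.3 by default; the smoothing constant is exposed
because no canonical value exists), which cancels the directional lag of a
single pass.

Wavelet denoising detrends by the spectrum mean, decomposes with a
Daubechies-4 wavelet to the maximum feasible level, soft-thresholds the
detail bands at the universal threshold σ̂√(2 ln n) with σ̂ estimated from
the median absolute deviation of the finest band, reconstructs and restores
the mean.

AsLS solves the Whittaker problem `min Σ wᵢ(yᵢ−zᵢ)² + λ Σ (Δ²z)²` with
asymmetric weights (p above the curve, 1−p below), λ = 10⁴ and p = 0.001,
iterated to weight convergence (≤ 50 iterations) via a banded Cholesky
solve.  Used as a *smoother* it returns the curve z; as a *baseline* it
returns y − z — the only reading under which the two category entries
differ.  At these parameters the converged curve sits ~1–3 % below a flat
noiseless baseline (scaling with the peak-to-baseline ratio); this is a
property of the estimator, not a bug, and the operator tests assert it at
realistic peak heights.

MSC regresses each spectrum on a reference (y ≈ a + b·ref) and returns
(y − a)/b.  The reference is the mean of the *calibration* spectra at that
pipeline stage and is reused unchanged for validation and hourly spectra —
the only cross-sample coupling in the filter library.  A non-positive gain
leaves the spectrum uncorrected with a warning.

The "linear" baseline is a full-spectrum OLS detrend (not endpoint
anchoring); peak-height and peak-area normalization use the global maximum
and the trapezoid area of |y|, with an optional wavenumber sub-range.

## Calibration models

**PLS.**  PLS1 components are extracted by NIPALS on mean-centred data
(closed form per component for a single response).  Predictions are
identical to scikit-learn's `PLSRegression(scale=False)`, which serves as
an independent cross-check in the test suite.  Q²cum comes from 7-group
cross-validation, groups assigned round-robin after a seeded shuffle.  The
retained component count is the last one whose cumulative Q² gain exceeds
0.01 (threshold exposed); the exhaustive screen caps components at 5 — at
the synthetic study's analyte count plus background dimensionality, more
latent variables mostly fit noise, and the cap keeps the 3 430-model screen
around a minute on one CPU.

**ANN.**  Inputs are PCA scores retaining 99 % variance (capped).  The
automated search trains every single-hidden-layer topology with
N_HN ∈ {1..N+1} and all 25 pairs of hidden/output activations from
{identity, logistic, tanh, exponential, sine} — exactly 25·(N+1)
candidates — with sum-of-squares loss, full-batch Adam, ≤ 500 epochs and
early stopping (patience 20) on the 15 % test split of a seeded 70/15/15
row split.  The winner maximises the test-set correlation between target
and output (configurable to the validation split); ties prefer fewer
hidden neurons, then the earlier activation pair.  Exponential and
logistic pre-activations are clipped at ±30 to avoid overflow; inputs and
target are standardised internally and predictions mapped back.
Non-convergent candidates are logged and skipped.

## Factorial models and desirability

Each metric (MAE, SD_AE; per parameter) is modelled by OLS on sum-to-zero
coded main effects and all two-factor interactions of the four categorical
factors (15 + 83 columns + intercept; full rank on the 480-cell grid).
Backward elimination removes whole factor terms by grouped partial F-tests,
with the per-term threshold set to α divided by the number of candidate
terms: this Bonferroni-style correction controls the probability of
retaining *any* spurious factor at ≈ α, so the reduced model names only
genuinely active filters.  Main effects are never removed while an
interaction containing them survives (hierarchy).

Response transformation (`auto`) follows the Box-Cox profile likelihood of
the regression: identity if the 95 % interval for λ contains 1, log if it
contains 0, otherwise the MLE λ̂.

Optimization evaluates the fitted models at all 480 cells (the space is
exhaustive, so no search heuristic is needed) and maximises Derringer
desirability with minimisation ramps between the observed response minimum
(d = 1) and maximum (d = 0), importance 5 for MAE and 4 for SD_AE.
Overall mode pools every parameter's two responses; each response is
ramped by its own bounds, so units never mix.  Optimizing over model
predictions (not raw observed metrics) smooths replicate noise; the raw
argmin is available for diagnostics.  The individual-vs-overall comparison
is a paired one-tailed t-test on the two combinations' validation AE
vectors at α = 0.05.

## The synthetic study

The generator emulates the monitoring campaign the workflow targets, not
any particular instrument:

* **Design** — five ~120 h batch runs (uninfected; two single infections
  at TOI 24 h and 36 h; a pre-infected inoculum; a co-infection at TOI
  24 h) with 12/12/13/13/15 offline samples, 65 in total.  Each
  calibration spectrum is the mean of 6 sub-spectra rendered at the
  sampling moment; hourly single spectra per run form the profile-
  validation stream.
* **Kinetics** — logistic Xv growth (μ = 0.045 h⁻¹, capacity 70 × 10⁵
  cells/mL) with lytic arrest one 12 h lag after infection and first-order
  decline thereafter; Monod-limited glucose/glutamine uptake proportional
  to Xv; lactate/glutamate/ammonium produced at fixed yields on the
  consumed nutrient; viability ≥ 96 % until arrest, then monotone decline
  toward 30 %.  Initial concentrations mimic a serum-free insect-cell
  medium (glucose 9 g/L, glutamine 1.4 g/L; products start near zero).
* **Spectra** — intensity is a linear mix of per-analyte Gaussian peak
  groups (positions loosely inspired by known Raman bands, e.g. glucose
  near 1125 cm⁻¹; they are configuration, not claims) over the full
  100–3425 cm⁻¹ axis at 1 cm⁻¹.  Response coefficients are scaled so each
  analyte's footprint is comparable over its realistic range.  Viability
  enters through two derived components: viable biomass (∝ Xv·CV) and
  debris (∝ Xv·(100−CV)).
* **Background and noise** — the fluorescence baseline is a degree-3
  polynomial plus two broad Gaussian humps with run-specific random
  coefficients, a deterministic per-run gain spread, and a slow within-run
  drift.  The humps matter: an exact low-order polynomial background spans
  a 4-dimensional subspace that a handful of PLS components can annihilate,
  which would make preprocessing look useless; real fluorescence is not so
  obliging.  Detector noise is additive (σ = 1.2 counts) plus 0.5 %
  multiplicative; offline reference assays carry 2 % CV multiplicative
  noise, typical of biochemistry-analyzer precision.

What passing tests on this fixture do **not** show: robustness to cosmic
spikes, probe fouling, nonlinear detector response, water/sapphire
artifacts, or matrix effects that break spectral linearity — none of which
the generator emulates.  The pipeline's *procedural* correctness (metric
algebra, factorial selection, desirability optimization, split hygiene) is
what the synthetic study certifies.

## Numerical choices and degenerate inputs

* Windowed operators use shrinking/extrapolated edge handling so output
  length always equals input length.
* All randomness flows from explicit seeds; the PLS screen is bitwise
  reproducible, the ANN path reproducible given the same seed.
* Zero-variance targets, constant spectra under SNV, non-positive peaks
  under peak normalization, and zero-area spectra raise typed errors; the
  screen converts them to failure rows.
* t-tests with zero-variance differences return t = 0, p = 0.5 (no
  difference) or a sign-appropriate limit.
* Desirability bounds default to the observed response min/max over the
  screen (configurable); degenerate all-zero desirability is reported, not
  silently argmaxed.

## Known limitations

* The commercial implementations this workflow is modelled on (SIMCA's
  EWMA/WDS/MSC variants, its calibration wizard's LV rule, Statistica's
  network search) are proprietary; the definitions here are documented
  best-effort equivalents, with the contracts tested being the public ones
  (counts, invariances, closed forms), not vendor trajectories.
* PLS is single-response (PLS1) by design — the screen calibrates each
  parameter separately.
* The ANN search is exhaustive over a small grid, not a general
  architecture search; deep or regularised networks are out of scope.
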