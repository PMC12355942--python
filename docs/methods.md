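# Methods

This note records the models implemented, the numerical and design choices
behind them, what the synthetic data do and do not emulate, and the known
limitations.

## Fluorescence indices

All indices are ratios of emission intensities read off a corrected EEM.
Lookups are bilinear (linear between adjacent excitation slices, then linear
in emission); exact grid hits return stored values, and requests outside
either grid raise an error rather than extrapolate. ARIX's wavelengths were
chosen to sit on the shoulders of the underlying fluorophore groups, in
spectral regions clear of Raman scatter and overlapping fluorophores;
fabricating off-grid intensity would defeat that, so extrapolation is never
offered.

Band integrals (HIX numerator and denominators, the freshness-index peak
search) are plain sums over a 1-nm linearly interpolated emission grid with
inclusive endpoints. The constant grid factor cancels in every ratio, and
on grids ≤ 2 nm the sums agree with trapezoid integration of the underlying
profile to well under 1 %. HIX and HIX₁₉₉₉ share a numerator, giving the
identity HIX = HIX₁₉₉₉/(1 + HIX₁₉₉₉), which is property-tested.

Undefined indices (grid does not cover the needed wavelengths, or a
denominator at/below the detection floor) are flagged `None` individually;
other indices of the same EEM are still computed. The ARIX detection floor
defaults to 0 (only non-positive denominators rejected) because no numeric
detection limit is established for low-fluorescence waters (estuarine
dilution makes ARIX vary randomly); the floor is exposed as configuration.

Inputs are assumed fully corrected (instrument correction, inner-filter,
scatter). A `mask_scatter` utility — off by default — excises ±10 nm around
first/second-order Rayleigh lines and the water Raman line (~3,500 cm⁻¹
Stokes shift; ex 320 nm → em ≈ 360 nm) and re-interpolates along emission,
for inputs whose upstream scatter handling is in doubt.

PARIX is computed from user-supplied PARAFAC Fmax scores
(long-emission/short-emission); PARAFAC fitting itself is out of scope by
design — avoiding it is ARIX's reason to exist.

## Absorbance

Decadic cell absorbance is the stored quantity; A254 in sample tables is
decadic absorbance per meter (1 cm cell value × 100). Napierian
coefficients use ln(10) at full floating-point precision for bit-stable
arithmetic. Spectral slopes are fitted two ways: log-linear regression of
ln a(λ) on λ (S = −slope), and nonlinear least squares of
a(λ) = a_ref·exp(S·(λ_ref − λ)) with λ_ref fixed at the band's upper edge,
unweighted, initialised from the log-linear estimate. Both agree exactly on
noise-free exponentials; they weight noise differently. The reference-edge
and unweighted choices are conventions isolated here — different slope
tooling differs in exactly these details. Slopes are stored in nm⁻¹
internally; the Pan-Arctic model and the 1/S ARINT proxy consume μm⁻¹
(×1000) and the Yan models consume nm⁻¹ (their printed constants 0.078 and
0.0084 live in that domain). Conversions are explicit at the model
boundary, never implicit.

## Regression

Model I regression is ordinary least squares; the robust option is IRLS
with Tukey's bisquare, tuning constant 4.685 and MAD scale (the default
behind common statistical tooling; a convention, not a requirement),
converging on coefficients at 1e-8 or 50 iterations. Both are delegated to
statsmodels behind the module surface. Model II (geometric-mean /
reduced-major-axis) regression is computed in closed form:
slope = sign(r)·s_y/s_x, intercept through the means, with the common
approximation SE ≈ |slope|·√((1−r²)/n). r = 0 leaves the slope sign
undefined and is an error rather than an arbitrary choice. R² = 1 − RSS/TSS
may be negative (a model fitting worse than the horizontal line through the
mean); RMSE uses df = n − (estimated mean parameters).

Model II is the appropriate estimator when both variables carry error and
depend on an unmeasured third quantity — e.g. a multi-instrument
compilation where neither SUVA nor ARIX is error-free. The geometric-mean
slope is consistent when the error-variance ratio σ²_y/σ²_x matches the
squared slope; the acceptance script's calibration-recovery simulation
generates errors on both axes in that regime.

## Published calibrations

The registry stores the printed coefficients digit-for-digit and is
immutable. The percent-aromaticity relation is exposed in both printed
forms (via SUVA and via ARIX); composing the isolate calibration slope 4.5
into the ¹³C-NMR relation slope 6.52 gives 29.34, matching the printed
ARIX-form coefficient 29.3 within rounding. Negative SUVA predictions from
the bulk-water calibration (possible below ARIX ≈ 0.115, beneath the
observed range 0.15–1.1) are returned with a warning, not clamped: they
signal out-of-domain input.

## DOC models

The interaction model includes aromaticity only as an interaction term,
never a main effect: the optical proxies are undefined when absorbance is
zero, so a main effect could take meaningless values. Rearranged, the model
reads A254 = (DOC − b₀)/(b₁ + b₂·P_π) — Beer–Lambert form with colored DOC
as the concentration and molar absorptivity ∝ 1/(b₁ + b₂·P_π). The
diagnostics report per-sample colored DOC, the absorptivity proxy (flagged
undefined where b₁ + b₂·P ≤ 0) and the interaction ratio b₂·P/b₁, whose
spread indicates how much improvement over the base regression to expect.

Unit conventions per model, carried by each fit object and never converted
silently: base/ARINT use decadic A254 (m⁻¹) and DOC in mg/L; Pan-Arctic
uses Napierian a₃₅₀ and S in μm⁻¹ (the convention under which its published
M range 0.04–0.07 is sensible at S ≈ 15–25); the Yan models use Napierian
a₂₇₅, slopes in nm⁻¹ and DOC in μmol/L, converted to mg/L with 12.011
g/mol. Pan-Arctic C and M are estimated by OLS in log₁₀ space (the source
describes the equation, not the fitting procedure; documented here as this
package's choice). The Yan global preset (Φ = 1507, DOC_cor = 32.2) is
exactly reproduced by a local fit pinned to those constants.

Information criteria use the Gaussian profile log-likelihood
logL = −(n/2)(ln 2π + ln(RSS/n) + 1) with parameter counts k = 0 (global
preset), 2 (base, Pan-Arctic, local Yan fit), 3 (interaction model) —
counting estimated mean parameters only, the convention of the printed
counts; a flag can add the residual variance (+1 uniformly, rank order
unchanged). RSS = 0 makes the likelihood diverge and is reported as a
degenerate comparison rather than an infinite criterion. Model comparison
runs all applicable models on shared complete cases so criteria share n,
reports RMSE, percent RMSE change versus the base model, and flags the
model lowest on a majority of the four criteria, with ties shared.

## Sensitivity simulation

The simulation asks how much scatter in SUVA-vs-ARIX a given level of
random measurement error would produce on its own. An error-free table
keeps observed DOC and ARIX but recomputes A254 = (β₁·ARIX + β₀)·DOC so
every sample lies exactly on the calibration line (defaults 6.1, −0.7).
Each run adds independent zero-mean Gaussian errors to DOC, ARIX and A254
(absolute in the variable's units, or relative as a multiplicative
1 + N(0, sd)), recomputes SUVA = A254/DOC, refits SUVA ~ ARIX by model I
and records the RMSE; the median across runs divided by the observed RMSE
is the reported ratio. Refitting per run (rather than scoring against the
fixed line) matches how prediction error is reported from fitted models;
the fixed-line alternative is exposed via `refit=False`. Perturbed DOC
values that come out non-positive are resampled, not truncated, preserving
the zero-mean error assumption approximately. Per-run RMSE below 1e-10 of
the SUVA scale is snapped to exactly zero, so the no-noise case reports a
ratio of exactly 0 instead of floating-point residue.

Error standard deviations are instrument- and laboratory-specific; the
package ships no default magnitudes and requires them explicitly. To first
order, ARIX-only absolute noise σ_A produces RMSE ≈ β₁·σ_A (slightly less
after regression attenuation), which the tests verify against the
delta-method value at σ_A = 0.05.

## Synthetic data

Fluorophores are separable Gaussian(excitation) × Gaussian(emission)
profiles. Real DOM emission spectra are not separable; the form is a test
fixture chosen because every index then has a closed form, not a physical
model. The default palette (long-emission component at 510/60 nm em,
short-emission at 400/40 nm) spans ARIX ≈ 0.15–1.1 over amplitude ratios
0.15–1.3, the range observed in natural bulk waters. Absorbance spectra
are pure exponentials with optional additive noise. Sample tables realise
the colored/uncolored DOC split generatively: P uniform on [0.2, 1.0]
(matching where most natural samples fall), colored DOC uniform on
[2, 30] mg/L, DOC = b₀ + cDOC, A254 = cDOC/(b₁ + b₂·P), with defaults
b₀ = 1, b₁ = 0.6, b₂ = −0.3 placing the interaction ratio in [−0.5, −0.1]
and SUVA within the natural 1–6 m² g_C⁻¹ span. Generation fails upfront if
b₁ + b₂·P can reach zero inside the proxy support. All randomness is
`numpy.random.default_rng` (PCG64) under explicit seeds, reproducible
across platforms.

Passing tests on these fixtures demonstrate correctness of the estimators
and the algebraic structure of the models; they do not demonstrate
performance on real waters, where non-separable spectra, scatter residues,
iron interference, pH effects and instrument bias all intrude.

## Problem sizes

Test and acceptance runs use n = 50 for noise-free recovery (exact to
numerical precision at any n), n = 150–200 with 3–5 % relative noise for
stochastic recovery and model selection (100 seeds for coverage), 100
Monte Carlo runs for the sensitivity simulation, and 21-point 1-nm bands
for slope fits — sizes at which every stochastic check is stable across
seeds while the full suite runs in seconds.

## Known limitations

- No inner-filter or Raman-normalisation corrections: inputs must be fully
  corrected EEMs.
- No iron-absorption or quenching corrections; these interferences are
  real in natural waters but no published algorithm is implemented.
- The model II standard-error formula is an approximation; published ±
  values from other tooling may differ in the third decimal.
- The Pan-Arctic and Yan models are implemented as published for
  comparison; they were developed on predominantly marine data and are
  expected to underperform in inland waters.
- The sensitivity simulation's noise magnitudes must come from the user's
  own instrument precision data.
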