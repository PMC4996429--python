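# Methods

## Model family

All models share the protonated molar fraction of a one-site equilibrium
with empirical Hill cooperativity `n`,

    f(pH) = hⁿ / (Kaⁿ + hⁿ) = 1 / (1 + 10^{n(pH − pKa)}),   h = 10^-pH.

`n = 1` is a simple proton-exchange reaction; `n < 1` (anticooperative)
arises when protonation is mediated by other proton-exchanging species
rather than by freely diffusing H⁺, as is expected in femtoliter-scale
compartments where very few free protons exist.

Observables:

* **One-site intensity** (`eq6`/`eq7`): `I = Ia·f + Ib·(1−f)` per
  emission channel, with limiting intensities `Ia` (acidic) and `Ib`
  (basic).
* **Full ratio model** (`eq9` for R12 = I₁/I₂, `eq10` for R21):
  `R12 = (I1a·f + I1b·(1−f)) / (I2a·f + I2b·(1−f))`, built from the four
  limiting channel intensities.  This is the correct forward model for a
  ratio, because the ratio of two affine functions of `f` is not itself
  affine in `f`.
* **Henderson–Hasselbalch ratio blend** (`eq5`/`eq8`):
  `R = Ra·f + Rb·(1−f)` applied directly to the ratio.  Implemented
  because it is the traditional approach; it is *biased* (below).
* **Manufacturer-manual model** (`eq12`/`eq14`): the F-factor-corrected
  form distributed with the probe.  Algebraically identical to the full
  ratio model at `n = 1` (verified to <1e−12 in the tests); it has no
  Hill term.

### Closed-form bias of the ratio-blend fit

Dividing the full R12 model's numerator and denominator by `I2a` rewrites
it exactly as a Henderson–Hasselbalch blend with
`Ka′ⁿ = Kaⁿ·(I2b/I2a)`.  A blend fit to exact full-model data therefore
recovers

    pKa_app = pKa − (1/n)·log10(I2b/I2a)       (R12)
    pKa_app = pKa − (1/n)·log10(I1b/I1a)       (R21)

`models.apparent_pka_shift` returns this apparent pKa; the test suite
confirms it against a brute-force nonlinear fit to 1e−6 across random
calibrations.  With a rising denominator channel the R12 fit reads low
and the R21 fit reads high, so the two orientations bracket the truth —
a quick diagnostic for real data.

### Inversion

    pH = pKa − (1/n)·log10 X,   X = (I1b − R·I2b) / (R·I2a − I1a)   (R12)

and the channel-swapped analogue for R21.  `X > 0` exactly when `R` lies
strictly between the limiting ratios `Rb < R < Ra` (the two factors then
share sign); the implementation guards on that open interval and reports
which limit a bad ratio violates.  Two exact identities follow directly
and are used as pipeline invariants:

* **Hill shift**: for a fixed ratio, `pH(n) − pKa = (pH(1) − pKa)/n`.
* **pKa translation**: `X` does not contain `pKa`, so shifting the
  calibration pKa by δ shifts every measured pH by exactly δ.

## Fitting

`TitrationCalibrator` wraps a Levenberg–Marquardt least-squares fit
(lmfit/`leastsq`) in the measured coordinate with unit weights; no
variance weighting is applied.  Convergence: relative RSS change below
1e−12 or parameter step below 1e−10, at most 500 iterations (both
configurable).  Standard errors are asymptotic — inverse curvature scaled
by residual variance — and are reported only for converged fits;
summaries print them to 2 decimals.

**Initialization.**  pKa starts at the pH where the normalized response
crosses one half (linear interpolation); `n` starts at 1 with bounds
[0.1, 3]; limiting intensities start at edge-window plateau means.  These
choices are robust for monotone sigmoids and the objective is
well-behaved near them.

**Plateau fixing.**  The full-ratio and manufacturer models are fitted
with the four limiting intensities *fixed* (free only on request,
`plateau_method="free"`), because the ratio model leaves `pKa` and the
denominator-channel ratio `I2b/I2a` jointly unidentifiable — precisely
the degeneracy behind the apparent-pKa bias.  The default fixing route
(`plateau_method="eq7"`) fits the one-site Hill curve to each channel
separately and takes its limiting values; this extrapolates correctly
even when the titration has not fully plateaued, which matters for
anticooperative data (at n ≈ 0.54 over pH 4.8–11 the raw edge windows sit
17 % away from the true basic limits).  A plain edge-window average
(`plateau_method="edges"`, `estimate_plateaus`) is available for data
with real plateaus; it requires a span of ≥ 3 pH units and ≥ 2 points per
window.

A consequence of conditioning on fixed plateaus is that the reported
standard errors omit plateau uncertainty.  In the recovery experiments
below the ±3 SE interval covers the true pKa in ≈ 99 % of replicates but
the true n in only ≈ 92 %; the package reports asymptotic conditional
SEs and labels them as such.

**End-point refusal.**  Fixed-plateau ratio fits are refused with a
"no titration end-point" diagnostic when the ratio still drifts more than
15 % of its full span (default, configurable) across either pH-extreme
edge window.  On the default anticooperative truth this accepts the R12
orientation (≈ 6 % drift) and refuses R21 (≈ 21 %), whose basic end
diverges without a visible plateau — fitting it would let the
least-squares objective be dominated by an unconstrained region.

**Model comparison.**  `compare_hill` fits the same data with and without
the Hill coefficient and reports both RSS values, the residual series and
the fitted `n ± SE`.  On anticooperative data the no-n model's residuals
form a few long sign-runs (systematic misfit) and its RSS is orders of
magnitude larger at 1 % noise.

## Synthetic data generator

`synth` emulates a scanning spectrofluorometer titration:

* **Spectra**: acidic and basic species profiles are sums of two Gaussian
  bands (centres 586/636 nm; band-1 SD 18 nm ≈ 42 nm FWHM, instrument-
  realistic for these dyes).  The band-2 width is solved from the
  isosbestic constraint — the two species profiles must agree at 620 nm —
  so every noiseless spectrum crosses there by construction (solved
  default ≈ 8 nm SD; if both widths are supplied they are checked for
  consistency and a config error raised otherwise).
* **Two-channel series**: each channel follows the one-site Hill curve
  with the shared true pKa/n.  Finite band width bleeds ≈ 2 % of band 1
  into the 636 nm channel (and ≈ 0.004 % of band 2 into 586 nm); this
  does not change the model *form*, only the effective limiting
  amplitudes, so the truth record carries the effective calibration
  (species profiles evaluated at the band centres) and the series is
  generated from it.  Spectra and series are therefore consistent to
  machine precision and the ground truth handed to recovery tests is the
  correct one.
* **Noise**: additive Gaussian per point, SD = 1 % of the local signal by
  default (absolute mode available).  Non-positive draws are resampled
  once and then floored with a warning (error in strict mode).
* **Defaults as study conditions**: true pKa 8.5, n 0.54, nominal
  amplitudes (I1a, I1b, I2a, I2b) = (100, 20, 30, 120), 25 pH points over
  4.8–11.0 — the broadened in-organello calibration span.  Replicate
  seeds derive from one master seed by unit increments.

What the generator does **not** emulate: photobleaching, inner-filter
effects, scattering by turbid suspensions, pH-independent background
pedestals (a constant-offset blank can be handled via
`subtract_background`), wavelength-dependent detector response, and drift
between replicates.  Passing recovery tests therefore demonstrates the
correctness of the estimation machinery under the stated noise model,
not robustness to every instrumental artifact.

## Numerical choices

* All blends are evaluated through the logistic form of `f(pH)`, finite
  for any pH and overflow-free for pH ∈ [0, 14], n ∈ [0.1, 3].
* The manufacturer model and inverter are implemented from their own
  literal formulas (not by delegating to the full model) so the
  equivalence checks are meaningful.
* Inversion round trips are exact to 1e−10 wherever the float64 ratio
  still resolves pH; once `n·|pH − pKa|` exceeds ≈ 5 the ratio is within
  ~1e−10 of a plateau and cancellation in `I1b − R·I2b` limits attainable
  precision (condition number ≈ 10^{n·|pH−pKa|}).  Property tests
  therefore sample the well-conditioned window and the out-of-range guard
  rejects ratios at or beyond the limits.
* Duplicate pH rows are averaged channelwise on load (with a warning);
  rows are kept sorted by pH.
* The published positivity conditions for the inversion radicand are
  mutually inconsistent as printed; the implemented guard
  `Rb < R < Ra` is the algebraically correct condition (both radicand
  factors share sign inside the open interval).

## Problem sizes

The test suite and recovery experiments use 25-point titrations, 200
replicate simulations for recovery statistics, 100 random calibrations ×
1000-point grids for the algebraic-equivalence checks, and 50-point
noiseless grids for the bias-oracle fits; the full suite runs in a few
seconds on one core.

## Known limitations

* Single protonation site only; no biphasic/multi-site models.
* No temperature or ionic-strength corrections to pKa.
* One instrument gain per dataset is assumed (limiting ratios at
  different gains are not normalized across datasets).
* Calibration-parameter uncertainty is not propagated into pH error
  bars; replicate scatter (mean ± sample SD, n−1) is the reported
  uncertainty.
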