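# snarfcal

Calibration and pH readout for **dual-emission ratiometric fluorescent pH
probes** (carboxy-SNARF-1 and similar dyes), with explicit Hill
cooperativity and a bias-free treatment of the fluorescence ratio.

## The problem

A SNARF-type probe exists in a protonated (HA) and deprotonated (A⁻) form
with distinct emission bands (≈586 nm and ≈636 nm under 488 nm
excitation).  Writing `h = [H+] = 10^-pH`, `Ka = 10^-pKa`, the protonated
molar fraction with Hill cooperativity `n` is

    f(pH) = hⁿ / (Kaⁿ + hⁿ)

and every observable is a blend of acidic/basic limiting values:

    single wavelength:  I(pH)   = Ia·f + Ib·(1−f)
    intensity ratio:    R12(pH) = (I1a·hⁿ + I1b·Kaⁿ) / (I2a·hⁿ + I2b·Kaⁿ)

The common shortcut of fitting the Henderson–Hasselbalch blend
`R = Ra·f + Rb·(1−f)` *directly to the ratio* is systematically biased:
on exact ratio-model data it recovers

    pKa_app = pKa − (1/n)·log10(I2b/I2a)        (R12 orientation)

so the two orientations R12 = I₁/I₂ and R21 = I₂/I₁ bracket the true pKa
from below and above.  snarfcal implements the full equation family, the
closed-form bias above (as a verifiable oracle), the corrected inversion

    pH = pKa − (1/n)·log10[(I1b − R·I2b) / (R·I2a − I1a)]

valid for R strictly between the limiting ratios Rb = I1b/I2b and
Ra = I1a/I2a, and an exact *Hill-shift identity* relating inversions at
different cooperativity: `pH(n) = pKa + (pH(1) − pKa)/n`.

This matters in small compartments (e.g. the mitochondrial matrix), where
in-organello calibrations show strong anticooperativity (n ≈ 0.54 versus
n ≈ 1 in bulk buffer); ignoring it inflates reported pH by ~0.5 unit.

## What is in the package

| module                | contents |
|-----------------------|----------|
| `snarfcal.models`     | pure evaluators/inverters for every model, species fractions, closed-form apparent-pKa bias |
| `snarfcal.io_spectra` | delimited-text titration tables & spectra matrices, channel extraction, background subtraction, ratio formation, JSON calibration files |
| `snarfcal.fitting`    | `TitrationCalibrator` (scikit-learn-style estimator over lmfit), plateau fixing, Hill-vs-no-Hill comparison, replicate aggregation, fit plots |
| `snarfcal.ph_measure` | ratio → pH measurements and replicate summaries (mean ± sample SD) |
| `snarfcal.synth`      | synthetic spectra/titrations with enforced isosbestic point, known truth, recovery experiments |
| `snarfcal.cli`        | `snarfcal simulate / calibrate / measure / recover` |

Calibration files are JSON objects with keys `pka`, `n`, `i1a`, `i1b`,
`i2a`, `i2b`, `lambda1_nm`, `lambda2_nm`, `method_tag`; all floats are
written at full round-trip precision.

## Worked example

Simulate an in-organello-style titration (true pKa 8.5, n 0.54, 25 points
over pH 4.8–11, 1 % proportional noise), then calibrate with and without
the Hill coefficient:

```sh
$ snarfcal simulate -o . --seed 1 --noise-sd 0.01
$ snarfcal calibrate titration_seed1.csv -m eq9
model eq9  converged=True  rss=0.0100903
  ...
  pka = 8.52 +/- 0.01
  n = 0.53 +/- 0.00
$ snarfcal calibrate titration_seed1.csv -m eq12
model eq12  converged=True  rss=1.78568
  ...
  pka = 7.99 +/- 0.07
  n = 1.00 (fixed)
```

The Hill fit recovers the truth; the manufacturer-manual model (`eq12`,
no cooperativity) misfits by ~180× in residual sum of squares and drags
the apparent pKa half a unit low — exactly the bias the corrected
algorithm removes.

Measuring three replicate ratios with a stored Hill calibration
(pKa 8.51, n 0.54):

```sh
$ snarfcal measure --calibration cal.json 2.0171 2.0873 1.5469
method=hill  pKa=8.51  n=0.54
replicate   ratio    pH
1           2.0171   7.12
2           2.0873   7.05
3           1.5469   7.60
Average              7.26 +/- 0.30
```

The same ratios inverted with n = 1 read 7.76/7.72/8.02 (average
7.83 ± 0.16): the anticooperativity correction lowers the answer by about
0.5 pH unit.

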