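"""Equation family for dual-emission ratiometric pH probes.

A ratiometric probe such as carboxy-SNARF-1 exists in a protonated (HA,
"acidic") and a deprotonated (A-, "basic") form with distinct emission
bands (maxima near 586 and 636 nm).  Writing ``h = [H+] = 10**-pH`` and
``Ka = 10**-pKa``, the protonated molar fraction with empirical Hill
cooperativity ``n`` is

    f_HA(pH) = h**n / (Ka**n + h**n) = 1 / (1 + 10**(n*(pH - pKa)))

Every observable in this module is a linear blend of an acidic and a basic
limiting value weighted by ``f_HA``:

* single-wavelength intensity        I(pH)  = Ia*f + Ib*(1-f)
* intensity ratio ("full" model)     R12(pH) = (I1a*f + I1b*(1-f)) /
                                               (I2a*f + I2b*(1-f))
* Henderson-Hasselbalch ratio model  R(pH)  = Ra*f + Rb*(1-f)

The Henderson-Hasselbalch form applied directly to a ratio is *biased*:
noiseless full-model data refit with the ratio-blend model returns an
apparent pKa shifted by -(1/n)*log10 of the denominator-channel limiting
intensity ratio (``apparent_pka_shift``).  The manufacturer's manual model
(with its F-factor correction) is algebraically identical to the full
model at n = 1.

Inversion of the full ratio model gives the pH behind a measured ratio:

    pH = pKa - (1/n) * log10( (I1b - R*I2b) / (R*I2a - I1a) )    (R = R12)

valid exactly for R strictly between the limiting ratios Rb and Ra.

All evaluators are pure, stateless, and accept scalars or numpy arrays of
pH / ratio values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

from ._exceptions import RatioRangeError, ValidationError

Orientation = Literal["R12", "R21"]

__all__ = [
    "Orientation",
    "CalibrationParameters",
    "SpeciesState",
    "protonated_fraction",
    "species_fraction",
    "eval_hh_ratio",
    "eval_one_site",
    "eval_ratio_full",
    "eval_manufacturer_ratio",
    "invert_ratio_to_ph",
    "invert_manufacturer",
    "apparent_pka_shift",
]


def _check_orientation(orientation: str) -> None:
    if orientation not in ("R12", "R21"):
        raise ValidationError(f"orientation must be 'R12' or 'R21', got {orientation!r}")


@dataclass(frozen=True)
class CalibrationParameters:
    """Full parameter set of a two-channel probe calibration.

    Parameters
    ----------
    pka : acid dissociation exponent of the probe's phenolic group
        (Ka = 10**-pka, molar).
    n : Hill cooperativity coefficient (n < 1: anticooperative).
    i1a, i1b : limiting fluorescence intensities at lambda1 in fully
        acidic / fully basic conditions (arbitrary units, > 0).
    i2a, i2b : limiting intensities at lambda2.
    lambda1_nm, lambda2_nm : emission wavelengths of the two channels.
    method_tag : identifier of the model that produced the parameters
        (e.g. ``"eq9"``); free text.

    The manufacturer-manual F-symbols map onto the limiting intensities as
    F1a = i1a, F1b = i1b, F2a = i2a, F2b = i2b.
    """

    pka: float
    n: float = 1.0
    i1a: float = 1.0
    i1b: float = 1.0
    i2a: float = 1.0
    i2b: float = 1.0
    lambda1_nm: float = 586.0
    lambda2_nm: float = 636.0
    method_tag: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.pka):
            raise ValidationError("pKa must be finite")
        if not (self.n > 0):
            raise ValidationError(f"Hill coefficient must be > 0, got {self.n}")
        for name in ("i1a", "i1b", "i2a", "i2b"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValidationError(f"limiting intensity {name} must be > 0, got {v}")
        if self.i1a == self.i1b:
            raise ValidationError("degenerate response: i1a == i1b")
        if self.i2a == self.i2b:
            raise ValidationError("degenerate response: i2a == i2b")
        if self.ra == self.rb:
            raise ValidationError("degenerate calibration: Ra == Rb")

    @property
    def ra(self) -> float:
        """Acidic limiting ratio of R12 (= i1a / i2a)."""
        return self.i1a / self.i2a

    @property
    def rb(self) -> float:
        """Basic limiting ratio of R12 (= i1b / i2b)."""
        return self.i1b / self.i2b

    def ratio_limits(self, orientation: Orientation = "R12") -> tuple[float, float]:
        """(acidic, basic) limiting ratio for the requested orientation."""
        _check_orientation(orientation)
        if orientation == "R12":
            return self.ra, self.rb
        return 1.0 / self.ra, 1.0 / self.rb

    def with_(self, **changes) -> "CalibrationParameters":
        """Copy with selected fields replaced (validation re-run)."""
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return {
            "pka": self.pka,
            "n": self.n,
            "i1a": self.i1a,
            "i1b": self.i1b,
            "i2a": self.i2a,
            "i2b": self.i2b,
            "lambda1_nm": self.lambda1_nm,
            "lambda2_nm": self.lambda2_nm,
            "method_tag": self.method_tag,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationParameters":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__ if k in d})


@dataclass(frozen=True)
class SpeciesState:
    """Molar fractions of the protonated (HA) and deprotonated (A-) probe."""

    fraction_ha: float
    fraction_a: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.fraction_a is None:
            object.__setattr__(self, "fraction_a", 1.0 - self.fraction_ha)
        if not (0.0 <= self.fraction_ha <= 1.0):
            raise ValidationError("fraction_ha must lie in [0, 1]")
        if abs(self.fraction_ha + self.fraction_a - 1.0) > 1e-12:
            raise ValidationError("species fractions must sum to 1")


def protonated_fraction(ph, pka: float, n: float = 1.0):
    """Protonated molar fraction f_HA = h^n / (Ka^n + h^n).

    Evaluated in the numerically stable logistic form
    ``1 / (1 + 10**(n*(pH - pKa)))``, finite for any pH.
    """
    if not n > 0:
        raise ValidationError(f"Hill coefficient must be > 0, got {n}")
    ph = np.asarray(ph, dtype=float)
    with np.errstate(over="ignore"):
        f = 1.0 / (1.0 + np.power(10.0, n * (ph - pka)))
    return f if f.ndim else float(f)


def species_fraction(ph: float, pka: float, n: float = 1.0) -> SpeciesState:
    """Species fractions of the protonation equilibrium HA <-> A- + H+."""
    f = protonated_fraction(ph, pka, n)
    return SpeciesState(fraction_ha=float(f))


def eval_hh_ratio(ph, ra: float, rb: float, pka: float, n: float = 1.0):
    """Henderson-Hasselbalch blend applied directly to the ratio.

    R(pH) = Ra*h^n/(Ka^n + h^n) + Rb*Ka^n/(Ka^n + h^n).  This is the
    classical (biased) ratio calibration model; with n a free exponent it
    is its Hill extension.
    """
    f = protonated_fraction(ph, pka, n)
    return ra * f + rb * (1.0 - f)


def eval_one_site(ph, ia: float, ib: float, pka: float, n: float = 1.0):
    """One-site binding curve for a single-wavelength intensity.

    I(pH) = Ia*h^n/(Ka^n + h^n) + Ib*Ka^n/(Ka^n + h^n); strictly monotone
    in pH when Ia != Ib.
    """
    f = protonated_fraction(ph, pka, n)
    return ia * f + ib * (1.0 - f)


def eval_ratio_full(ph, cal: CalibrationParameters, orientation: Orientation = "R12"):
    """Exact ratio model built from the four limiting channel intensities.

    R12(pH) = (I1a*h^n + I1b*Ka^n) / (I2a*h^n + I2b*Ka^n); R21 is its
    pointwise reciprocal.  Limits: Ra = I1a/I2a (acidic), Rb = I1b/I2b
    (basic) for R12.
    """
    _check_orientation(orientation)
    f = protonated_fraction(ph, cal.pka, cal.n)
    num = cal.i1a * f + cal.i1b * (1.0 - f)
    den = cal.i2a * f + cal.i2b * (1.0 - f)
    r12 = num / den
    return r12 if orientation == "R12" else 1.0 / r12


def eval_manufacturer_ratio(ph, cal: CalibrationParameters, orientation: Orientation = "R12"):
    """Probe manual's ratio model with the F-factor correction (n == 1).

    R12(pH) = ([H+]*Ra*F2a + Ka*Rb*F2b) / (Ka*F2b + [H+]*F2a) with
    F2a = i2a, F2b = i2b (and the F1-analogue for R21).  Algebraically
    identical to :func:`eval_ratio_full` at n = 1; the Hill coefficient in
    ``cal`` is ignored.
    """
    _check_orientation(orientation)
    ph = np.asarray(ph, dtype=float)
    h = np.power(10.0, -ph)
    ka = 10.0 ** (-cal.pka)
    if orientation == "R12":
        ra, rb = cal.ra, cal.rb
        fa, fb = cal.i2a, cal.i2b
    else:
        ra, rb = 1.0 / cal.ra, 1.0 / cal.rb
        fa, fb = cal.i1a, cal.i1b
    r = (h * ra * fa + ka * rb * fb) / (ka * fb + h * fa)
    return r if r.ndim else float(r)


def _check_ratio_range(r, cal: CalibrationParameters, orientation: Orientation) -> None:
    r_acid, r_basic = cal.ratio_limits(orientation)
    lo, hi = min(r_acid, r_basic), max(r_acid, r_basic)
    flat = np.atleast_1d(np.asarray(r, dtype=float))
    out = (flat <= lo) | (flat >= hi)
    if np.any(out):
        bad = float(flat[np.argmax(out)])
        limit = lo if bad <= lo else hi
        which = "acidic" if limit == r_acid else "basic"
        raise RatioRangeError(
            f"ratio {bad:g} outside the open calibration interval "
            f"({lo:g}, {hi:g}) for {orientation}: violates the {which} "
            f"limit {limit:g}"
        )


def invert_ratio_to_ph(r, cal: CalibrationParameters, orientation: Orientation = "R12"):
    """pH behind a measured ratio, inverse of :func:`eval_ratio_full`.

    For R12:  pH = pKa - (1/n) * log10( (I1b - R*I2b) / (R*I2a - I1a) );
    the R21 inversion swaps the channel roles.  Valid for ratios strictly
    inside the open interval between the limiting ratios; both radicand
    factors then share sign, so the argument of the logarithm is positive.
    """
    _check_orientation(orientation)
    _check_ratio_range(r, cal, orientation)
    r = np.asarray(r, dtype=float)
    if orientation == "R12":
        x = (cal.i1b - r * cal.i2b) / (r * cal.i2a - cal.i1a)
    else:
        x = (cal.i2b - r * cal.i1b) / (r * cal.i1a - cal.i2a)
    if np.any(x <= 0):  # unreachable once the range check passes
        raise RatioRangeError("radicand is non-positive; ratio outside valid range")
    ph = cal.pka - np.log10(x) / cal.n
    return ph if ph.ndim else float(ph)


def invert_manufacturer(r, cal: CalibrationParameters, orientation: Orientation = "R12"):
    """pH from the probe manual's inversion with the F-factor correction.

    For R12:  [H+] = Ka * (R - Rb)/(Ra - R) * F2b/F2a, i.e.
    pH = pKa - log10((R - Rb)/(Ra - R) * i2b/i2a).  Identical to
    :func:`invert_ratio_to_ph` with n = 1.
    """
    _check_orientation(orientation)
    _check_ratio_range(r, cal, orientation)
    r = np.asarray(r, dtype=float)
    r_acid, r_basic = cal.ratio_limits(orientation)
    factor = (cal.i2b / cal.i2a) if orientation == "R12" else (cal.i1b / cal.i1a)
    x = (r - r_basic) / (r_acid - r) * factor
    ph = cal.pka - np.log10(x)
    return ph if ph.ndim else float(ph)


def apparent_pka_shift(cal: CalibrationParameters, orientation: Orientation = "R12") -> float:
    """Apparent pKa recovered by a Henderson-Hasselbalch ratio fit.

    Noiseless full-model (four-intensity) ratio data refit with the
    ratio-blend model at the same n returns a pKa shifted by the
    denominator channel's limiting-intensity ratio:

        R12:  pKa_app = pKa - (1/n) * log10(i2b / i2a)
        R21:  pKa_app = pKa - (1/n) * log10(i1b / i1a)

    The identity is exact: dividing numerator and denominator of the full
    ratio model by the denominator channel's acidic intensity rewrites it
    as a Henderson-Hasselbalch blend with Ka'^n = Ka^n * (i_den,b/i_den,a).
    Returns the apparent pKa; the shift itself is ``apparent - cal.pka``.
    """
    _check_orientation(orientation)
    if orientation == "R12":
        return cal.pka - math.log10(cal.i2b / cal.i2a) / cal.n
    return cal.pka - math.log10(cal.i1b / cal.i1a) / cal.n
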