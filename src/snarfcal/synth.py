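"""Synthetic titrations with known ground truth.

The generator emulates the phenomenology of a dual-emission ratiometric
pH probe measured on a scanning spectrofluorometer:

* two Gaussian emission bands (defaults: 586 nm falling and 636 nm rising
  with pH) riding on a one-site protonation curve with adjustable Hill
  coefficient;
* an isosbestic point (default 620 nm) enforced by construction — the
  acidic- and basic-species spectral profiles are made to agree there, so
  every noiseless spectrum crosses at that wavelength;
* additive Gaussian instrument noise, by default proportional to signal.

Because each band has finite width, a little of band 1 bleeds into the
636 nm channel and vice versa.  The bleed does not change the *form* of
the two-channel model — each channel remains a one-site Hill curve and
the ratio remains the four-intensity ratio model — it only shifts the
effective limiting intensities.  The ground-truth record therefore
reports the *effective* channel amplitudes (species profiles evaluated at
the band centres) alongside the nominal ones, and the two-channel series
is generated from the effective values so that spectra and series are
mutually consistent to machine precision.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from ._exceptions import ConfigError, ValidationError
from .fitting import FitSpec, fit_calibration
from .io_spectra import EmissionSpectrum, RatioSeries, TitrationDataset, compute_ratio_series
from .models import CalibrationParameters, Orientation, protonated_fraction

__all__ = [
    "SyntheticConfig",
    "SimulationTruth",
    "RecoveryReport",
    "simulate_ratio_series",
    "simulate_spectra",
    "recovery_experiment",
]

#: pH grid of the in-organello calibration protocol: 25 points, 4.8-11.0.
DEFAULT_PH_GRID = tuple(np.round(np.linspace(4.8, 11.0, 25), 6))


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground truth and instrument model for one synthetic titration.

    ``amplitudes`` are the nominal limiting band amplitudes
    (i1a, i1b, i2a, i2b).  ``band2_width`` may be left ``None``; it is
    then solved from the isosbestic constraint (see
    :func:`solve_band2_width`).  ``noise_sd`` is interpreted as a
    fraction of the local signal in ``"proportional"`` mode or in
    intensity units in ``"absolute"`` mode.
    """

    pka_true: float = 8.5
    n_true: float = 0.54
    amplitudes: tuple[float, float, float, float] = (100.0, 20.0, 30.0, 120.0)
    band1_center: float = 586.0
    band2_center: float = 636.0
    band1_width: float = 18.0
    band2_width: float | None = None
    isosbestic_nm: float = 620.0
    wavelength_grid: tuple[float, ...] = field(
        default_factory=lambda: tuple(np.arange(520.0, 721.0, 1.0))
    )
    ph_grid: tuple[float, ...] = DEFAULT_PH_GRID
    noise_sd: float = 0.01
    noise_mode: str = "proportional"
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.noise_mode not in ("proportional", "absolute"):
            raise ConfigError(f"unknown noise_mode {self.noise_mode!r}")
        if any(a <= 0 for a in self.amplitudes):
            raise ConfigError("band amplitudes must be > 0")
        if not self.n_true > 0:
            raise ConfigError("Hill coefficient must be > 0")
        if len(self.ph_grid) >= 2 and (max(self.ph_grid) - min(self.ph_grid)) < 2.0:
            raise ConfigError("ph_grid must span >= 2 pH units for calibration use")


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters plus the effective two-channel calibration."""

    config: SyntheticConfig
    calibration: CalibrationParameters  # effective (bleed-corrected) amplitudes
    band2_width: float
    #: fraction of each channel's acidic-limit signal contributed by the
    #: other band (reported so the overlap is auditable)
    bleed_into_channel1: float
    bleed_into_channel2: float


def _gauss(wl, center: float, width: float):
    wl = np.asarray(wl, dtype=float)
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def solve_band2_width(config: SyntheticConfig) -> float:
    """Band-2 width enforcing a common crossing at the isosbestic point.

    The acidic and basic species profiles agree at the isosbestic
    wavelength iff ``(i1a - i1b) * g1 = (i2b - i2a) * g2`` where ``g1``
    and ``g2`` are the unit-peak band shapes evaluated there.  Given
    ``band1_width`` this fixes ``g2``; a solution exists only when the
    implied ``g2`` lies in (0, 1).
    """
    i1a, i1b, i2a, i2b = config.amplitudes
    if (i1a - i1b) * (i2b - i2a) <= 0:
        raise ConfigError(
            "no isosbestic crossing: channel amplitudes must move in opposite "
            "directions with pH (i1a > i1b and i2b > i2a, or both reversed)"
        )
    g1 = float(_gauss(config.isosbestic_nm, config.band1_center, config.band1_width))
    g2 = (i1a - i1b) * g1 / (i2b - i2a)
    if not (0.0 < g2 < 1.0):
        raise ConfigError(
            f"no isosbestic crossing for band1_width={config.band1_width}: "
            f"required band-2 shape value {g2:.3g} at {config.isosbestic_nm} nm "
            "is not attainable by a unit-peak Gaussian"
        )
    return abs(config.isosbestic_nm - config.band2_center) / math.sqrt(-2.0 * math.log(g2))


def _species_profiles(config: SyntheticConfig):
    """Return (band2_width, S_acid(wl), S_basic(wl)) on the wavelength grid."""
    w2 = config.band2_width if config.band2_width is not None else solve_band2_width(config)
    i1a, i1b, i2a, i2b = config.amplitudes
    wl = np.asarray(config.wavelength_grid, dtype=float)
    g1 = _gauss(wl, config.band1_center, config.band1_width)
    g2 = _gauss(wl, config.band2_center, w2)
    s_acid = i1a * g1 + i2a * g2
    s_basic = i1b * g1 + i2b * g2
    iso = float(config.isosbestic_nm)
    sa = i1a * float(_gauss(iso, config.band1_center, config.band1_width)) + i2a * float(
        _gauss(iso, config.band2_center, w2)
    )
    sb = i1b * float(_gauss(iso, config.band1_center, config.band1_width)) + i2b * float(
        _gauss(iso, config.band2_center, w2)
    )
    if abs(sa - sb) > 1e-9 * max(abs(sa), abs(sb), 1.0):
        raise ConfigError(
            f"band parameters admit no common crossing at {iso} nm "
            f"(acidic profile {sa:.6g} vs basic {sb:.6g}); leave band2_width "
            "unset to have it solved from the isosbestic constraint"
        )
    return w2, s_acid, s_basic


def simulation_truth(config: SyntheticConfig) -> SimulationTruth:
    """Effective two-channel calibration implied by the band model."""
    w2, _, _ = _species_profiles(config)
    i1a, i1b, i2a, i2b = config.amplitudes
    c1, c2 = config.band1_center, config.band2_center
    g1_at_2 = float(_gauss(c2, c1, config.band1_width))  # band1 bleed at channel 2
    g2_at_1 = float(_gauss(c1, c2, w2))  # band2 bleed at channel 1
    eff = CalibrationParameters(
        pka=config.pka_true,
        n=config.n_true,
        i1a=i1a + i2a * g2_at_1,
        i1b=i1b + i2b * g2_at_1,
        i2a=i2a + i1a * g1_at_2,
        i2b=i2b + i1b * g1_at_2,
        lambda1_nm=c1,
        lambda2_nm=c2,
        method_tag="truth",
    )
    return SimulationTruth(
        config=config,
        calibration=eff,
        band2_width=w2,
        bleed_into_channel1=i2a * g2_at_1 / (i1a + i2a * g2_at_1),
        bleed_into_channel2=i1a * g1_at_2 / (i2a + i1a * g1_at_2),
    )


def _add_noise(rng: np.random.Generator, signal: np.ndarray, config: SyntheticConfig) -> np.ndarray:
    if config.noise_sd == 0:
        return signal.copy()
    sd = config.noise_sd * signal if config.noise_mode == "proportional" else config.noise_sd
    noisy = signal + rng.normal(0.0, 1.0, size=signal.shape) * sd
    bad = noisy <= 0
    if np.any(bad) and config.strict:
        raise ConfigError(
            "noise produced non-positive intensities (strict mode); "
            "reduce noise_sd or disable strict"
        )
    if np.any(bad):  # one resample, then floor what remains
        redraw = signal[bad] + rng.normal(0.0, 1.0, size=int(bad.sum())) * (
            sd[bad] if np.ndim(sd) else sd
        )
        noisy[bad] = redraw
        bad = noisy <= 0
        if np.any(bad):
            warnings.warn(
                "non-positive noisy intensities floored", UserWarning, stacklevel=2
            )
            noisy[bad] = 1e-6 * float(np.max(signal))
    return noisy


def simulate_ratio_series(
    config: SyntheticConfig, orientation: Orientation = "R12"
) -> tuple[TitrationDataset, RatioSeries, SimulationTruth]:
    """Two-channel titration series + ratio series + ground-truth record.

    Channel intensities follow the one-site Hill curve with the shared
    true pKa and n and the *effective* limiting amplitudes of the band
    model; with ``noise_sd = 0`` the ratio series equals the four-
    intensity ratio model of the truth calibration exactly.
    """
    truth = simulation_truth(config)
    cal = truth.calibration
    ph = np.asarray(config.ph_grid, dtype=float)
    f = protonated_fraction(ph, config.pka_true, config.n_true)
    clean1 = cal.i1a * f + cal.i1b * (1.0 - f)
    clean2 = cal.i2a * f + cal.i2b * (1.0 - f)
    rng = np.random.default_rng(config.seed)
    i1 = _add_noise(rng, clean1, config)
    i2 = _add_noise(rng, clean2, config)
    dataset = TitrationDataset(
        ph=ph,
        i1=i1,
        i2=i2,
        lambda1_nm=config.band1_center,
        lambda2_nm=config.band2_center,
        replicate_id=f"synthetic-seed{config.seed}",
    )
    return dataset, compute_ratio_series(dataset, orientation), truth


def simulate_spectra(config: SyntheticConfig) -> list[EmissionSpectrum]:
    """Full emission spectra, one per grid pH.

    Each spectrum is the protonated-fraction-weighted blend of the acidic
    and basic species profiles; all noiseless spectra agree at the
    isosbestic wavelength by construction.  Noise is drawn per grid point
    with the configured model.
    """
    w2, s_acid, s_basic = _species_profiles(config)
    del w2
    rng = np.random.default_rng(config.seed)
    spectra = []
    for ph in config.ph_grid:
        f = float(protonated_fraction(ph, config.pka_true, config.n_true))
        clean = f * s_acid + (1.0 - f) * s_basic
        spectra.append(
            EmissionSpectrum(
                wavelength_nm=np.asarray(config.wavelength_grid, dtype=float),
                intensity=_add_noise(rng, clean, config),
                ph_label=float(ph),
            )
        )
    return spectra


@dataclass(frozen=True)
class RecoveryReport:
    """Parameter-recovery statistics across seeded replicate simulations."""

    model_id: str
    n_replicates: int
    n_failed: int
    truth: dict[str, float]
    mean: dict[str, float]
    bias: dict[str, float]
    sd: dict[str, float]
    median_abs_error: dict[str, float]
    coverage_3se: dict[str, float]
    mean_rss: float


def recovery_experiment(
    config: SyntheticConfig,
    fit_spec: FitSpec | None = None,
    n_replicates: int = 200,
    parameters: Sequence[str] = ("pka", "n"),
) -> RecoveryReport:
    """Repeat simulate-and-fit over derived seeds and summarize recovery.

    Replicate ``i`` uses seed ``config.seed + i``.  For each monitored
    parameter the report gives bias, spread, median absolute error and
    the coverage of +/- 3 standard-error intervals.
    """
    if n_replicates < 2:
        raise ValidationError("n_replicates must be >= 2")
    spec = fit_spec or FitSpec(model_id="eq9")
    truth_map = {"pka": config.pka_true, "n": config.n_true}
    estimates: dict[str, list[float]] = {p: [] for p in parameters}
    covered: dict[str, list[bool]] = {p: [] for p in parameters}
    rss_values: list[float] = []
    n_failed = 0
    orientation = {"eq10": "R21", "eq14": "R21"}.get(spec.model_id, "R12")
    for i in range(n_replicates):
        cfg = replace(config, seed=config.seed + i)
        dataset, _series, _ = simulate_ratio_series(cfg, orientation)
        try:
            result = fit_calibration(dataset, spec)
        except Exception:
            n_failed += 1
            continue
        if not result.converged:
            n_failed += 1
            continue
        rss_values.append(result.rss)
        for p in parameters:
            if p not in result.estimates:
                continue
            est = result.estimates[p]
            estimates[p].append(est)
            se = (result.stderr or {}).get(p)
            if se and p in truth_map:
                covered[p].append(abs(est - truth_map[p]) <= 3 * se)
    report_params = [p for p in parameters if estimates[p]]
    mean = {p: float(np.mean(estimates[p])) for p in report_params}
    return RecoveryReport(
        model_id=spec.model_id,
        n_replicates=n_replicates,
        n_failed=n_failed,
        truth={p: truth_map[p] for p in report_params if p in truth_map},
        mean=mean,
        bias={p: mean[p] - truth_map[p] for p in report_params if p in truth_map},
        sd={p: float(np.std(estimates[p], ddof=1)) for p in report_params},
        median_abs_error={
            p: float(np.median(np.abs(np.array(estimates[p]) - truth_map[p])))
            for p in report_params
            if p in truth_map
        },
        coverage_3se={
            p: float(np.mean(covered[p])) for p in report_params if covered[p]
        },
        mean_rss=float(np.mean(rss_values)) if rss_values else math.nan,
    )
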