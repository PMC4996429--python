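"""Reading, writing and reduction of titration data.

Two delimited-text layouts are supported (comma or tab, auto-detected,
header row required, decimal point only):

* ``two_channel`` — one row per titration point::

      pH,I_586,I_636
      6.35,102.1,18.4

  The channel columns may be named ``I_<wavelength>`` (the wavelength is
  picked up as metadata) or anything else (defaults 586/636 nm apply).

* ``spectra_matrix`` — a wavelength column followed by one intensity
  column per pH::

      wavelength_nm,pH_4.82,pH_6.30,...
      520,1.03,0.98,...

Calibration parameters and pH result tables are serialized as JSON; all
floats are written with full round-trip precision (>= 10 significant
digits).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from ._exceptions import ParseError, ValidationError
from .models import CalibrationParameters, Orientation

__all__ = [
    "EmissionSpectrum",
    "TitrationDataset",
    "RatioSeries",
    "read_titration_table",
    "write_titration_table",
    "extract_channel_intensities",
    "subtract_background",
    "compute_ratio_series",
    "save_calibration",
    "load_calibration",
]

MIN_POINTS_FOR_FIT = 5


@dataclass(frozen=True)
class EmissionSpectrum:
    """A single emission scan at one buffer pH.

    ``wavelength_nm`` must be strictly increasing and the same length
    (>= 2) as ``intensity``; all values must be finite.
    """

    wavelength_nm: np.ndarray
    intensity: np.ndarray
    ph_label: float
    excitation_nm: float = 488.0

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        it = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "intensity", it)
        if wl.ndim != 1 or wl.size < 2 or it.shape != wl.shape:
            raise ValidationError(
                "wavelength grid and intensities must be 1-D, equal length >= 2"
            )
        if not np.all(np.isfinite(wl)) or not np.all(np.isfinite(it)):
            raise ValidationError("spectrum contains non-finite values")
        if not np.all(np.diff(wl) > 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if not math.isfinite(self.ph_label):
            raise ValidationError("ph_label must be finite")

    def intensity_at(self, wavelength: float, band_halfwidth: float = 0.0) -> float:
        """Intensity at a target wavelength.

        With ``band_halfwidth == 0`` the nearest grid point is returned;
        otherwise the mean over grid points within +/- band_halfwidth.
        """
        wl = self.wavelength_nm
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise ValidationError(
                f"wavelength {wavelength} nm outside grid [{wl[0]}, {wl[-1]}]"
            )
        if band_halfwidth <= 0:
            return float(self.intensity[int(np.argmin(np.abs(wl - wavelength)))])
        mask = np.abs(wl - wavelength) <= band_halfwidth
        return float(self.intensity[mask].mean())


@dataclass(frozen=True)
class TitrationDataset:
    """Paired (pH, I_lambda1, I_lambda2) observations for one run.

    Intensities must be positive (post background subtraction); duplicate
    pH values are averaged channelwise on construction with a warning.
    Rows are kept sorted by pH ascending.
    """

    ph: np.ndarray
    i1: np.ndarray
    i2: np.ndarray
    lambda1_nm: float = 586.0
    lambda2_nm: float = 636.0
    replicate_id: str = ""

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        i1 = np.asarray(self.i1, dtype=float)
        i2 = np.asarray(self.i2, dtype=float)
        if not (ph.shape == i1.shape == i2.shape) or ph.ndim != 1:
            raise ValidationError("ph, i1, i2 must be 1-D arrays of equal length")
        if not np.all(np.isfinite(ph)):
            raise ValidationError("pH values must be finite")
        if not np.all(np.isfinite(i1)) or not np.all(np.isfinite(i2)):
            raise ValidationError("intensities must be finite")
        if np.any(i1 <= 0) or np.any(i2 <= 0):
            bad = ph[(i1 <= 0) | (i2 <= 0)]
            raise ValidationError(
                f"non-positive intensity after background subtraction at pH {bad.tolist()}"
            )
        if np.unique(ph).size != ph.size:
            warnings.warn(
                "duplicate pH values averaged channelwise", UserWarning, stacklevel=2
            )
            uniq, inv = np.unique(ph, return_inverse=True)
            i1 = np.bincount(inv, weights=i1) / np.bincount(inv)
            i2 = np.bincount(inv, weights=i2) / np.bincount(inv)
            ph = uniq
        order = np.argsort(ph, kind="stable")
        object.__setattr__(self, "ph", ph[order])
        object.__setattr__(self, "i1", i1[order])
        object.__setattr__(self, "i2", i2[order])

    def __len__(self) -> int:
        return self.ph.size

    @property
    def ph_span(self) -> float:
        return float(self.ph[-1] - self.ph[0])


@dataclass(frozen=True)
class RatioSeries:
    """Fluorescence-intensity ratio versus pH in a fixed orientation."""

    ph: np.ndarray
    ratio: np.ndarray
    orientation: Orientation = "R12"
    source: TitrationDataset | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        ph = np.asarray(self.ph, dtype=float)
        ratio = np.asarray(self.ratio, dtype=float)
        if ph.shape != ratio.shape or ph.ndim != 1:
            raise ValidationError("ph and ratio must be 1-D arrays of equal length")
        if np.any(ratio <= 0) or not np.all(np.isfinite(ratio)):
            raise ValidationError("ratios must be positive and finite")
        if self.orientation not in ("R12", "R21"):
            raise ValidationError(f"invalid orientation {self.orientation!r}")
        object.__setattr__(self, "ph", ph)
        object.__setattr__(self, "ratio", ratio)

    def __len__(self) -> int:
        return self.ph.size


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:  # pandas raises several parser subclasses
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: expected at least 2 delimited columns")
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            line = int(np.argmax(coerced.isna().to_numpy())) + 2  # 1-based + header
            raise ParseError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
        df[col] = coerced.astype(float)
    return df


def _channel_wavelength(name: str, default: float) -> float:
    digits = "".join(c for c in str(name) if c.isdigit() or c == ".")
    try:
        return float(digits)
    except ValueError:
        return default


def read_titration_table(
    path: str | Path,
    format: Literal["two_channel", "spectra_matrix"] = "two_channel",
    replicate_id: str = "",
):
    """Parse a delimited titration table.

    ``two_channel`` returns a :class:`TitrationDataset`; ``spectra_matrix``
    returns one :class:`EmissionSpectrum` per pH-labelled column.
    """
    df = _read_delimited(path)
    if format == "two_channel":
        if df.shape[1] != 3:
            raise ParseError(
                f"{path}: two_channel format needs exactly 3 columns (pH, ch1, ch2), "
                f"found {df.shape[1]}"
            )
        ph_col, c1, c2 = df.columns
        if "ph" not in str(ph_col).lower():
            raise ParseError(f"{path}: first column header must name pH, got {ph_col!r}")
        return TitrationDataset(
            ph=df[ph_col].to_numpy(),
            i1=df[c1].to_numpy(),
            i2=df[c2].to_numpy(),
            lambda1_nm=_channel_wavelength(c1, 586.0),
            lambda2_nm=_channel_wavelength(c2, 636.0),
            replicate_id=replicate_id or Path(path).stem,
        )
    if format == "spectra_matrix":
        wl = df.iloc[:, 0].to_numpy()
        spectra = []
        for col in df.columns[1:]:
            ph_label = _channel_wavelength(col, math.nan)
            if not math.isfinite(ph_label):
                raise ParseError(f"{path}: cannot read a pH value from header {col!r}")
            spectra.append(
                EmissionSpectrum(wavelength_nm=wl, intensity=df[col].to_numpy(), ph_label=ph_label)
            )
        return spectra
    raise ValidationError(f"unknown format {format!r}")


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest round-trip decimal representation


def write_titration_table(dataset: TitrationDataset, path: str | Path, delimiter: str = ",") -> None:
    """Write a dataset in the two_channel layout (bit-exact round trip)."""
    lines = [
        delimiter.join(
            ["pH", f"I_{dataset.lambda1_nm:g}", f"I_{dataset.lambda2_nm:g}"]
        )
    ]
    for ph, a, b in zip(dataset.ph, dataset.i1, dataset.i2):
        lines.append(delimiter.join([_fmt(ph), _fmt(a), _fmt(b)]))
    Path(path).write_text("\n".join(lines) + "\n")


def extract_channel_intensities(
    spectra: Sequence[EmissionSpectrum],
    lambda1: float = 586.0,
    lambda2: float = 636.0,
    band_halfwidth: float = 0.0,
    replicate_id: str = "",
) -> TitrationDataset:
    """Reduce full spectra to a two-channel dataset, ordered by pH."""
    if not spectra:
        raise ValidationError("no spectra supplied")
    rows = sorted(spectra, key=lambda s: s.ph_label)
    return TitrationDataset(
        ph=np.array([s.ph_label for s in rows]),
        i1=np.array([s.intensity_at(lambda1, band_halfwidth) for s in rows]),
        i2=np.array([s.intensity_at(lambda2, band_halfwidth) for s in rows]),
        lambda1_nm=lambda1,
        lambda2_nm=lambda2,
        replicate_id=replicate_id,
    )


def subtract_background(
    dataset: TitrationDataset,
    background: TitrationDataset | tuple[float, float],
) -> TitrationDataset:
    """Channelwise background subtraction.

    ``background`` is either a constant (b1, b2) pair applied uniformly or
    a blank titration whose pH grid matches the dataset.  The result must
    stay strictly positive at every point.
    """
    if isinstance(background, TitrationDataset):
        if len(background) != len(dataset) or not np.allclose(
            background.ph, dataset.ph, atol=1e-9
        ):
            raise ValidationError("background pH coverage does not match dataset")
        b1, b2 = background.i1, background.i2
    else:
        b1, b2 = float(background[0]), float(background[1])
    i1 = dataset.i1 - b1
    i2 = dataset.i2 - b2
    bad = (i1 <= 0) | (i2 <= 0)
    if np.any(bad):
        raise ValidationError(
            "background subtraction produced non-positive intensity at pH "
            f"{dataset.ph[bad].tolist()}"
        )
    return TitrationDataset(
        ph=dataset.ph.copy(),
        i1=i1,
        i2=i2,
        lambda1_nm=dataset.lambda1_nm,
        lambda2_nm=dataset.lambda2_nm,
        replicate_id=dataset.replicate_id,
    )


def compute_ratio_series(
    dataset: TitrationDataset, orientation: Orientation = "R12"
) -> RatioSeries:
    """Form the intensity ratio in the requested orientation.

    R12 = I_lambda1 / I_lambda2 per point; R21 is the reciprocal.
    """
    if orientation not in ("R12", "R21"):
        raise ValidationError(f"invalid orientation {orientation!r}")
    ratio = dataset.i1 / dataset.i2 if orientation == "R12" else dataset.i2 / dataset.i1
    return RatioSeries(ph=dataset.ph.copy(), ratio=ratio, orientation=orientation, source=dataset)


def save_calibration(cal: CalibrationParameters, path: str | Path) -> None:
    """Serialize calibration parameters as JSON (full float precision)."""
    Path(path).write_text(json.dumps(cal.to_dict(), indent=2) + "\n")


def load_calibration(path: str | Path) -> CalibrationParameters:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return CalibrationParameters.from_dict(payload)
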