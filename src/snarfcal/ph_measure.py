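"""Ratio-to-pH conversion and replicate summaries.

Two inversion routes are provided, matching the two calibration schools:

* ``"hill"`` — inversion of the full four-intensity ratio model with an
  explicit Hill coefficient (the corrected route);
* ``"manufacturer"`` — the probe manual's F-factor inversion, which
  implicitly assumes n = 1.

A useful exact identity connects the two at shared limiting intensities:
for the same measured ratio, ``pH(n) = pKa + (pH(1) - pKa) / n`` (the
Hill-shift identity), and translating pKa by delta translates every
measured pH by exactly delta (the log-term is pKa-independent).

Replicate pH values are summarized as arithmetic mean +/- sample (n-1)
standard deviation; rounding to 2 decimals happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from ._exceptions import ValidationError
from .models import (
    CalibrationParameters,
    Orientation,
    invert_manufacturer,
    invert_ratio_to_ph,
)

__all__ = ["PhMeasurement", "ReplicateSummary", "measure_ph", "summarize_replicates", "render_table"]

Method = Literal["hill", "manufacturer"]


@dataclass(frozen=True)
class PhMeasurement:
    """pH of one replicate, with the calibration that produced it."""

    replicate_id: str
    ratio: float
    orientation: Orientation
    ph: float
    method: Method
    calibration: CalibrationParameters


@dataclass(frozen=True)
class ReplicateSummary:
    """Per-replicate pH values with mean and sample SD."""

    per_replicate: tuple[PhMeasurement, ...]
    mean: float
    sd: float

    def __post_init__(self) -> None:
        phs = [m.ph for m in self.per_replicate]
        if abs(self.mean - float(np.mean(phs))) > 1e-9:
            raise ValidationError("summary mean inconsistent with replicates")


def measure_ph(
    ratio: float,
    cal: CalibrationParameters,
    orientation: Orientation = "R12",
    method: Method = "hill",
    replicate_id: str = "",
) -> PhMeasurement:
    """Convert one measured ratio to pH with the chosen calibration.

    ``method="hill"`` uses the Hill-aware inversion of the full ratio
    model; ``method="manufacturer"`` uses the probe manual's F-factor
    inversion (n implicitly 1).  The ratio must lie strictly between the
    calibration's limiting ratios for the chosen orientation.
    """
    aliases = {"eq17_18": "hill", "eq11_13": "manufacturer"}
    method = aliases.get(method, method)
    if method == "hill":
        ph = invert_ratio_to_ph(ratio, cal, orientation)
    elif method == "manufacturer":
        ph = invert_manufacturer(ratio, cal, orientation)
    else:
        raise ValidationError(f"unknown method {method!r}")
    return PhMeasurement(
        replicate_id=replicate_id,
        ratio=float(ratio),
        orientation=orientation,
        ph=float(ph),
        method=method,
        calibration=cal,
    )


def summarize_replicates(measurements: Sequence[PhMeasurement]) -> ReplicateSummary:
    """Mean and sample (n-1) SD of replicate pH determinations.

    All measurements must share the inversion method and calibration
    parameters; mixing calibrations would average incommensurate scales.
    """
    if len(measurements) < 2:
        raise ValidationError("at least 2 replicate measurements required")
    if len({m.method for m in measurements}) != 1 or len(
        {m.calibration for m in measurements}
    ) != 1:
        raise ValidationError("replicates mix calibration methods or parameters")
    phs = np.array([m.ph for m in measurements], dtype=float)
    sd = 0.0 if np.ptp(phs) == 0 else float(phs.std(ddof=1))
    return ReplicateSummary(
        per_replicate=tuple(measurements),
        mean=float(phs.mean()),
        sd=sd,
    )


def render_table(summary: ReplicateSummary) -> str:
    """Per-replicate rows plus an Average row, 2-decimal presentation."""
    cal = summary.per_replicate[0].calibration
    head = (
        f"method={summary.per_replicate[0].method}  "
        f"pKa={cal.pka:.2f}  n={cal.n:.2f}"
    )
    lines = [head, "replicate\tratio\tpH"]
    for m in summary.per_replicate:
        lines.append(f"{m.replicate_id or '-'}\t{m.ratio:.4f}\t{m.ph:.2f}")
    lines.append(f"Average\t\t{summary.mean:.2f} +/- {summary.sd:.2f}")
    return "\n".join(lines)
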