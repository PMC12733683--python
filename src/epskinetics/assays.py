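"""Colorimetric assay arithmetic.

Two routine calculations used around the fermentation pipeline: a linear
standard curve for the phenol-sulfuric total-carbohydrate assay (absorbance
at 490 nm versus glucose-equivalent concentration), and the alpha-amylase
inhibition rate computed from three absorbance readings

    inhibition (%) = [1 - (A - B)/C] * 100

with A the sample reaction (sample + enzyme + substrate), B the sample
background (no enzyme) and C the uninhibited enzyme-substrate control.  The
A/B/C roles follow the conventional reading of that formula; the arithmetic
itself is agnostic to the interpretation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CalibrationCurve",
    "InhibitionReading",
    "fit_calibration",
    "concentration_from_absorbance",
    "amylase_inhibition",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve: absorbance = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int

    def __post_init__(self) -> None:
        if self.n_standards < 2:
            raise ValueError("need at least 2 standards")
        if self.slope == 0.0:
            raise ValueError("slope must be nonzero for invertibility")

    def predict(self, concentration):
        return self.slope * np.asarray(concentration, dtype=float) + self.intercept


@dataclass(frozen=True)
class InhibitionReading:
    """Absorbance triple for one inhibition measurement."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        for name in ("A", "B", "C"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0.0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.C <= 0.0:
            raise ValueError("control absorbance C must be > 0")


def fit_calibration(standards) -> CalibrationCurve:
    """Ordinary least-squares line through (concentration, absorbance) pairs."""
    pts = np.asarray(standards, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("standards must be >= 2 (concentration, absorbance) pairs")
    conc, absb = pts[:, 0], pts[:, 1]
    if np.ptp(conc) == 0.0:
        raise ValueError("all standard concentrations identical; line is degenerate")
    design = np.column_stack([conc, np.ones_like(conc)])
    (slope, intercept), *_ = np.linalg.lstsq(design, absb, rcond=None)
    pred = slope * conc + intercept
    ss_tot = float(np.sum((absb - absb.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - float(np.sum((absb - pred) ** 2)) / ss_tot
    return CalibrationCurve(
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        n_standards=len(conc),
    )


def concentration_from_absorbance(
    curve: CalibrationCurve, A: float, dilution: float = 1.0
) -> float:
    """Invert the standard curve: dilution * (A - intercept) / slope (mg/mL).

    Negative results are returned as computed (below the calibration limit),
    not clipped; callers should treat them as below-detection.
    """
    if dilution <= 0.0:
        raise ValueError("dilution factor must be > 0")
    return dilution * (A - curve.intercept) / curve.slope


def amylase_inhibition(r: InhibitionReading) -> float:
    """Alpha-amylase inhibition rate [1 - (A - B)/C] * 100, in percent.

    Values outside [0, 100] are returned as computed — real assays can
    exceed either bound — and are the caller's cue to inspect the readings.
    """
    return (1.0 - (r.A - r.B) / r.C) * 100.0
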