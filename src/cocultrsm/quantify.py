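"""Quantification conversions for fermentation products.

Covers the three bookkeeping steps of the ester-production assay chain:
densitometric TLC signal to mass via an external cetyl-palmitate standard
curve, GC peak areas to alcohol concentration via internal-standard
normalization, and plate counts of a fluorescently labelled strain to a
population percentage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ConversionError, InvalidParameterError

__all__ = [
    "CalibrationCurve",
    "ColonyCount",
    "ExtrapolationWarning",
    "fit_calibration",
    "au_to_mg_per_l",
    "alcohol_concentration",
    "strain_ratio",
]


class ExtrapolationWarning(UserWarning):
    """A converted value lies outside the calibrated standard range."""


@dataclass(frozen=True)
class CalibrationCurve:
    """Least-squares line ``signal = slope * amount + intercept``."""

    slope: float
    intercept: float
    r2: float
    x_range: tuple[float, float]

    @property
    def invertible(self) -> bool:
        return abs(self.slope) > 1e-300

    def forward(self, amount: float) -> float:
        return self.slope * amount + self.intercept

    def inverse(self, signal: float) -> float:
        if not self.invertible:
            raise ConversionError("calibration curve has zero slope; not invertible")
        return (signal - self.intercept) / self.slope


@dataclass(frozen=True)
class ColonyCount:
    fluorescent: int
    total: int

    def __post_init__(self) -> None:
        if self.fluorescent < 0 or self.total < self.fluorescent:
            raise InvalidParameterError(
                "need 0 <= fluorescent <= total colony counts"
            )


def fit_calibration(points) -> CalibrationCurve:
    """Fit a standard curve through (amount, signal) pairs by OLS."""
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise InvalidParameterError("need >= 2 (amount, signal) points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ConversionError("all standard amounts identical; calibration singular")
    res = stats.linregress(x, y)
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue**2),
        x_range=(float(x.min()), float(x.max())),
    )


def au_to_mg_per_l(
    signal: float, curve: CalibrationCurve, cell_equivalent: float = 1.0
) -> float:
    """Densitometric signal (A.U.) -> product titer (mg/L).

    Inverts the standard curve to micrograms, then rescales by
    ``cell_equivalent``, the configured factor mapping the processed cell
    pellet (the 1 mL at OD600 = 10 convention) back to culture volume.
    Warns when the inverted amount falls outside the calibrated range.
    """
    if not curve.invertible:
        raise ConversionError("calibration curve is not invertible")
    ug = curve.inverse(signal)
    lo, hi = curve.x_range
    if not lo <= ug <= hi:
        warnings.warn(
            f"inverted amount {ug:.3g} ug outside calibrated range [{lo:g}, {hi:g}]",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return ug * cell_equivalent


def alcohol_concentration(
    peak_area: float, istd_area: float, response_curve: CalibrationCurve
) -> float:
    """GC peak area -> concentration (mM) via internal-standard ratio.

    The analyte/internal-standard area ratio is mapped through the
    per-alcohol response curve (fitted as concentration vs. area ratio).
    Negative inversions (blank-level signals) clamp to 0 with a warning.
    """
    if istd_area == 0:
        raise ConversionError("internal standard missing (area = 0)")
    ratio = peak_area / istd_area
    conc = response_curve.inverse(ratio)
    if conc < 0:
        warnings.warn(
            f"inverted concentration {conc:.3g} mM < 0; clamped to 0",
            ExtrapolationWarning,
            stacklevel=2,
        )
        conc = 0.0
    return conc


def strain_ratio(count: ColonyCount) -> float:
    """Percent fluorescent of total colonies: 100 * fluorescent / total."""
    if count.total == 0:
        raise ConversionError("no colonies counted; ratio undefined")
    return 100.0 * count.fluorescent / count.total
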