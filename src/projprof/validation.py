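"""Analytical-method-validation statistics.

Covers the computations behind precision (repeatability), linearity and
accuracy (recovery) assessments of a chromatographic method:

* response normalization to [0, 1] (divide by the maximum);
* repeatability as percent relative standard deviation (RSD);
* linearity of a calibration series A = a + bC by least squares, reported as
  the correlation coefficient r, intercept a and slope b;
* spike recovery, using the calibration slope to convert the blank-subtracted
  spiked-sample area into a found concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CalibrationSeries", "RegressionFit", "normalize_response",
           "rsd_percent", "fit_linearity", "recovery_percent"]


@dataclass
class CalibrationSeries:
    """Concentrations (ug/mL) paired with measured peak areas (mAU*min)."""

    concentrations: np.ndarray
    areas: np.ndarray

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.concentrations.shape != self.areas.shape:
            raise ValueError("concentrations and areas must have equal length")
        if self.concentrations.size < 2:
            raise ValueError("need at least 2 calibration points")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be non-negative")
        if np.ptp(self.concentrations) == 0:
            raise ValueError("concentrations must not all be equal")

    @property
    def n(self) -> int:
        return self.concentrations.size


@dataclass
class RegressionFit:
    """Least-squares line A = a + b C with correlation coefficient r."""

    r: float
    a: float  # intercept, mAU*min
    b: float  # slope, mAU*min per ug/mL


def normalize_response(x) -> np.ndarray:
    """Rescale responses into [0, 1] by dividing by the maximum.

    Valid because chromatographic responses are positive (or negligibly
    negative) with minima near zero, so the full min-max rescaling collapses
    to a division by the maximum.
    """
    x = np.asarray(x, dtype=float)
    m = x.max() if x.size else 0.0
    if m <= 0:
        raise ValueError("normalization requires a positive maximum response")
    return x / m


def rsd_percent(values) -> float:
    """Percent relative standard deviation, 100 * sd / mean (sample sd, n-1)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("RSD needs at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("RSD undefined for zero mean")
    return float(100.0 * values.std(ddof=1) / mean)


def fit_linearity(series: CalibrationSeries) -> RegressionFit:
    """Closed-form least squares of area on concentration.

    b = S_xy / S_xx, a = mean(A) - b mean(C), r = S_xy / sqrt(S_xx S_yy)
    with S the centered sums of squares/products.
    """
    x = series.concentrations
    y = series.areas
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    syy = float(np.sum((y - ym) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    if sxx == 0:
        raise ValueError("degenerate fit: zero variance in concentration")
    b = sxy / sxx
    a = ym - b * xm
    r = sxy / np.sqrt(sxx * syy) if syy > 0 else 0.0
    return RegressionFit(r=float(r), a=float(a), b=float(b))


def recovery_percent(area_spiked: float, m_i: float, m: float,
                     area_unspiked: float, c_control: float,
                     fit: RegressionFit) -> float:
    """Spike recovery in percent.

    Recovery = (A_spiked - (m_i / m) * A_unspiked) / (c_control * b) * 100,
    where m_i is the spiked-sample weight, m the unspiked-sample weight,
    c_control the spiked (control) concentration and b the calibration slope.
    The m_i/m factor scales the unspiked contribution to the spiked sample's
    weight before subtraction.
    """
    if fit.b == 0:
        raise ZeroDivisionError("recovery undefined for zero calibration slope")
    if m_i <= 0 or m <= 0:
        raise ValueError("sample weights must be positive")
    return float((area_spiked - (m_i / m) * area_unspiked)
                 / (c_control * fit.b) * 100.0)
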