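"""Projection profiling and chromatogram-information parameters.

The projection profile collapses a baseline-corrected DAD cube to a single
trace in which every component appears at its maximum-absorption wavelength:
at each time point the profile takes the maximum corrected absorbance over
the chosen wavelength window.  At a peak apex this equals the chromatogram at
that compound's lambda_max, so no peak datum is altered; between peaks the
profile rides the envelope of the noise.

Two information parameters rank candidate wavelengths (or the projection):

* ``Mean(H - H')``: mean over peaks of apex response minus effective height
  — near zero when the baseline under the peaks is flat;
* ``Peaks(H'/N > 10)``: the number of quantifiable peaks, where N is the
  detrended peak-to-peak noise fluctuation in peak-free time windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dad_io import DADCube, Profile, RangeError
from .peaks import Peak

__all__ = ["ProjectionProfile", "InfoParams", "project_cube",
           "noise_fluctuation", "info_params", "DEFAULT_NOISE_WINDOWS"]

#: Peak-free windows (min) used for noise assessment on the default time axis.
DEFAULT_NOISE_WINDOWS = ((1.0, 2.0), (10.5, 11.0), (32.5, 33.0))


@dataclass
class ProjectionProfile:
    profile: Profile
    argmax_wavelength: np.ndarray   # nm, per time point
    wavelength_range: tuple         # (low, high) nm actually used


@dataclass
class InfoParams:
    mean_baseline_height: float     # Mean(H - H'), mAU; NaN when no peaks
    quantifiable_peaks: int         # Peaks(H'/N > 10)
    total_peaks: int
    noise_n: float                  # N, mAU


def project_cube(corrected: DADCube, low: float, high: float) -> ProjectionProfile:
    """Pointwise maximum over wavelengths in [low, high]; ties take the lower
    wavelength.  The per-time argmax wavelength is recorded so detected peaks
    can be annotated with their lambda_max."""
    keep = (corrected.wavelength >= low) & (corrected.wavelength <= high)
    if not keep.any():
        raise RangeError(f"projection window [{low}, {high}] nm misses the grid")
    sub = corrected.absorbance[:, keep]
    lams = corrected.wavelength[keep]
    j = np.argmax(sub, axis=1)  # first maximum = lowest wavelength on ties
    prof = Profile(time=corrected.time.copy(),
                   response=sub[np.arange(sub.shape[0]), j],
                   label="projection")
    return ProjectionProfile(profile=prof, argmax_wavelength=lams[j],
                             wavelength_range=(float(lams[0]), float(lams[-1])))


def noise_fluctuation(profile: Profile,
                      windows=DEFAULT_NOISE_WINDOWS) -> float:
    """N = mean over windows of the peak-to-peak response after removing each
    window's linear trend (so gradient drift does not inflate the noise)."""
    t, y = profile.time, profile.response
    spans = []
    for lo, hi in windows:
        sel = (t >= lo) & (t <= hi)
        if sel.sum() < 3:
            raise ValueError(f"noise window [{lo}, {hi}] min has fewer than 3 points")
        tw, yw = t[sel], y[sel]
        if np.ptp(yw) == 0.0:
            spans.append(0.0)
            continue
        slope, intercept = np.polyfit(tw, yw, 1)
        detrended = yw - (slope * tw + intercept)
        spans.append(float(np.ptp(detrended)))
    return float(np.mean(spans))


def info_params(profile: Profile, peaks: list[Peak], n_noise: float) -> InfoParams:
    """Chromatogram-information parameters for one profile.

    With N = 0 (an ideal noiseless trace) every peak with positive effective
    height counts as quantifiable.
    """
    if n_noise < 0:
        raise ValueError("noise fluctuation must be non-negative")
    total = len(peaks)
    if total == 0:
        return InfoParams(float("nan"), 0, 0, n_noise)
    mean_bh = float(np.mean([p.apex_height - p.h_prime for p in peaks]))
    if n_noise == 0:
        quant = sum(1 for p in peaks if p.h_prime > 0)
    else:
        quant = sum(1 for p in peaks if p.h_prime / n_noise > 10.0)
    return InfoParams(mean_bh, quant, total, n_noise)
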