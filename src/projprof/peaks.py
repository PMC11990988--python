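"""Peak detection, bordering and integration on chromatographic profiles.

Detection runs on a pseudo-Gaussian-smoothed copy of the trace (three passes
of an unweighted moving average): peak apexes are the downward zero-crossings
of its first derivative, and borders the nearest flanking local minima.
Candidates must clear slope, amplitude, height, width and area thresholds.
Smoothing is used *only* for detection — every height and area is measured on
the raw, unsmoothed signal to avoid quantitation bias.

Two numerical integrators and two model-fit integrators are provided:

* PD (perpendicular drop): fused peak clusters are split at verticals dropped
  from shared valleys; each slice gets the signal-above-zero area.
* TS (tangent skim / valley-to-valley): each peak is integrated above the
  straight line joining its two valley points.
* Gaussian and EGH least-squares fits of the border-clipped segment, with
  areas from the fitted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .dad_io import Profile
from .shapes import egh, gaussian, gaussian_area, egh_area

__all__ = [
    "DetectionParams", "Peak", "smooth_pseudo_gaussian", "detect_peaks",
    "integrate_pd", "integrate_ts", "fit_gaussian_peak", "fit_egh_peak",
    "peaks_to_frame",
]


@dataclass
class DetectionParams:
    """Thresholds a peak candidate must clear.

    Defaults suit projection profiles of major constituents (tens to hundreds
    of mAU); tighten ``min_height`` for noisy traces.
    """

    smooth_window: int = 7       # points, odd
    min_slope: float = 0.0       # mAU/min at the zero-crossing
    min_amplitude: float = 0.0   # mAU prominence on the smoothed trace
    min_height: float = 5.0      # mAU raw apex height
    min_width: float = 0.01      # min between borders
    min_area: float = 0.0        # mAU*min quick trapezoid

    def __post_init__(self) -> None:
        if self.smooth_window < 3 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 3")
        for name in ("min_slope", "min_amplitude", "min_height",
                     "min_width", "min_area"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class Peak:
    apex_time: float            # min (t_R)
    apex_height: float          # mAU (H)
    h_prime: float              # mAU (H'): apex minus mean valley level
    left_border: float          # min
    right_border: float         # min
    area_pd: float | None = None     # mAU*min
    area_ts: float | None = None     # mAU*min
    fit_gaussian: tuple | None = None  # (H, t_R, sigma)
    area_gauss: float | None = None
    fit_egh: tuple | None = None       # (H, t_R, sigma_g, tau)
    area_egh: float | None = None
    lambda_max: float | None = None    # nm, filled from projection argmax
    # sample indices into the profile, kept for the integrators
    left_idx: int = field(default=0, repr=False)
    apex_idx: int = field(default=0, repr=False)
    right_idx: int = field(default=0, repr=False)


def _moving_average_shrink(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; windows shrink near the ends so the output
    has the same length as the input."""
    half = window // 2
    n = y.size
    c = np.concatenate(([0.0], np.cumsum(y)))
    lo = np.maximum(0, np.arange(n) - half)
    hi = np.minimum(n, np.arange(n) + half + 1)
    return (c[hi] - c[lo]) / (hi - lo)


def smooth_pseudo_gaussian(y: np.ndarray, window: int) -> np.ndarray:
    """Three passes of an unweighted centered moving average.

    Three rectangular passes approximate a Gaussian kernel (by the central
    limit theorem) while staying cheap and ringing-free.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    y = np.asarray(y, dtype=float)
    if window >= y.size:
        raise ValueError("window must be shorter than the signal")
    out = y
    for _ in range(3):
        out = _moving_average_shrink(out, window)
    return out


def detect_peaks(profile: Profile, params: DetectionParams | None = None) -> list[Peak]:
    """Find peaks on ``profile``; empty list when nothing clears the thresholds."""
    params = params or DetectionParams()
    t, y = profile.time, profile.response
    n = t.size
    if n < 2 * params.smooth_window:
        return []
    ys = smooth_pseudo_gaussian(y, params.smooth_window)
    deriv = np.gradient(ys, t)

    peaks: list[Peak] = []
    down = np.nonzero((deriv[:-1] > 0) & (deriv[1:] <= 0))[0]
    for i in down:
        apex_s = i if ys[i] >= ys[i + 1] else i + 1
        if max(abs(deriv[i]), abs(deriv[i + 1])) < params.min_slope:
            continue
        # borders: nearest flanking local minima of the smoothed trace,
        # skipping minima that are not significant (a lower value exists
        # within the next smooth_window points)
        left = apex_s
        while left > 0 and ys[left - 1] < ys[left]:
            left -= 1
        right = apex_s
        while right < n - 1 and ys[right + 1] < ys[right]:
            right += 1
        win = params.smooth_window
        while True:
            seg = ys[max(0, left - win):left]
            if seg.size == 0 or seg.min() >= ys[left]:
                break
            left = max(0, left - win) + int(np.argmin(seg))
        while True:
            seg = ys[right + 1:right + 1 + win]
            if seg.size == 0 or seg.min() >= ys[right]:
                break
            right = right + 1 + int(np.argmin(seg))
        if right - left < 2:
            continue
        # apex position from the smoothed trace (noise-robust); height and
        # areas from the raw trace
        half = params.smooth_window // 2
        w_lo = max(left, apex_s - half)
        w_hi = min(right, apex_s + half) + 1
        apex_idx = w_lo + int(np.argmax(ys[w_lo:w_hi]))
        height = float(y[apex_idx])
        valley = 0.5 * (float(y[left]) + float(y[right]))
        h_prime = height - valley
        prominence = float(ys[apex_s]) - 0.5 * (float(ys[left]) + float(ys[right]))
        width = float(t[right] - t[left])
        quick_area = float(np.trapezoid(np.clip(y[left:right + 1], 0.0, None),
                                        t[left:right + 1]))
        if (prominence < params.min_amplitude or height < params.min_height
                or h_prime <= 0 or width < params.min_width
                or quick_area < params.min_area):
            continue
        peaks.append(Peak(
            apex_time=float(t[apex_idx]), apex_height=height, h_prime=h_prime,
            left_border=float(t[left]), right_border=float(t[right]),
            left_idx=int(left), apex_idx=int(apex_idx), right_idx=int(right),
        ))
    # de-duplicate candidates that collapsed onto the same apex sample
    unique: dict[int, Peak] = {}
    for p in peaks:
        unique[p.apex_idx] = p
    return sorted(unique.values(), key=lambda p: p.apex_time)


def _clusters(peaks: list[Peak]) -> list[list[Peak]]:
    """Group contiguous peaks (shared valley sample) into fused clusters."""
    groups: list[list[Peak]] = []
    for p in sorted(peaks, key=lambda q: q.apex_time):
        if groups and groups[-1][-1].right_idx >= p.left_idx:
            groups[-1].append(p)
        else:
            groups.append([p])
    return groups


def integrate_pd(profile: Profile, peaks: list[Peak]) -> list[Peak]:
    """Perpendicular-drop areas: signal-above-zero area within each cluster,
    split at verticals through the shared valleys (trapezoidal quadrature)."""
    t, y = profile.time, np.clip(profile.response, 0.0, None)
    for cluster in _clusters(peaks):
        for p in cluster:
            seg = slice(p.left_idx, p.right_idx + 1)
            p.area_pd = float(np.trapezoid(y[seg], t[seg]))
    return peaks


def integrate_ts(profile: Profile, peaks: list[Peak]) -> list[Peak]:
    """Tangent-skim (valley-to-valley) areas: signal above the straight line
    joining the two valley points, negative excursions clipped to zero."""
    t, y = profile.time, profile.response
    for p in peaks:
        seg = slice(p.left_idx, p.right_idx + 1)
        ts, ys = t[seg], y[seg]
        line = np.interp(ts, [ts[0], ts[-1]], [ys[0], ys[-1]])
        p.area_ts = float(np.trapezoid(np.clip(ys - line, 0.0, None), ts))
    return peaks


def _segment(profile: Profile, peak: Peak) -> tuple[np.ndarray, np.ndarray]:
    seg = slice(peak.left_idx, peak.right_idx + 1)
    return profile.time[seg], profile.response[seg]


def fit_gaussian_peak(profile: Profile, peak: Peak) -> Peak:
    """Least-squares Gaussian fit of the border-clipped segment.

    On failure (too few points, no convergence) the fit stays absent rather
    than raising.
    """
    ts, ys = _segment(profile, peak)
    if ts.size < 5:
        return peak
    sigma0 = _half_height_sigma(ts, ys, peak)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                gaussian, ts, ys,
                p0=(peak.apex_height, peak.apex_time, sigma0),
                bounds=([0.0, ts[0], 1e-6], [np.inf, ts[-1], ts[-1] - ts[0]]),
                maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return peak
    h, t_r, sigma = map(float, popt)
    peak.fit_gaussian = (h, t_r, sigma)
    peak.area_gauss = gaussian_area(h, sigma)
    return peak


def fit_egh_peak(profile: Profile, peak: Peak) -> Peak:
    """Least-squares EGH fit; area by adaptive quadrature over the support."""
    ts, ys = _segment(profile, peak)
    if ts.size < 6:
        return peak
    sigma0 = _half_height_sigma(ts, ys, peak)
    span = ts[-1] - ts[0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                egh, ts, ys,
                p0=(peak.apex_height, peak.apex_time, sigma0, 0.0),
                bounds=([0.0, ts[0], 1e-6, -span], [np.inf, ts[-1], span, span]),
                maxfev=4000,
            )
    except (RuntimeError, ValueError):
        return peak
    h, t_r, sigma_g, tau = map(float, popt)
    peak.fit_egh = (h, t_r, sigma_g, tau)
    peak.area_egh = egh_area(h, t_r, sigma_g, tau)
    return peak


def _half_height_sigma(ts: np.ndarray, ys: np.ndarray, peak: Peak) -> float:
    """Initial width guess from the half-height crossing points."""
    above = ys >= 0.5 * peak.apex_height
    if above.sum() >= 2:
        idx = np.nonzero(above)[0]
        fwhm = ts[idx[-1]] - ts[idx[0]]
        if fwhm > 0:
            return float(fwhm / 2.3548)
    return float(max((ts[-1] - ts[0]) / 6.0, 1e-4))


def peaks_to_frame(peaks: list[Peak], sample: str = "") -> pd.DataFrame:
    """Delimited-text-ready peak table (one row per peak)."""
    return pd.DataFrame({
        "sample": sample,
        "apex_time": [p.apex_time for p in peaks],
        "H": [p.apex_height for p in peaks],
        "H_prime": [p.h_prime for p in peaks],
        "left": [p.left_border for p in peaks],
        "right": [p.right_border for p in peaks],
        "area_pd": [p.area_pd for p in peaks],
        "area_ts": [p.area_ts for p in peaks],
        "area_gauss": [p.area_gauss for p in peaks],
        "area_egh": [p.area_egh for p in peaks],
        "lambda_max": [p.lambda_max for p in peaks],
    })
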