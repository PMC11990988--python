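"""Chromatographic peak shape models.

Two line shapes cover the peaks this package generates and fits:

* Gaussian: ``f(t) = H exp(-(t - t_R)^2 / (2 sigma^2))`` for symmetric peaks.
* Exponential-Gaussian hybrid (EGH): adds an exponential-decay time constant
  ``tau`` to model tailing (tau > 0) or fronting (tau < 0),

  ``f(t) = H exp(-(t - t_R)^2 / (2 sigma_g^2 + tau (t - t_R)))``

  wherever the denominator ``2 sigma_g^2 + tau (t - t_R)`` is positive, and 0
  elsewhere.  With tau = 0 the EGH reduces exactly to the Gaussian.
"""

from __future__ import annotations

import numpy as np
from scipy import integrate

__all__ = ["gaussian", "egh", "gaussian_area", "egh_area"]


def gaussian(t, height: float, t_r: float, sigma: float):
    """Gaussian peak evaluated at ``t`` (scalar or array)."""
    t = np.asarray(t, dtype=float)
    return height * np.exp(-((t - t_r) ** 2) / (2.0 * sigma**2))


def egh(t, height: float, t_r: float, sigma_g: float, tau: float):
    """Exponential-Gaussian hybrid peak evaluated at ``t``.

    Zero outside the support ``2 sigma_g^2 + tau (t - t_R) > 0``.
    """
    t = np.asarray(t, dtype=float)
    denom = 2.0 * sigma_g**2 + tau * (t - t_r)
    out = np.zeros_like(t, dtype=float)
    ok = denom > 0
    out[ok] = height * np.exp(-((t[ok] - t_r) ** 2) / denom[ok])
    return out


def gaussian_area(height: float, sigma: float) -> float:
    """Closed-form Gaussian peak area ``H sigma sqrt(2 pi)``."""
    return float(height * sigma * np.sqrt(2.0 * np.pi))


def egh_area(height: float, t_r: float, sigma_g: float, tau: float) -> float:
    """EGH peak area by adaptive quadrature over the model's support."""
    if tau == 0.0:
        return gaussian_area(height, sigma_g)
    # beyond ~20 Gaussian widths or exponential decay lengths the integrand
    # is negligible; additionally clip at the support boundary
    span = 20.0 * (abs(sigma_g) + abs(tau))
    lo, hi = t_r - span, t_r + span
    boundary = t_r - 2.0 * sigma_g**2 / tau
    if tau > 0:
        lo = max(lo, boundary)
    else:
        hi = min(hi, boundary)
    val, _ = integrate.quad(
        lambda x: float(egh(np.array([x]), height, t_r, sigma_g, tau)[0]),
        lo, hi, limit=200, points=[t_r],
    )
    return float(val)
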