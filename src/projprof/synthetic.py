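"""Synthetic HPLC-DAD cube generator with known ground truth.

Every downstream stage (baseline correction, projection, peak integration,
similarity) is validated against cubes whose true peak areas, lambda_max and
baseline surface are known by construction.  The generator emulates a
reverse-phase gradient run on a UV diode-array detector:

* EGH-shaped peaks (tailing controlled per compound by tau);
* compound-specific UV spectra built from Gaussian absorption bands, the
  strongest band defining lambda_max;
* a solvent baseline that decays exponentially in both time and wavelength —
  strongest below ~210 nm where mobile-phase absorbance dominates — plus an
  optional linear gradient drift;
* i.i.d. Gaussian detector noise.

Defaults follow a 0-35 min run sampled at 2.5 Hz over 194-450 nm in 1 nm
steps (5250 x 257 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dad_io import DADCube
from .shapes import egh

__all__ = ["CompoundSpec", "SimulationSpec", "GroundTruth",
           "spectrum_value", "simulate_cube", "default_simulation"]


@dataclass
class CompoundSpec:
    """One simulated analyte.

    ``spectrum_bands`` is a list of ``(center nm, width nm, relative
    intensity in (0, 1])`` Gaussian absorption bands; the band with relative
    intensity 1 defines the compound's lambda_max.
    """

    retention_time: float  # min
    height: float          # mAU at lambda_max
    sigma_g: float         # min
    tau: float = 0.0       # min; 0 = symmetric Gaussian
    spectrum_bands: list = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        if self.sigma_g <= 0:
            raise ValueError("sigma_g must be positive")
        if self.height <= 0:
            raise ValueError("height must be positive")
        if not self.spectrum_bands:
            raise ValueError("at least one spectrum band is required")
        peak = max(b[2] for b in self.spectrum_bands)
        if not np.isclose(peak, 1.0):
            raise ValueError("the strongest band must have relative intensity 1")

    @property
    def lambda_max(self) -> float:
        """Wavelength of the (first) band with relative intensity 1."""
        for center, _w, inten in self.spectrum_bands:
            if np.isclose(inten, 1.0):
                return float(center)
        raise AssertionError("unreachable: validated in __post_init__")


@dataclass
class SimulationSpec:
    compounds: list
    time_span: tuple = (0.0, 35.0)        # min
    sampling_rate: float = 2.5            # Hz
    wavelength_range: tuple = (194.0, 450.0, 1.0)  # (lo nm, hi nm, step nm)
    baseline_amplitude: float = 200.0     # mAU at t=0, lambda=lambda_min
    baseline_wavelength_decay: float = 8.0   # nm
    baseline_time_decay: float = 10.0     # min
    linear_drift: float = 0.05            # mAU/min
    noise_sd: float = 0.05                # mAU, typical DAD short-term noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def time_axis(self) -> np.ndarray:
        start, end = self.time_span
        step = 1.0 / (self.sampling_rate * 60.0)  # min per sample
        n = int(round((end - start) * self.sampling_rate * 60.0))
        return start + step * np.arange(n)

    def wavelength_axis(self) -> np.ndarray:
        lo, hi, step = self.wavelength_range
        return np.arange(lo, hi + 0.5 * step, step)


@dataclass
class GroundTruth:
    """Per-compound truth for oracle tests: lambda_max and the true area of
    the pure (baseline- and noise-free) trace at lambda_max, by trapezoidal
    quadrature on the simulation time grid."""

    names: list
    retention_times: np.ndarray
    lambda_max: np.ndarray
    true_area: np.ndarray   # mAU*min at lambda_max
    true_height: np.ndarray  # mAU at lambda_max

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "compound": self.names,
            "t_R_min": self.retention_times,
            "lambda_max_nm": self.lambda_max,
            "true_area": self.true_area,
            "true_height": self.true_height,
        })


def spectrum_value(bands, lam) -> np.ndarray:
    """Relative spectral intensity s(lambda) = sum of Gaussian bands, clipped to <= 1."""
    lam = np.asarray(lam, dtype=float)
    s = np.zeros_like(lam, dtype=float)
    for center, width, inten in bands:
        s = s + inten * np.exp(-((lam - center) ** 2) / (2.0 * width**2))
    return np.clip(s, None, 1.0)


def baseline_surface(spec: SimulationSpec, time: np.ndarray,
                     wavelength: np.ndarray) -> np.ndarray:
    """Separable solvent-front surface: exp decay in t and lambda plus linear drift."""
    t_term = np.exp(-time / spec.baseline_time_decay)[:, None]
    lam_term = np.exp(-(wavelength - wavelength[0]) / spec.baseline_wavelength_decay)[None, :]
    drift = (spec.linear_drift * time)[:, None]
    return spec.baseline_amplitude * t_term * lam_term + drift


def simulate_cube(spec: SimulationSpec) -> tuple[DADCube, GroundTruth]:
    """Generate a cube and its ground truth.

    absorbance(t, lambda) = sum_c EGH(t; H_c s_c(lambda), t_R, sigma_g, tau)
                            + baseline(t, lambda) + Normal(0, noise_sd^2)
    """
    time = spec.time_axis()
    wavelength = spec.wavelength_axis()
    signal = np.zeros((time.size, wavelength.size))

    names, t_rs, lmaxes, areas, heights = [], [], [], [], []
    for k, comp in enumerate(spec.compounds):
        trace = egh(time, comp.height, comp.retention_time, comp.sigma_g, comp.tau)
        s_lam = spectrum_value(comp.spectrum_bands, wavelength)
        signal += trace[:, None] * s_lam[None, :]
        names.append(comp.name or f"compound_{k + 1}")
        t_rs.append(comp.retention_time)
        lmaxes.append(comp.lambda_max)
        areas.append(float(np.trapezoid(trace, time)))
        heights.append(comp.height)

    cube_values = signal + baseline_surface(spec, time, wavelength)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        cube_values = cube_values + rng.normal(0.0, spec.noise_sd, cube_values.shape)

    cube = DADCube(time=time, wavelength=wavelength, absorbance=cube_values,
                   meta={"sampling_rate_hz": str(spec.sampling_rate),
                         "seed": str(spec.seed)})
    truth = GroundTruth(names=names,
                        retention_times=np.asarray(t_rs),
                        lambda_max=np.asarray(lmaxes),
                        true_area=np.asarray(areas),
                        true_height=np.asarray(heights))
    return cube, truth


def default_simulation(seed: int = 0, n_time_min: float = 35.0) -> SimulationSpec:
    """A five-compound mixture on the default axes.

    Retention times, widths and tailing are typical of a 35 min reverse-phase
    gradient; heights (60-250 mAU) give major-peak signal-to-noise well above
    the quantifiability cut.  lambda_max values spread over 205-310 nm so the
    projection must visit several wavelengths.
    """
    compounds = [
        CompoundSpec(4.0, 180.0, 0.060, 0.020,
                     [(207.0, 9.0, 1.0), (252.0, 14.0, 0.35)], "cpd_A"),
        CompoundSpec(9.5, 250.0, 0.080, 0.030,
                     [(222.0, 10.0, 1.0), (275.0, 16.0, 0.25)], "cpd_B"),
        CompoundSpec(15.0, 120.0, 0.090, 0.040,
                     [(254.0, 12.0, 1.0), (214.0, 8.0, 0.45)], "cpd_C"),
        CompoundSpec(21.5, 90.0, 0.110, 0.050,
                     [(278.0, 13.0, 1.0), (230.0, 9.0, 0.30)], "cpd_D"),
        CompoundSpec(28.0, 60.0, 0.130, 0.060,
                     [(310.0, 15.0, 1.0), (240.0, 10.0, 0.20)], "cpd_E"),
    ]
    return SimulationSpec(compounds=compounds, time_span=(0.0, n_time_min),
                          seed=seed)
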