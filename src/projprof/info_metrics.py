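"""Effective-information factor (EI) and EI-driven baseline parameter search.

A good baseline correction should (a) leave peaks quantifiable above the
noise, (b) leave them undistorted by residual drift, and (c) never capture
real peaks into the estimated baseline.  The EI score folds all three into

    EI = (P_N + P_D) / P_ALL  *  (A_N + A_D) / A_ALL  *  1 / (P_B + 1)

where P/A are peak counts/areas: subscript N for peaks unaffected by noise
(H'/N > 10), D for peaks unaffected by drift, ALL for everything detected on
the projection profile, and P_B counts peaks detected in the *baselines*
(the projected baseline and the fitted baseline at 210 nm) — a symptom of
baseline overfitting.  EI ranges over [0, 4]; EI = 4 is ideal correction.

Parameter optimization evaluates EI over a grid (20 log-spaced smoothness
values spanning 1..1e10 for the PLS family); with more than two parameters,
pairs are optimized sequentially ("couple-by-couple") holding the rest fixed.
"""

from __future__ import annotations

import itertools
import time as _time
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .baselines import BaselineParams, correct_cube, default_params
from .dad_io import DADCube, Profile, extract_chromatogram
from .peaks import DetectionParams, Peak, detect_peaks, integrate_ts
from .projection import DEFAULT_NOISE_WINDOWS, noise_fluctuation, project_cube

__all__ = ["EIComponents", "GridSearchReport", "effective_information",
           "classify_peaks", "baseline_peak_count", "evaluate_ei",
           "grid_search_baseline"]


@dataclass
class EIComponents:
    """The seven counters/areas entering the EI score."""

    p_n: int = 0
    p_d: int = 0
    p_all: int = 0
    a_n: float = 0.0
    a_d: float = 0.0
    a_all: float = 0.0
    p_b: int = 0

    def validate(self) -> None:
        if not (0 <= self.p_n <= self.p_all and 0 <= self.p_d <= self.p_all):
            raise ValueError("need 0 <= p_n, p_d <= p_all")
        if not (0 <= self.a_n <= self.a_all + 1e-12
                and 0 <= self.a_d <= self.a_all + 1e-12):
            raise ValueError("need 0 <= a_n, a_d <= a_all")
        if self.p_b < 0:
            raise ValueError("p_b must be non-negative")
        if self.p_all > 0 and self.a_all <= 0:
            raise ValueError("a_all must be positive when peaks were detected")


def effective_information(c: EIComponents) -> float:
    """EI in [0, 4]; raises when no peaks were detected (P_ALL = 0)."""
    c.validate()
    if c.p_all == 0:
        raise ValueError("EI undefined: no peaks detected (p_all = 0)")
    return ((c.p_n + c.p_d) / c.p_all) * ((c.a_n + c.a_d) / c.a_all) \
        * (1.0 / (c.p_b + 1.0))


def classify_peaks(peaks: list[Peak], n_noise: float,
                   drift_tolerance: float = 0.05) -> EIComponents:
    """Sort detected peaks into noise-unaffected and drift-unaffected bins.

    Noise-unaffected: H'/N > 10 (with N = 0 every positive peak passes).
    Drift-unaffected: (H - H')/H' <= drift_tolerance, i.e. the residual
    baseline under the apex is a small fraction of the effective height.
    Areas are TS areas; ``p_b`` is left at 0 for the caller to fill.
    """
    comp = EIComponents()
    for p in peaks:
        area = p.area_ts if p.area_ts is not None else 0.0
        comp.p_all += 1
        comp.a_all += area
        noise_ok = (p.h_prime > 0) if n_noise == 0 else (p.h_prime / n_noise > 10.0)
        if noise_ok:
            comp.p_n += 1
            comp.a_n += area
        if p.h_prime > 0 and (p.apex_height - p.h_prime) / p.h_prime <= drift_tolerance:
            comp.p_d += 1
            comp.a_d += area
    return comp


def baseline_peak_count(projection_baseline: Profile, baseline_210: Profile,
                        params: DetectionParams) -> int:
    """P_B: peaks detected in the projected baseline plus in the 210 nm
    channel baseline, with the same detection settings as the profile.
    Counts are summed over the two baselines (coincident artifacts are not
    deduplicated)."""
    return len(detect_peaks(projection_baseline, params)) \
        + len(detect_peaks(baseline_210, params))


@dataclass
class GridSearchReport:
    grid: pd.DataFrame          # one row per evaluation
    best: BaselineParams
    best_ei: float
    tie_rule: str = "ties broken toward larger lam (smoother baseline)"


def evaluate_ei(cube: DADCube, params: BaselineParams,
                detection: DetectionParams,
                window: tuple = (205.0, 450.0),
                noise_windows=DEFAULT_NOISE_WINDOWS,
                drift_tolerance: float = 0.05,
                reference_wavelength: float = 210.0):
    """Full pipeline for one parameter point: correct -> project -> detect ->
    integrate (TS) -> classify -> EI.  Returns (EI, components, N)."""
    corrected, baseline = correct_cube(cube, params)
    proj = project_cube(corrected, *window)
    pks = detect_peaks(proj.profile, detection)
    integrate_ts(proj.profile, pks)
    n_noise = noise_fluctuation(proj.profile, noise_windows)
    comp = classify_peaks(pks, n_noise, drift_tolerance)
    proj_base = project_cube(baseline, *window)
    base_ref = extract_chromatogram(baseline, reference_wavelength)
    comp.p_b = baseline_peak_count(proj_base.profile, base_ref, detection)
    ei = effective_information(comp) if comp.p_all > 0 else 0.0
    return ei, comp, n_noise


def _param_points(grid_spec: dict) -> list[dict]:
    """Expand a {name: values} grid.  One or two parameters: full product.
    More: couple-by-couple is handled by the caller."""
    names = list(grid_spec)
    combos = itertools.product(*(grid_spec[n] for n in names))
    return [dict(zip(names, c)) for c in combos]


def _apply(params: BaselineParams, point: dict) -> BaselineParams:
    updates = dict(point)
    if "order" in updates:
        updates["order"] = int(updates["order"])
    if "window" in updates:
        updates["window"] = int(updates["window"])
    return replace(params, **updates)


def grid_search_baseline(cube: DADCube, method: str, grid_spec: dict,
                         detection: DetectionParams | None = None,
                         window: tuple = (205.0, 450.0),
                         noise_windows=DEFAULT_NOISE_WINDOWS,
                         drift_tolerance: float = 0.05) -> GridSearchReport:
    """Maximize EI over a parameter grid for one baseline method.

    With more than two grid parameters, pairs are optimized sequentially in
    the order given, holding the remaining parameters at their current
    values.  Failed corrections score EI = 0 and the search continues.
    Ties prefer the larger ``lam`` (smoother baseline), then earlier rows.
    """
    if not grid_spec or any(len(v) == 0 for v in grid_spec.values()):
        raise ValueError("grid must be non-empty")
    detection = detection or DetectionParams()
    base = default_params(method)
    names = list(grid_spec)

    # couple-by-couple: chunk the parameter names into pairs
    chunks = [names[i:i + 2] for i in range(0, len(names), 2)] \
        if len(names) > 2 else [names]

    rows = []
    current = base
    best_params, best_key = current, None
    for chunk in chunks:
        sub = {n: grid_spec[n] for n in chunk}
        chunk_best, chunk_key = None, None
        for point in _param_points(sub):
            params = _apply(current, point)
            t0 = _time.perf_counter()
            try:
                ei, comp, n_noise = evaluate_ei(
                    cube, params, detection, window, noise_windows,
                    drift_tolerance)
                note = ""
            except Exception as exc:
                ei, comp, n_noise = 0.0, EIComponents(), float("nan")
                note = f"error: {exc}"
            runtime = _time.perf_counter() - t0
            rows.append({**{n: getattr(params, n) for n in names},
                         "EI": ei, "P_ALL": comp.p_all, "P_B": comp.p_b,
                         "noise_N": n_noise, "runtime_s": runtime,
                         "note": note})
            key = (ei, params.lam)
            if chunk_key is None or key > chunk_key:
                chunk_best, chunk_key = params, key
        current = chunk_best
        if best_key is None or chunk_key > best_key:
            best_params, best_key = chunk_best, chunk_key

    return GridSearchReport(grid=pd.DataFrame(rows), best=best_params,
                            best_ei=float(best_key[0]))
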