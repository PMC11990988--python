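"""Fingerprint similarity analysis.

Peak tables from many sample runs are matched on retention time into a
samples x peaks area matrix; the reference fingerprint (RFP) is the
coordinate-wise median over samples (robust to outlier batches); and each
sample fingerprint (SFP) x is compared with the reference y through six
parameters:

qualitative (cosine family, in [0, 1] for non-negative inputs)
    S_F   cosine of the angle between x and y — weighted toward strong peaks;
    S_F'  cosine between the ratio vector r (r_i = x_i / y_i) and the unit
          vector — weighted toward weak peaks;
    S_R   like S_F' but on the bounded ratio p_i = x_i/y_i (x_i < y_i) or
          2 - y_i/x_i (x_i >= y_i) — no strong/weak bias;

quantitative (percent of the reference)
    L     norm ratio 100 ||x|| / ||y|| — strong-peak biased;
    M     mean area ratio 100 mean(x_i / y_i) — weak-peak biased;
    R     total-area ratio 100 sum(x) / sum(y) — unbiased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PeakMatrix", "SimilarityScores", "match_peaks",
           "reference_fingerprint", "similarity_scores", "similarity_study",
           "QUALITATIVE", "QUANTITATIVE"]

QUALITATIVE = ("S_F", "S_F_prime", "S_R")
QUANTITATIVE = ("L", "M", "R")


@dataclass
class PeakMatrix:
    """Samples x matched-peaks area table; 0 marks an absent peak."""

    samples: list
    reference_times: np.ndarray  # min, one anchor per matched peak
    areas: np.ndarray            # (n_samples, n_peaks), mAU*min

    def __post_init__(self) -> None:
        self.reference_times = np.asarray(self.reference_times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (len(self.samples), self.reference_times.size):
            raise ValueError("areas shape must be (n_samples, n_anchors)")
        if np.any(self.areas < 0):
            raise ValueError("areas must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{t:.3f}" for t in self.reference_times]
        return pd.DataFrame(self.areas, index=self.samples, columns=cols)


@dataclass
class SimilarityScores:
    s_f: float
    s_f_prime: float
    s_r: float
    l: float  # percent
    m: float  # percent
    r: float  # percent

    def as_dict(self) -> dict:
        return {"S_F": self.s_f, "S_F_prime": self.s_f_prime, "S_R": self.s_r,
                "L": self.l, "M": self.m, "R": self.r}


def match_peaks(tables: list[pd.DataFrame], rt_tolerance: float = 0.2,
                min_presence: float = 0.5) -> PeakMatrix:
    """Match peaks across samples on retention time.

    Every apex time from every table is pooled and clustered by single
    linkage: sorted times split wherever the gap between neighbours exceeds
    ``rt_tolerance``.  Each cluster's median time becomes an anchor; each
    sample contributes the TS area of its nearest in-tolerance peak (0 when
    absent, with the nearer peak kept and a warning issued if two peaks of
    one sample fall on the same anchor).  Anchors present in fewer than
    ``min_presence`` of the samples are dropped.

    Tables need columns ``sample``, ``apex_time`` and ``area_ts``.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 peak tables")
    if rt_tolerance <= 0:
        raise ValueError("rt_tolerance must be positive")

    frames = []
    for i, tab in enumerate(tables):
        name = str(tab["sample"].iloc[0]) if ("sample" in tab and len(tab)) \
            else f"sample_{i + 1}"
        frames.append(pd.DataFrame({
            "sample_idx": i, "sample": name,
            "time": tab["apex_time"].to_numpy(dtype=float),
            "area": tab["area_ts"].to_numpy(dtype=float),
        }))
    pool = pd.concat(frames, ignore_index=True).sort_values("time")
    samples = [f.loc[0, "sample"] if len(f) else f"sample_{i+1}"
               for i, f in enumerate(frames)]

    times = pool["time"].to_numpy()
    breaks = np.nonzero(np.diff(times) > rt_tolerance)[0]
    cluster_id = np.zeros(times.size, dtype=int)
    for b in breaks:
        cluster_id[b + 1:] += 1
    pool = pool.assign(cluster=cluster_id)

    anchors, columns = [], []
    n_samples = len(tables)
    for _, grp in pool.groupby("cluster"):
        anchor = float(np.median(grp["time"]))
        col = np.zeros(n_samples)
        present = 0
        for s_idx, sub in grp.groupby("sample_idx"):
            dist = np.abs(sub["time"].to_numpy() - anchor)
            in_tol = dist <= rt_tolerance
            if not in_tol.any():
                continue
            if in_tol.sum() > 1:
                warnings.warn(
                    f"sample {samples[s_idx]!r}: {int(in_tol.sum())} peaks map "
                    f"to anchor {anchor:.3f} min; keeping the nearest",
                    stacklevel=2)
            col[s_idx] = float(sub["area"].to_numpy()[np.argmin(dist)])
            present += 1
        if present / n_samples >= min_presence:
            anchors.append(anchor)
            columns.append(col)

    areas = np.column_stack(columns) if columns else np.zeros((n_samples, 0))
    return PeakMatrix(samples=samples, reference_times=np.asarray(anchors),
                      areas=areas)


def reference_fingerprint(matrix: PeakMatrix) -> np.ndarray:
    """Coordinate-wise median over samples (mean of middle two for even
    counts); robust to a single outlier batch."""
    if len(matrix.samples) < 2:
        raise ValueError("need at least 2 samples")
    ref = np.median(matrix.areas, axis=0)
    if np.any(ref == 0):
        warnings.warn("reference fingerprint has zero coordinates; "
                      "ratio-based parameters will exclude them", stacklevel=2)
    return ref


def similarity_scores(x, y) -> SimilarityScores:
    """Six similarity parameters of a sample fingerprint x against a
    reference y.

    Coordinates with y_i = 0 cannot enter the ratio-based parameters
    (S_F', S_R, M); they are excluded pairwise with a warning.  S_F, L and R
    always use the full vectors.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D of equal length")
    if x.size == 0:
        raise ValueError("empty fingerprint vectors")

    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if ny == 0 or y.sum() == 0:
        raise ValueError("reference fingerprint is identically zero")
    # cosines are clipped at 1: rounding can push x @ y past |x||y|
    s_f = min(float(x @ y / (nx * ny)), 1.0) if nx > 0 else 0.0
    l_val = float(100.0 * nx / ny)
    r_val = float(100.0 * x.sum() / y.sum())

    ok = y > 0
    if not ok.all():
        warnings.warn(f"{int((~ok).sum())} zero-reference coordinate(s) "
                      "excluded from ratio-based parameters", stacklevel=2)
    xr, yr = x[ok], y[ok]
    if xr.size == 0:
        raise ValueError("no coordinates with positive reference area")
    n = xr.size

    ratio = xr / yr
    denom = np.sqrt(n) * np.linalg.norm(ratio)
    s_f_prime = min(float(ratio.sum() / denom), 1.0) if denom > 0 else 0.0

    with np.errstate(divide="ignore"):
        p = np.where(xr < yr, ratio, 2.0 - yr / np.where(xr > 0, xr, np.inf))
    denom = np.sqrt(n) * np.linalg.norm(p)
    s_r = min(float(p.sum() / denom), 1.0) if denom > 0 else 0.0

    m_val = float(100.0 * ratio.mean())
    return SimilarityScores(s_f, s_f_prime, s_r, l_val, m_val, r_val)


def similarity_study(matrices: dict, rt_tolerance: float = 0.2) -> pd.DataFrame:
    """Tidy long-format similarity table over several profile sources.

    ``matrices`` maps a source label (a wavelength like ``"220 nm"`` or
    ``"projection"``) to a :class:`PeakMatrix`.  For each source the RFP is
    the median fingerprint and every sample is scored against it; rows are
    (sample, source, parameter, group, value) with group "quality" for
    S_F/S_F'/S_R and "quantity" for L/M/R — the shape a downstream ANOVA
    consumes.
    """
    rows = []
    for source, matrix in matrices.items():
        ref = reference_fingerprint(matrix)
        for i, sample in enumerate(matrix.samples):
            scores = similarity_scores(matrix.areas[i], ref).as_dict()
            for name, value in scores.items():
                group = "quality" if name in QUALITATIVE else "quantity"
                rows.append({"sample": sample, "source": source,
                             "parameter": name, "group": group,
                             "value": value})
    return pd.DataFrame(rows)
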