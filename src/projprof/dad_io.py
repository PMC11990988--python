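"""Containers and text I/O for diode-array-detector (DAD) data.

A DAD records absorbance simultaneously across UV-Vis wavelengths while the
chromatographic run proceeds, yielding a cube: time x wavelength x absorbance
(mAU).  Files use a "wide CSV" layout: the first row holds the wavelength grid
in nm, the first column the time grid in minutes, and cell (i, j) the
absorbance at (time_i, wavelength_j).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DADCube",
    "Profile",
    "read_cube",
    "write_cube",
    "read_profile",
    "write_profile",
    "extract_chromatogram",
    "trim_wavelengths",
]

_TIME_STEP_TOL = 1e-6  # minutes


class AxisError(ValueError):
    """A time or wavelength axis violates monotonicity/uniformity."""


class RangeError(ValueError):
    """A requested wavelength or window falls outside the recorded grid."""


@dataclass
class Profile:
    """A 1D response-vs-time trace (single-wavelength chromatogram or projection).

    Attributes
    ----------
    time : ndarray
        Time axis in minutes, strictly increasing.
    response : ndarray
        Detector response in mAU, same length as ``time``.
    label : str
        Free-form provenance, e.g. ``"220 nm"`` or ``"projection"``.
    """

    time: np.ndarray
    response: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.time.ndim != 1 or self.response.ndim != 1:
            raise ValueError("time and response must be 1D")
        if self.time.shape != self.response.shape:
            raise ValueError(
                f"time ({self.time.size}) and response ({self.response.size}) "
                "length mismatch"
            )
        if self.time.size >= 2 and not np.all(np.diff(self.time) > 0):
            raise AxisError("profile time axis must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class DADCube:
    """The 3D DAD record: time vs wavelength vs absorbance.

    Attributes
    ----------
    time : ndarray
        Minutes, strictly increasing with a uniform step (to 1e-6 min).
    wavelength : ndarray
        Nanometres, strictly increasing.
    absorbance : ndarray
        mAU, shape (n_time, n_wavelength).
    meta : dict
        Free-form key -> text annotations (sample id, sampling rate, ...).
    """

    time: np.ndarray
    wavelength: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise AxisError("time axis must be 1D with at least 2 points")
        if self.wavelength.ndim != 1 or self.wavelength.size < 1:
            raise AxisError("wavelength axis must be 1D with at least 1 point")
        steps = np.diff(self.time)
        if not np.all(steps > 0):
            raise AxisError("time axis must be strictly increasing")
        if np.ptp(steps) > _TIME_STEP_TOL:
            raise AxisError(
                f"time step must be uniform to {_TIME_STEP_TOL} min "
                f"(spread {np.ptp(steps):.3g})"
            )
        if self.wavelength.size >= 2 and not np.all(np.diff(self.wavelength) > 0):
            raise AxisError("wavelength axis must be strictly increasing")
        expected = (self.time.size, self.wavelength.size)
        if self.absorbance.shape != expected:
            raise ValueError(
                f"absorbance shape {self.absorbance.shape} does not match axes {expected}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.absorbance.shape

    @property
    def time_step(self) -> float:
        """Sampling interval in minutes."""
        return float(self.time[1] - self.time[0])


def read_cube(path, dialect: str = "wide_csv") -> DADCube:
    """Read a DAD cube from a wide delimited-text file.

    Row 1 carries the wavelength grid (nm), column 1 the time grid (min);
    cell (i, j) is absorbance in mAU.  Raises a parse error naming the
    offending row for ragged input and :class:`AxisError` for non-monotone
    or duplicated axes.
    """
    if dialect != "wide_csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    # validate the wavelength header before pandas mangles duplicate columns
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                header = line.rstrip("\n").split(",")[1:]
                break
        else:
            raise ValueError(f"empty cube file {path}")
    try:
        wavelength = np.array([float(v) for v in header])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavelength header in {path}: {exc}") from exc
    if wavelength.size >= 2 and not np.all(np.diff(wavelength) > 0):
        raise AxisError(f"wavelength header in {path} is not strictly "
                        "increasing (duplicate or out-of-order columns)")
    try:
        frame = pd.read_csv(path, index_col=0, comment="#")
    except pd.errors.ParserError as exc:  # pandas names the bad row
        raise ValueError(f"ragged or malformed cube file {path}: {exc}") from exc
    try:
        time = frame.index.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric time labels in {path}: {exc}") from exc
    try:
        return DADCube(time=time, wavelength=wavelength,
                       absorbance=frame.to_numpy(dtype=float))
    except AxisError:
        raise
    except ValueError as exc:
        raise ValueError(f"cannot parse {path}: {exc}") from exc


def write_cube(cube: DADCube, path) -> object:
    """Write ``cube`` in the wide_csv layout; round-trips to 1e-9 mAU."""
    frame = pd.DataFrame(cube.absorbance, index=cube.time, columns=cube.wavelength)
    frame.index.name = "time_min"
    frame.to_csv(path, float_format="%.10g")
    return path


def write_profile(profile: Profile, path, header_lines: list[str] | None = None):
    """Two-column delimited text (time_min, response_mau); optional
    ``#``-prefixed provenance lines at the top."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(f"# label: {profile.label}\n")
        fh.write("time_min,response_mau\n")
        for t, r in zip(profile.time, profile.response):
            fh.write(f"{t:.10g},{r:.10g}\n")
    return path


def read_profile(path) -> Profile:
    """Read a profile written by :func:`write_profile`; ``#`` lines ignored
    except that a ``# label:`` line restores the label."""
    label = ""
    with open(path) as fh:
        for line in fh:
            if line.startswith("# label:"):
                label = line.split(":", 1)[1].strip()
            elif not line.startswith("#"):
                break
    frame = pd.read_csv(path, comment="#")
    return Profile(time=frame.iloc[:, 0].to_numpy(dtype=float),
                   response=frame.iloc[:, 1].to_numpy(dtype=float),
                   label=label)


def nearest_wavelength_index(wavelength: np.ndarray, target: float) -> int:
    """Index of the grid wavelength nearest ``target``; ties round up."""
    lo, hi = wavelength[0], wavelength[-1]
    if not (lo <= target <= hi):
        raise RangeError(
            f"wavelength {target} nm outside recorded range [{lo}, {hi}] nm"
        )
    # searchsorted gives the first grid point >= target; compare with its
    # left neighbour, preferring the higher wavelength on an exact tie.
    j = int(np.searchsorted(wavelength, target))
    if j == 0:
        return 0
    if j == wavelength.size:
        return j - 1
    return j if (wavelength[j] - target) <= (target - wavelength[j - 1]) else j - 1


def extract_chromatogram(cube: DADCube, target_wavelength: float) -> Profile:
    """Single-wavelength chromatogram at the grid point nearest ``target_wavelength``.

    The label records the actual grid wavelength used.
    """
    j = nearest_wavelength_index(cube.wavelength, target_wavelength)
    lam = cube.wavelength[j]
    return Profile(time=cube.time.copy(),
                   response=cube.absorbance[:, j].copy(),
                   label=f"{lam:g} nm")


def trim_wavelengths(cube: DADCube, low: float, high: float) -> DADCube:
    """Retain only columns with ``low <= lambda <= high``; time axis unchanged.

    Dropping the solvent-dominated low-wavelength channels before projection
    trades a little information for quantitative accuracy.
    """
    if not low < high:
        raise RangeError(f"need low < high, got [{low}, {high}]")
    keep = (cube.wavelength >= low) & (cube.wavelength <= high)
    if not keep.any():
        raise RangeError(
            f"window [{low}, {high}] nm does not intersect grid "
            f"[{cube.wavelength[0]}, {cube.wavelength[-1]}] nm"
        )
    return DADCube(time=cube.time.copy(),
                   wavelength=cube.wavelength[keep].copy(),
                   absorbance=cube.absorbance[:, keep].copy(),
                   meta=dict(cube.meta))
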