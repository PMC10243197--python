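"""Spectrum containers, I/O, resampling, normalization and characteristics.

Spectra live on uniform wavelength grids.  Two grids matter in practice:
the 58-point UV grid (230 + 3k nm, k = 0..57) used by the single-molecule
stage, and the 43-point visible grid (360..780 nm, 10 nm step) used by the
mixture stage.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
import re

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectralCharacteristics",
    "ConcentrationCode",
    "UV_GRID",
    "VIS_GRID",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "normalize_minmax",
    "extract_characteristics",
    "parse_concentration_code",
]

#: Reference concentration (mol/l) of the dye stock coded ".2" / bare.
REFERENCE_CONCENTRATION = 1.0e-4

#: Concentration code suffix -> mol/l.
_SUFFIX_CONC = {1: 0.75e-4, 2: 1.0e-4, 3: 1.25e-4}


@dataclass(frozen=True)
class Spectrum:
    """Absorbance sampled on a uniform ascending wavelength grid."""

    grid_start_nm: float
    grid_step_nm: float
    absorbance: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.absorbance, dtype=float)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("absorbance must be a non-empty 1-D vector")
        if self.grid_step_nm <= 0:
            raise ValueError("grid_step_nm must be positive")
        object.__setattr__(self, "absorbance", arr)

    @property
    def n_points(self) -> int:
        return int(self.absorbance.size)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid_start_nm + self.grid_step_nm * np.arange(self.n_points)

    @property
    def grid_end_nm(self) -> float:
        return float(self.wavelengths[-1])

    def with_absorbance(self, absorbance: np.ndarray, *, normalized: bool | None = None) -> "Spectrum":
        return replace(
            self,
            absorbance=np.asarray(absorbance, dtype=float),
            normalized=self.normalized if normalized is None else normalized,
        )

    def same_grid(self, other: "Spectrum") -> bool:
        return (
            self.n_points == other.n_points
            and np.isclose(self.grid_start_nm, other.grid_start_nm)
            and np.isclose(self.grid_step_nm, other.grid_step_nm)
        )


def _uniform_grid(start: float, step: float, n: int) -> "GridSpec":
    return GridSpec(start, step, n)


@dataclass(frozen=True)
class GridSpec:
    """A uniform wavelength grid: start + step * k, k = 0..n-1."""

    start_nm: float
    step_nm: float
    n: int

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n)

    def spectrum(self, absorbance: np.ndarray, *, normalized: bool = False) -> Spectrum:
        arr = np.asarray(absorbance, dtype=float)
        if arr.size != self.n:
            raise ValueError(f"expected {self.n} points, got {arr.size}")
        return Spectrum(self.start_nm, self.step_nm, arr, normalized=normalized)


#: 58-point UV grid: 230 + 3k nm, k = 0..57 (ends at 401 nm; the terminal
#: point is clamp-interpolated from 230-400 nm sources).
UV_GRID = GridSpec(230.0, 3.0, 58)

#: 43-point visible grid: 360..780 nm at 10 nm.
VIS_GRID = GridSpec(360.0, 10.0, 43)


@dataclass(frozen=True)
class SpectralCharacteristics:
    """The three scalar summaries of a spectrum: peak wavelength, area, height.

    ``area_sum`` is the plain sum of absorbances over the grid (not a
    trapezoid area), and ``peak_height`` is the absorbance at the peak if an
    interior local maximum exists, else the absorbance at 250 nm.
    """

    lambda_peak_nm: float
    area_sum: float
    peak_height: float

    def as_array(self) -> np.ndarray:
        return np.array([self.lambda_peak_nm, self.area_sum, self.peak_height])


@dataclass(frozen=True)
class ConcentrationCode:
    """One component of a mixture code: dye id plus molar concentration."""

    dye_id: int
    concentration_mol_per_l: float

    @property
    def relative_concentration(self) -> float:
        """Concentration in units of the 1e-4 mol/l reference."""
        return self.concentration_mol_per_l / REFERENCE_CONCENTRATION


# ---------------------------------------------------------------------------
# I/O


def read_spectrum(path: str | Path) -> Spectrum:
    """Read a two-column (wavelength_nm, absorbance) CSV into a Spectrum.

    The wavelength column must form a uniform ascending grid.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2 or df.shape[0] == 0:
        raise ValueError(f"{path}: expected a non-empty two-column CSV")
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    ab = df.iloc[:, 1].to_numpy(dtype=float)
    if wl.size == 1:
        raise ValueError(f"{path}: a spectrum needs at least two points")
    steps = np.diff(wl)
    step = steps[0]
    bad = np.where(~np.isclose(steps, step, rtol=0, atol=1e-6))[0]
    if step <= 0 or bad.size:
        rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
        raise ValueError(f"{path}: non-uniform wavelength grid (rows {rows or 2})")
    return Spectrum(float(wl[0]), float(step), ab)


def write_spectrum(s: Spectrum, path: str | Path) -> None:
    """Write a Spectrum as a two-column CSV (header ``wavelength_nm,absorbance``)."""
    df = pd.DataFrame({"wavelength_nm": s.wavelengths, "absorbance": s.absorbance})
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# Transforms


def resample(s: Spectrum, start: float, step: float, n: int, *, clamp: bool = False) -> Spectrum:
    """Linearly interpolate onto the grid start + k*step, k = 0..n-1.

    Target points must lie within the source coverage; with ``clamp=True``
    points beyond the source end repeat the terminal value (used to fill the
    401 nm endpoint of the 58-point UV grid from 230-400 nm sources).
    """
    target = start + step * np.arange(n)
    lo, hi = s.grid_start_nm, s.grid_end_nm
    tol = 1e-9
    if target[0] < lo - tol or (not clamp and target[-1] > hi + tol):
        raise ValueError(
            f"target grid [{target[0]}, {target[-1]}] outside source coverage [{lo}, {hi}]"
        )
    out = np.interp(target, s.wavelengths, s.absorbance)
    return Spectrum(float(start), float(step), out, normalized=s.normalized)


def to_uv_grid(s: Spectrum) -> Spectrum:
    """Resample onto the 58-point UV grid (clamped at the 401 nm endpoint)."""
    return resample(s, UV_GRID.start_nm, UV_GRID.step_nm, UV_GRID.n, clamp=True)


def normalize_minmax(s: Spectrum) -> Spectrum:
    """Affinely rescale so min(absorbance) = 0 and max(absorbance) = 1."""
    a = s.absorbance
    lo, hi = float(a.min()), float(a.max())
    if hi - lo <= 0:
        raise ValueError("cannot min-max normalize a constant spectrum")
    return s.with_absorbance((a - lo) / (hi - lo), normalized=True)


def extract_characteristics(s: Spectrum) -> SpectralCharacteristics:
    """Extract (lambda_peak, area_sum, peak_height) from a spectrum.

    lambda is the grid wavelength of the global maximum (ties break to the
    lowest wavelength); S is the plain sum of absorbances; H is the
    absorbance at lambda when the spectrum has an interior local maximum
    (a grid point strictly above both neighbours), else the absorbance at
    250 nm (nearest grid point).
    """
    a = s.absorbance
    wl = s.wavelengths
    idx = int(np.argmax(a))  # argmax takes the first (lowest-wavelength) tie
    lam = float(wl[idx])
    area = float(a.sum())
    interior = a[1:-1]
    has_peak = bool(np.any((interior > a[:-2]) & (interior > a[2:])))
    if has_peak:
        height = float(a[idx])
    else:
        height = float(a[int(np.argmin(np.abs(wl - 250.0)))])
    return SpectralCharacteristics(lam, area, height)


# ---------------------------------------------------------------------------
# Concentration codes

_COMPONENT_RE = re.compile(r"^(\d+)(?:\.([123]))?$")


def parse_concentration_code(code: str) -> list[ConcentrationCode]:
    """Parse a mixture code like ``"1.1 + 3.3"`` into components.

    Suffix ".1" means 0.75e-4 mol/l, ".2" (or no suffix) 1.0e-4 mol/l and
    ".3" 1.25e-4 mol/l; components are joined by "+".
    """
    out: list[ConcentrationCode] = []
    pos = 0
    for part in code.split("+"):
        token = part.strip()
        m = _COMPONENT_RE.match(token)
        if not m:
            raise ValueError(
                f"malformed concentration code {code!r}: bad component {token!r} "
                f"at position {pos}"
            )
        suffix = int(m.group(2)) if m.group(2) else 2
        out.append(ConcentrationCode(int(m.group(1)), _SUFFIX_CONC[suffix]))
        pos += len(part) + 1
    if not out:
        raise ValueError(f"empty concentration code {code!r}")
    return out
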