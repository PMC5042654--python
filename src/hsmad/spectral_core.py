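"""Wavelength grids and per-spectrum preprocessing primitives.

Every spectrum in the package lives on a :class:`WavelengthGrid`, a uniform
inclusive wavelength axis (default 400-1000 nm in 361 samples, i.e. a 5/3 nm
spacing).  The preprocessing applied to a pixel spectrum before clustering or
classification is always the same three steps, in order: truncation below a
noise cutoff (default 566 nm), Savitzky-Golay smoothing, and normalization to
unit maximum.  :class:`PreprocessConfig` bundles those choices so that
training and classification are guaranteed to use identical preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

from .errors import DegenerateSpectrumError, InvalidGridError

__all__ = [
    "WavelengthGrid",
    "BandWindow",
    "PreprocessConfig",
    "DEFAULT_GRID",
    "NP_BAND",
    "build_grid",
    "truncate_to_cutoff",
    "smooth_savgol",
    "normalize_max",
    "band_mean",
    "band_indices",
    "preprocess_spectra",
]


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, inclusive wavelength axis in nanometres.

    Parameters
    ----------
    start_nm, end_nm
        First and last sample wavelengths (inclusive).
    n_samples
        Number of samples; must be at least 2.
    """

    start_nm: float
    end_nm: float
    n_samples: int

    def __post_init__(self):
        if self.n_samples < 2:
            raise InvalidGridError(f"grid needs >= 2 samples, got {self.n_samples}")
        if not self.end_nm > self.start_nm:
            raise InvalidGridError(
                f"grid must be increasing: start={self.start_nm}, end={self.end_nm}"
            )

    @property
    def spacing_nm(self) -> float:
        return (self.end_nm - self.start_nm) / (self.n_samples - 1)

    @property
    def values(self) -> np.ndarray:
        return np.linspace(self.start_nm, self.end_nm, self.n_samples)

    def nearest_index(self, wavelength_nm: float) -> int:
        """Index of the grid sample closest to ``wavelength_nm``."""
        k = int(round((wavelength_nm - self.start_nm) / self.spacing_nm))
        return min(max(k, 0), self.n_samples - 1)

    def to_dict(self) -> dict:
        return {"start": self.start_nm, "end": self.end_nm, "n": self.n_samples}

    @classmethod
    def from_dict(cls, d: dict) -> "WavelengthGrid":
        return cls(float(d["start"]), float(d["end"]), int(d["n"]))

    @classmethod
    def from_values(cls, values, tol_nm: float = 1e-6) -> "WavelengthGrid":
        """Build a grid from an explicit wavelength list, requiring uniformity.

        Raises
        ------
        InvalidGridError
            If the values are not strictly increasing and uniformly spaced to
            within ``tol_nm``.
        """
        values = np.asarray(values, dtype=float)
        if values.ndim != 1 or values.size < 2:
            raise InvalidGridError("need a 1-D list of >= 2 wavelengths")
        steps = np.diff(values)
        if np.any(steps <= 0):
            raise InvalidGridError("wavelengths must be strictly increasing")
        if np.ptp(steps) > tol_nm:
            raise InvalidGridError(
                f"wavelengths not uniform: spacing varies by {np.ptp(steps):.3g} nm"
            )
        return cls(float(values[0]), float(values[-1]), int(values.size))


#: Instrument default: 400-1000 nm in 361 uniform samples.
DEFAULT_GRID = WavelengthGrid(400.0, 1000.0, 361)


@dataclass(frozen=True)
class BandWindow:
    """Closed wavelength interval [lo_nm, hi_nm] used for band statistics."""

    lo_nm: float
    hi_nm: float

    def __post_init__(self):
        if not self.lo_nm < self.hi_nm:
            raise ValueError(f"band requires lo < hi, got [{self.lo_nm}, {self.hi_nm}]")


#: Near-infrared plasmon band of large gold nanorods.
NP_BAND = BandWindow(833.0, 988.0)


@dataclass(frozen=True)
class PreprocessConfig:
    """Per-spectrum preprocessing: truncate, smooth, max-normalize.

    ``cutoff_nm`` discards the noisy short-wavelength end of each spectrum;
    ``sg_window``/``sg_order`` parameterize the Savitzky-Golay filter.  The
    defaults (11-sample window, cubic) suppress shot noise while preserving
    plasmon peaks a few tens of nm wide on a 5/3 nm grid.
    """

    cutoff_nm: float = 566.0
    sg_window: int = 11
    sg_order: int = 3

    def to_dict(self) -> dict:
        return {
            "cutoff_nm": self.cutoff_nm,
            "sg_window": self.sg_window,
            "sg_order": self.sg_order,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(
            float(d.get("cutoff_nm", 566.0)),
            int(d.get("sg_window", 11)),
            int(d.get("sg_order", 3)),
        )


def build_grid(start_nm: float, end_nm: float, n_samples: int) -> WavelengthGrid:
    """Uniform inclusive wavelength grid from ``start_nm`` to ``end_nm``."""
    return WavelengthGrid(float(start_nm), float(end_nm), int(n_samples))


def truncate_to_cutoff(spectrum, grid: WavelengthGrid, cutoff_nm: float):
    """Drop all samples below ``cutoff_nm``.

    Returns the retained sub-spectrum (wavelength >= cutoff, order preserved)
    together with the matching sub-grid.

    Raises
    ------
    ValueError
        If the cutoff lies beyond the last grid sample (empty result).
    """
    spectrum = np.asarray(spectrum)
    if spectrum.shape[-1] != grid.n_samples:
        raise InvalidGridError(
            f"spectrum has {spectrum.shape[-1]} samples, grid {grid.n_samples}"
        )
    if cutoff_nm > grid.end_nm:
        raise ValueError(f"cutoff {cutoff_nm} nm is beyond grid end {grid.end_nm} nm")
    keep = grid.values >= cutoff_nm
    values = grid.values[keep]
    sub = spectrum[..., keep]
    if values.size == 1:
        # single-sample result: cannot form a WavelengthGrid (needs n >= 2)
        return sub, values
    subgrid = WavelengthGrid.from_values(values)
    return sub, subgrid


def smooth_savgol(spectrum, window_len: int = 11, poly_order: int = 3):
    """Savitzky-Golay smoothing (local least-squares polynomial fit).

    Boundary samples are smoothed by fitting the edge polynomial rather than
    padding, so polynomials of degree <= ``poly_order`` pass through exactly.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    n = spectrum.shape[-1]
    if window_len % 2 == 0 or window_len <= poly_order or window_len > n:
        raise ValueError(
            f"window_len must be odd, > poly_order and <= {n}; "
            f"got window_len={window_len}, poly_order={poly_order}"
        )
    return savgol_filter(spectrum, window_len, poly_order, axis=-1, mode="interp")


def normalize_max(spectrum):
    """Scale a spectrum (or stack of spectra, last axis) to unit maximum."""
    spectrum = np.asarray(spectrum, dtype=float)
    if not np.all(np.isfinite(spectrum)):
        raise DegenerateSpectrumError("spectrum contains non-finite values")
    peak = spectrum.max(axis=-1, keepdims=True)
    if np.any(peak <= 0):
        raise DegenerateSpectrumError("spectrum maximum must be > 0 to normalize")
    return spectrum / peak


def band_indices(grid: WavelengthGrid, band: BandWindow) -> np.ndarray:
    """Indices of grid samples whose wavelength lies in [lo, hi] inclusive."""
    values = grid.values
    mask = (values >= band.lo_nm) & (values <= band.hi_nm)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"band [{band.lo_nm}, {band.hi_nm}] nm contains no grid samples")
    return idx


def band_mean(spectrum, grid: WavelengthGrid, band: BandWindow):
    """Arithmetic mean of the samples falling inside ``band`` (inclusive)."""
    spectrum = np.asarray(spectrum)
    idx = band_indices(grid, band)
    return spectrum[..., idx].mean(axis=-1)


def preprocess_spectra(spectra, grid: WavelengthGrid, config: PreprocessConfig):
    """Apply the canonical truncate -> smooth -> max-normalize chain.

    ``spectra`` may be a single spectrum or an (n, bands) stack.  Returns
    ``(processed, subgrid)`` where ``processed`` rows each have max 1.
    """
    sub, subgrid = truncate_to_cutoff(np.asarray(spectra, dtype=float), grid, config.cutoff_nm)
    smoothed = smooth_savgol(sub, config.sg_window, config.sg_order)
    return normalize_max(smoothed), subgrid
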