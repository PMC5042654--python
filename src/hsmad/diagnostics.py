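"""Diagnostic evaluation: confusion counts, sensitivity/specificity with
log-method confidence intervals, and the single-particle point-spread check.

The log-method interval for a proportion p = a/n places the normal
approximation on ln p: SE(ln p) = sqrt(1/a - 1/n), CI = p * exp(+-z SE),
capped above at 1.  It is the standard ratio-scale interval for proportions
near 1, where the plain Wald interval overshoots.

A diffraction-limited point source through the objective is well
approximated by a Gaussian spot with sigma = 0.21 * lambda / NA, which gives
0.25 um at 910 nm and NA 0.75 — an isolated detected pixel whose band-mean
intensity profile matches that Gaussian is consistent with a single particle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_envi import HyperCube
from .spectral_core import BandWindow, NP_BAND, band_mean

__all__ = [
    "ConfusionCounts",
    "DiagnosticResult",
    "PsfModel",
    "confusion_from_truth",
    "sens_spec",
    "log_method_ci",
    "psf_sigma",
    "single_particle_check",
]

#: Gaussian approximation constant for a diffraction-limited PSF.
PSF_GAUSSIAN_CONSTANT = 0.21


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be nonnegative")
        if self.tp + self.fp + self.tn + self.fn == 0:
            raise ValueError("at least one scored pixel required")


@dataclass(frozen=True)
class DiagnosticResult:
    sensitivity: float | None
    specificity: float | None
    sensitivity_ci95: tuple | None
    specificity_ci95: tuple | None
    counts: ConfusionCounts


@dataclass(frozen=True)
class PsfModel:
    """Gaussian point-spread model sampled on the camera pixel lattice."""

    wavelength_nm: float = 910.0
    numerical_aperture: float = 0.75
    pixel_pitch_nm: tuple = (410.0, 408.0)

    @property
    def sigma_nm(self) -> float:
        return psf_sigma(self.wavelength_nm, self.numerical_aperture)


def confusion_from_truth(detection, truth_np_mask, eval_mask=None) -> ConfusionCounts:
    """2x2 confusion counts of a detection map against a truth mask.

    By default only candidate pixels are scored (low-intensity pixels were
    never classified); pass ``eval_mask`` to widen or narrow the scored set.
    """
    truth = np.asarray(truth_np_mask, dtype=bool)
    if truth.shape != detection.assignments.shape:
        raise ValueError("truth mask shape does not match detection map")
    if eval_mask is None:
        eval_mask = detection.candidate_mask
    eval_mask = np.asarray(eval_mask, dtype=bool)
    if not eval_mask.any():
        raise ValueError("evaluation mask selects no pixels")
    pred = detection.np_mask[eval_mask]
    true = truth[eval_mask]
    return ConfusionCounts(
        tp=int((pred & true).sum()),
        fp=int((pred & ~true).sum()),
        tn=int((~pred & ~true).sum()),
        fn=int((~pred & true).sum()),
    )


def log_method_ci(numerator: int, denominator: int, z: float = 1.96):
    """Log-method confidence interval for the proportion numerator/denominator.

    Returns ``(lo, hi)`` with ``hi`` capped at 1.  With a zero numerator the
    log method is undefined; the rule-of-three upper bound 3/n is returned
    as ``(0.0, min(1, 3/n))``.
    """
    a, n = int(numerator), int(denominator)
    if n <= 0 or a > n or a < 0:
        raise ValueError(f"need 0 <= numerator <= denominator, got {a}/{n}")
    if a == 0:
        return 0.0, min(1.0, 3.0 / n)
    p = a / n
    se = np.sqrt(1.0 / a - 1.0 / n)
    lo = p * np.exp(-z * se)
    hi = p * np.exp(z * se)
    return float(lo), float(min(hi, 1.0))


def sens_spec(counts: ConfusionCounts, z: float = 1.96) -> DiagnosticResult:
    """Point sensitivity/specificity with log-method 95% intervals.

    A metric whose denominator is zero is reported as ``None``; both
    denominators zero is an error.
    """
    sens = spec = sens_ci = spec_ci = None
    if counts.tp + counts.fn > 0:
        sens = counts.tp / (counts.tp + counts.fn)
        sens_ci = log_method_ci(counts.tp, counts.tp + counts.fn, z)
    if counts.tn + counts.fp > 0:
        spec = counts.tn / (counts.tn + counts.fp)
        spec_ci = log_method_ci(counts.tn, counts.tn + counts.fp, z)
    if sens is None and spec is None:
        raise ValueError("no positives and no negatives to score")
    return DiagnosticResult(sens, spec, sens_ci, spec_ci, counts)


def psf_sigma(wavelength_nm: float, numerical_aperture: float) -> float:
    """Gaussian PSF standard deviation in nm: sigma = 0.21 * lambda / NA."""
    if not 0 < numerical_aperture <= 1.5:
        raise ValueError("numerical aperture must be in (0, 1.5]")
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    return PSF_GAUSSIAN_CONSTANT * wavelength_nm / numerical_aperture


def _profile_rmse(profile, offsets_px, pitch_nm, sigma_nm):
    """RMSE between a max-normalized profile and the model Gaussian."""
    profile = np.asarray(profile, dtype=float)
    profile = profile - profile.min()
    peak = profile.max()
    if peak <= 0:
        return np.inf
    profile = profile / peak
    model = np.exp(-0.5 * (offsets_px * pitch_nm / sigma_nm) ** 2)
    return float(np.sqrt(np.mean((profile - model) ** 2)))


def single_particle_check(
    cube: HyperCube,
    detection,
    pixel,
    psf_model: PsfModel = PsfModel(),
    band: BandWindow = NP_BAND,
    half_width_px: int = 4,
    isolation_radius_px: int = 5,
):
    """Compare the intensity spot around a detected pixel with the model PSF.

    Extracts horizontal and vertical band-mean intensity profiles of
    half-width ``half_width_px`` through the pixel, max-normalizes them, and
    measures the RMSE against the discrete model Gaussian.  The report marks
    the spot *consistent with a single particle* iff both RMSEs are <= 0.1
    and the profile peak sits within 1 px of the detected pixel.

    A pixel with another NP-positive detection within ``isolation_radius_px``
    is not isolated and yields ``{"isolated": False, "consistent": None}``.
    NP-positive pixels 8-connected to the target belong to the same sub-pixel
    spot and do not break isolation.
    """
    from scipy.ndimage import label as cc_label

    row, col = pixel
    if not detection.np_mask[row, col]:
        raise ValueError("pixel is not NP-positive")

    components, _ = cc_label(detection.np_mask, structure=np.ones((3, 3), int))
    np_mask = detection.np_mask & (components != components[row, col])
    rr, cc = np.nonzero(np_mask)
    if rr.size and np.min(np.hypot(rr - row, cc - col)) <= isolation_radius_px:
        return {"isolated": False, "consistent": None}

    h, w = detection.assignments.shape
    r0, r1 = max(0, row - half_width_px), min(h, row + half_width_px + 1)
    c0, c1 = max(0, col - half_width_px), min(w, col + half_width_px + 1)
    band_img = band_mean(cube.data.astype(float), cube.grid, band)
    horiz = band_img[row, c0:c1]
    vert = band_img[r0:r1, col]

    pitch_row, pitch_col = psf_model.pixel_pitch_nm
    sigma = psf_model.sigma_nm
    off_h = np.arange(c0, c1) - col
    off_v = np.arange(r0, r1) - row
    rmse_h = _profile_rmse(horiz, off_h, pitch_col, sigma)
    rmse_v = _profile_rmse(vert, off_v, pitch_row, sigma)
    peak_offset = max(
        abs(int(np.argmax(horiz)) + c0 - col), abs(int(np.argmax(vert)) + r0 - row)
    )
    return {
        "isolated": True,
        "rmse_h": rmse_h,
        "rmse_v": rmse_v,
        "peak_offset_px": peak_offset,
        "consistent": bool(rmse_h <= 0.1 and rmse_v <= 0.1 and peak_offset <= 1),
    }
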