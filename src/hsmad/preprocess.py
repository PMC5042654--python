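"""Vignetting correction and adaptive intensity segmentation.

Dark-field illumination falls off radially following the cosine-fourth law:
brightness at a point a physical distance R (mm) off the optical axis is
attenuated by cos^4(arctan(R/d)).  Correction divides each pixel by that
factor, with d fitted once per instrument (2 mm at 40x).

Segmentation then splits each field of view into background / tissue /
candidate-nanoparticle pixels from the histogram of per-pixel mean
intensities: the background threshold sits at the first local minimum of the
(510-bin, step-resampled) histogram scaled by ``alpha``; the candidate
threshold sits at the dominant tissue peak scaled by ``beta``.  Both scale
factors are slightly above 1 and are per-study tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .errors import SegmentationError
from .io_envi import HyperCube

__all__ = [
    "Label",
    "VignetteModel",
    "ThresholdParams",
    "mean_intensity",
    "vignette_correct",
    "adaptive_thresholds",
    "segment",
]


class Label(IntEnum):
    """Per-pixel segmentation classes."""

    BACKGROUND = 0
    TISSUE = 1
    CANDIDATE = 2


@dataclass(frozen=True)
class VignetteModel:
    """cos^4 radial falloff model in physical units.

    ``d_mm`` is the fitted falloff distance; ``pixel_pitch_nm`` the per-axis
    sampling resolution (row pitch, col pitch), 410 x 408 nm at 40x.
    ``center`` defaults to the image centre and may be fractional.
    """

    d_mm: float = 2.0
    pixel_pitch_nm: tuple = (410.0, 408.0)
    center: tuple | None = None

    def __post_init__(self):
        if self.d_mm <= 0:
            raise ValueError("falloff distance d must be > 0")
        if any(p <= 0 for p in self.pixel_pitch_nm):
            raise ValueError("pixel pitch must be > 0")

    def attenuation(self, shape) -> np.ndarray:
        """Per-pixel cos^4(arctan(R/d)) attenuation map for an image shape."""
        h, w = shape[:2]
        cy, cx = self.center if self.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
        prow, pcol = self.pixel_pitch_nm
        # physical offsets in mm (1 nm = 1e-6 mm)
        dy = (np.arange(h) - cy)[:, None] * prow * 1e-6
        dx = (np.arange(w) - cx)[None, :] * pcol * 1e-6
        r_mm = np.hypot(dy, dx)
        return np.cos(np.arctan(r_mm / self.d_mm)) ** 4


@dataclass(frozen=True)
class ThresholdParams:
    """Adaptive-histogram parameters: 510 bins, 5-unit resample, alpha/beta."""

    n_bins: int = 510
    resample_step: float = 5.0
    alpha: float = 1.05
    beta: float = 1.5

    def __post_init__(self):
        if self.n_bins < 10:
            raise ValueError("n_bins must be >= 10")
        if self.alpha < 1 or self.beta < 1:
            raise ValueError("alpha and beta must be >= 1")
        if self.resample_step <= 0:
            raise ValueError("resample_step must be > 0")


def mean_intensity(cube: HyperCube) -> np.ndarray:
    """Per-pixel arithmetic mean intensity across all bands."""
    return cube.data.mean(axis=2)


def vignette_correct(cube_or_image, model: VignetteModel):
    """Divide intensities by the cos^4 falloff; the centre pixel is unchanged.

    Accepts a :class:`HyperCube` (returns a corrected cube) or a 2-D image
    (returns a corrected image).  The correction factor is >= 1 everywhere.
    """
    if isinstance(cube_or_image, HyperCube):
        att = model.attenuation(cube_or_image.data.shape)
        return HyperCube(cube_or_image.data / att[:, :, None], cube_or_image.grid)
    image = np.asarray(cube_or_image, dtype=float)
    return image / model.attenuation(image.shape)


def _resampled_histogram(image: np.ndarray, params: ThresholdParams):
    """510-bin histogram over [0, max], linearly re-read every step units."""
    flat = image.ravel()
    top = float(flat.max())
    counts, edges = np.histogram(flat, bins=params.n_bins, range=(0.0, top))
    centers = 0.5 * (edges[:-1] + edges[1:])
    xs = np.arange(0.0, top + params.resample_step, params.resample_step)
    ys = np.interp(xs, centers, counts.astype(float))
    return xs, ys


def adaptive_thresholds(intensity_image, params: ThresholdParams = ThresholdParams()):
    """Background and candidate thresholds from the intensity histogram.

    Returns ``(bg_threshold, candidate_threshold)`` where the background
    threshold is the intensity of the first strict local minimum of the
    resampled histogram (after its first local maximum) times ``alpha``, and
    the candidate threshold is the intensity of the highest histogram peak
    above the background threshold times ``beta``.

    Raises
    ------
    SegmentationError
        If the histogram is constant or exhibits no local minimum; the
        resampled histogram is attached for diagnosis.
    """
    image = np.asarray(intensity_image, dtype=float)
    if image.max() <= image.min():
        raise SegmentationError("constant image: no histogram structure")
    xs, ys = _resampled_histogram(image, params)

    # first substantial local maximum, scanning upward from zero intensity;
    # a handful of dark outlier pixels must not pass for the background mode
    min_height = 0.05 * ys.max()
    peak_i = None
    for i in range(len(ys)):
        left = ys[i - 1] if i > 0 else -np.inf
        right = ys[i + 1] if i + 1 < len(ys) else -np.inf
        if ys[i] >= left and ys[i] > right and ys[i] >= min_height:
            peak_i = i
            break
    if peak_i is None:
        raise SegmentationError("no local maximum in histogram", histogram=(xs, ys))

    # first strict local minimum after that maximum
    min_i = None
    for i in range(peak_i + 1, len(ys) - 1):
        if ys[i] < ys[i - 1] and ys[i] <= ys[i + 1]:
            min_i = i
            break
    if min_i is None:
        raise SegmentationError(
            "no local minimum after background peak", histogram=(xs, ys)
        )
    bg_threshold = xs[min_i] * params.alpha

    above = xs > bg_threshold
    if not np.any(above):
        raise SegmentationError("no histogram mass above background", histogram=(xs, ys))
    tissue_peak = xs[above][np.argmax(ys[above])]
    candidate_threshold = tissue_peak * params.beta
    if not bg_threshold < candidate_threshold:
        raise SegmentationError(
            "thresholds collapsed (background >= candidate)", histogram=(xs, ys)
        )
    return float(bg_threshold), float(candidate_threshold)


def segment(intensity_image, thresholds) -> np.ndarray:
    """Label pixels background / tissue / candidate by intensity.

    Boundary values (exactly equal to a threshold) are tissue.
    """
    bg, cand = thresholds
    if not bg < cand:
        raise ValueError("background threshold must be below candidate threshold")
    image = np.asarray(intensity_image, dtype=float)
    labels = np.full(image.shape, Label.TISSUE, dtype=np.uint8)
    labels[image < bg] = Label.BACKGROUND
    labels[image > cand] = Label.CANDIDATE
    return labels
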