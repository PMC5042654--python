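"""Biodistribution statistics.

The per-field measure of nanoparticle uptake is the *relative NP signal*:
the sum of the plasmon-band mean intensity over NP-positive pixels, divided
by the number of tissue pixels (all pixels minus background) and by the
median plasmon-band signal over the NP-positive pixels.  The numerator and
the median scale together, so the measure is invariant to global intensity
changes; dividing by tissue area makes fields of view comparable.  For small
regions of interest, where the median is unstable, the simpler *pixel
coverage* (NP-positive pixels over non-background pixels) is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import numpy as np

from .errors import UndefinedQuantityError
from .io_envi import HyperCube
from .spectral_core import BandWindow, NP_BAND, band_mean

__all__ = ["QuantResult", "relative_np_signal", "pixel_coverage", "aggregate_fovs"]


@dataclass(frozen=True)
class QuantResult:
    """Quantification summary for one field of view / ROI."""

    relative_signal: float
    pixel_coverage: float
    n_np_pixels: int
    n_tissue_pixels: int
    band: BandWindow


def relative_np_signal(cube: HyperCube, detection, band: BandWindow = NP_BAND) -> float:
    """Relative NP signal of one field of view.

    sum over NP+ pixels of the band-mean intensity, divided by the tissue
    pixel count (total minus background) and by the median NP+ band-mean.
    Returns 0.0 when there are no NP-positive pixels.

    Raises
    ------
    UndefinedQuantityError
        If the field contains no tissue pixels at all.
    """
    n_total = detection.assignments.size
    n_background = int(detection.background_mask.sum())
    n_tissue = n_total - n_background
    if n_tissue == 0:
        raise UndefinedQuantityError("no non-background pixels in field of view")
    np_mask = detection.np_mask
    if not np_mask.any():
        return 0.0
    signals = band_mean(cube.data[np_mask].astype(float), cube.grid, band)
    return float(signals.sum() / n_tissue / np.median(signals))


def pixel_coverage(detection, roi_map, roi_label: int) -> float:
    """NP-positive fraction of the non-background pixels inside one ROI."""
    roi_map = np.asarray(roi_map)
    if roi_map.shape != detection.assignments.shape:
        raise ValueError("ROI map shape does not match detection map")
    roi = roi_map == roi_label
    if not roi.any():
        raise UndefinedQuantityError(f"ROI label {roi_label} not present")
    denom = int((roi & ~detection.background_mask).sum())
    if denom == 0:
        raise UndefinedQuantityError(f"ROI {roi_label} has no non-background pixels")
    return float((roi & detection.np_mask).sum() / denom)


def aggregate_fovs(values):
    """Mean, sample standard deviation and standard error over fields of view.

    With a single value the spread statistics are unavailable (returned as
    ``None``); sd uses the n-1 denominator and sem = sd / sqrt(n).
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValueError("need at least one value")
    mean = float(values.mean())
    if values.size == 1:
        return mean, None, None
    sd = float(values.std(ddof=1))
    return mean, sd, sd / sqrt(values.size)
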