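"""False-color composites and detection overlays.

The false-color view integrates each pixel's spectrum under three Gaussian
windows centered at the red/green/blue band centers (800.0 / 700.6 /
526.2 nm by default, 80-sample window) and min-max scales each channel
independently.  Detection overlays paint NP-positive pixels in a role color
(orange for the nanoparticle cluster) over the grayscale intensity image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import gaussian as gaussian_window

from .io_envi import HyperCube

__all__ = ["RenderConfig", "false_color_rgb", "detection_overlay"]

#: default overlay colors per role (unit RGB)
DEFAULT_OVERLAY_COLORS = {
    "np": (1.0, 0.55, 0.0),  # orange
    "np_alt": (0.0, 1.0, 1.0),  # cyan (second particle type)
    "np_alt2": (0.0, 1.0, 0.0),  # green (third particle type)
}


@dataclass(frozen=True)
class RenderConfig:
    """Channel band centers (nm), Gaussian window length, overlay colors."""

    band_centers_nm: tuple = (800.0, 700.6, 526.2)
    window_len_samples: int = 80
    overlay_colors: dict = field(default_factory=lambda: dict(DEFAULT_OVERLAY_COLORS))

    def __post_init__(self):
        if self.window_len_samples < 1:
            raise ValueError("window length must be >= 1")


def _channel_weights(grid, center_nm: float, window_len: int) -> np.ndarray:
    """Gaussian weights over the full grid, centered at ``center_nm``.

    The window has length ``window_len`` samples with sigma = (L-1)/5 (the
    common window convention), placed at the nearest grid sample and cropped
    at the grid ends; weights are renormalized to sum 1.
    """
    if not grid.start_nm <= center_nm <= grid.end_nm:
        raise ValueError(f"band center {center_nm} nm outside grid")
    weights = np.zeros(grid.n_samples)
    if window_len == 1:
        weights[grid.nearest_index(center_nm)] = 1.0
        return weights
    win = gaussian_window(window_len, std=(window_len - 1) / 5.0)
    center_idx = grid.nearest_index(center_nm)
    half = (window_len - 1) // 2
    lo = center_idx - half
    for j, wv in enumerate(win):
        k = lo + j
        if 0 <= k < grid.n_samples:
            weights[k] += wv
    return weights / weights.sum()


def _minmax(channel: np.ndarray) -> np.ndarray:
    lo, hi = channel.min(), channel.max()
    if hi <= lo:
        return np.zeros_like(channel)
    return (channel - lo) / (hi - lo)


def false_color_rgb(cube: HyperCube, config: RenderConfig = RenderConfig()) -> np.ndarray:
    """(H, W, 3) float RGB in [0, 1]; each channel scaled independently."""
    channels = []
    for center in config.band_centers_nm:
        w = _channel_weights(cube.grid, center, config.window_len_samples)
        channels.append(_minmax(cube.data.astype(float) @ w))
    return np.stack(channels, axis=-1)


def detection_overlay(
    intensity_image, detection, config: RenderConfig = RenderConfig(), role: str = "np"
) -> np.ndarray:
    """Grayscale intensity with NP-positive pixels painted in the role color."""
    image = np.asarray(intensity_image, dtype=float)
    if image.shape != detection.assignments.shape:
        raise ValueError("intensity image shape does not match detection map")
    gray = _minmax(image)
    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    rgb[detection.np_mask] = config.overlay_colors[role]
    return rgb
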