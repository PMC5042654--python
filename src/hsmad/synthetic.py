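"""Synthetic hyperspectral phantoms with ground truth.

The generator emulates every spectral and spatial phenomenon the detection
pipeline must handle, each with a ground-truth mask:

* tissue blobs carrying mixtures of two broad visible-band stain spectra
  (hematoxylin-like ~560 nm, eosin-like ~620 nm) with log-normal brightness;
* nanoparticles as sub-pixel point sources convolved with the microscope's
  Gaussian PSF, carrying a Lorentzian plasmon line (a narrow ~900 nm
  nanorod-like line by default, red-shifted +80 nm by the mounting medium);
* aggregates carrying hybridized (blue-shifted, split-peak) spectra;
* chromatic-aberration edge artifacts: broad red-shifted lines on a fraction
  of tissue-boundary pixels;
* cos^4 vignetting, then additive Gaussian sensor noise (optionally
  Poisson), clipped at zero.

Everything is deterministic per seed; tissue geometry, particle placement,
edge placement and noise draw from independent child streams so that, e.g.,
changing the particle density leaves the tissue geometry untouched.

No electromagnetic scattering is computed: the Lorentzian is a line-shape
surrogate whose parameters (not physics) are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_erosion, gaussian_filter

from .diagnostics import psf_sigma
from .io_envi import HyperCube
from .preprocess import VignetteModel
from .spectral_core import DEFAULT_GRID, WavelengthGrid

__all__ = [
    "SpectrumModel",
    "PhantomConfig",
    "PhantomTruth",
    "lorentzian_spectrum",
    "gaussian_spectrum",
    "hybridized_spectrum",
    "generate_phantom",
    "preset_config",
]


@dataclass(frozen=True)
class SpectrumModel:
    """Parametric line shape for one scatterer class.

    ``center_nm`` is the intrinsic resonance; the phantom applies the
    mounting-medium red shift on top of it.  ``gamma_nm`` is the Lorentzian
    half-width at half-maximum (FWHM = 2 gamma).
    """

    center_nm: float
    gamma_nm: float
    amplitude: float = 1.0
    baseline: float = 0.0

    def __post_init__(self):
        if self.gamma_nm <= 0 or self.amplitude <= 0:
            raise ValueError("gamma and amplitude must be positive")


def lorentzian_spectrum(center_nm, gamma_nm, amplitude, baseline, grid: WavelengthGrid):
    """baseline + A * gamma^2 / ((lambda - center)^2 + gamma^2) on the grid."""
    if gamma_nm <= 0:
        raise ValueError("gamma must be positive")
    lam = grid.values
    return baseline + amplitude * gamma_nm**2 / ((lam - center_nm) ** 2 + gamma_nm**2)


def gaussian_spectrum(center_nm, sigma_nm, amplitude, grid: WavelengthGrid):
    """Broad Gaussian band used for stain scattering surrogates."""
    lam = grid.values
    return amplitude * np.exp(-0.5 * ((lam - center_nm) / sigma_nm) ** 2)


def hybridized_spectrum(base: SpectrumModel, blue_shift_nm, split_sep_nm, grid):
    """Aggregate (plasmon-hybridized) line: blue-shifted, split in two.

    The sum of two Lorentzians at center - blue_shift +- sep/2; it shows two
    local maxima once the separation exceeds the linewidth (sep > 2 gamma).
    """
    if split_sep_nm < 0:
        raise ValueError("separation must be nonnegative")
    c = base.center_nm - blue_shift_nm
    half = 0.5 * split_sep_nm
    lo = lorentzian_spectrum(c - half, base.gamma_nm, base.amplitude, 0.0, grid)
    hi = lorentzian_spectrum(c + half, base.gamma_nm, base.amplitude, 0.0, grid)
    return base.baseline + 0.5 * (lo + hi) * 2.0 / (1.0 + lorentzian_overlap(split_sep_nm, base.gamma_nm))


def lorentzian_overlap(sep_nm: float, gamma_nm: float) -> float:
    """Peak cross-talk of two unit Lorentzians a distance ``sep`` apart."""
    return gamma_nm**2 / (sep_nm**2 + gamma_nm**2)


@dataclass(frozen=True)
class PhantomConfig:
    """Study conditions for one synthetic field of view.

    Amplitudes are in detector counts.  ``np_density`` is the fraction of
    tissue pixels seeded with a single particle; ``noise_sigma_rel`` scales
    the Gaussian sensor noise relative to the particle peak amplitude.
    """

    height: int = 256
    width: int = 256
    grid: WavelengthGrid = DEFAULT_GRID
    seed: int = 0
    # tissue
    tissue_fraction: float = 0.25
    tissue_smooth_px: float = 12.0
    tissue_amp_log_mean: float = float(np.log(1100.0))
    tissue_amp_log_sigma: float = 0.35
    stain_centers_nm: tuple = (560.0, 620.0)
    stain_sigmas_nm: tuple = (85.0, 90.0)
    # particles
    np_model: SpectrumModel = SpectrumModel(center_nm=820.0, gamma_nm=30.0, amplitude=8000.0)
    second_model: SpectrumModel | None = None
    np_density: float = 0.01
    aggregate_fraction: float = 0.1
    hybrid_blue_shift_nm: float = 120.0
    hybrid_split_sep_nm: float = 140.0
    medium_shift_nm: float = 80.0
    psf_wavelength_nm: float = 910.0
    psf_numerical_aperture: float = 0.75
    # artifacts
    edge_artifact_rate: float = 0.02
    edge_model: SpectrumModel = SpectrumModel(center_nm=835.0, gamma_nm=60.0, amplitude=3000.0)
    # optics / sensor
    vignette: VignetteModel = VignetteModel()
    background_level: float = 20.0
    noise_sigma_rel: float = 0.05
    poisson_noise: bool = False

    def __post_init__(self):
        for name in ("np_density", "aggregate_fraction", "edge_artifact_rate", "tissue_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class PhantomTruth:
    """Ground-truth masks and particle positions for one phantom."""

    background: np.ndarray
    tissue: np.ndarray
    np_single: np.ndarray
    np_second: np.ndarray
    np_aggregate: np.ndarray
    #: ambiguous ring around every planted particle: pixels receiving real
    #: particle light but below the truth threshold; excluded from scoring
    np_halo: np.ndarray
    edge_artifact: np.ndarray
    np_positions: np.ndarray  # (n, 2) fractional (row, col)
    np_second_positions: np.ndarray
    shifted_np_center_nm: float


def _tissue_mask(rng, h, w, fraction, smooth_px):
    """Blob geometry: thresholded smoothed Gaussian random field."""
    if fraction <= 0:
        return np.zeros((h, w), dtype=bool)
    noise = rng.standard_normal((h, w))
    smooth = gaussian_filter(noise, smooth_px)
    thresh = np.quantile(smooth, 1.0 - fraction)
    return smooth > thresh


def _stamp_spots(shape, positions, sigma_px, reach=4):
    """Sum of unit-peak Gaussian spots at fractional positions."""
    weights = np.zeros(shape)
    h, w = shape
    srow, scol = sigma_px
    for r, c in positions:
        r0, r1 = max(0, int(r) - reach), min(h, int(r) + reach + 1)
        c0, c1 = max(0, int(c) - reach), min(w, int(c) + reach + 1)
        rows = np.arange(r0, r1)[:, None]
        cols = np.arange(c0, c1)[None, :]
        weights[r0:r1, c0:c1] += np.exp(
            -0.5 * (((rows - r) / srow) ** 2 + ((cols - c) / scol) ** 2)
        )
    return weights


def _place_particles(rng, interior_pixels, n):
    """Pick n interior pixels and jitter to sub-pixel positions."""
    if n == 0 or len(interior_pixels) == 0:
        return np.empty((0, 2))
    idx = rng.choice(len(interior_pixels), size=min(n, len(interior_pixels)), replace=False)
    base = interior_pixels[idx].astype(float)
    return base + rng.uniform(-0.5, 0.5, size=base.shape)


#: a pixel is truth-positive when it receives a majority share of a
#: particle's peak point-source energy; pixels with any appreciable but
#: sub-majority share are genuinely mixed and land in the don't-care halo
TRUTH_WEIGHT_THRESHOLD = 0.5
HALO_WEIGHT_THRESHOLD = 0.05


def generate_phantom(config: PhantomConfig):
    """Build one phantom cube and its ground truth.  Deterministic per seed."""
    h, w = config.height, config.width
    grid = config.grid
    ss = np.random.SeedSequence(config.seed)
    rng_tissue, rng_np, rng_edge, rng_noise = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    cube = np.full((h, w, grid.n_samples), float(config.background_level), dtype=np.float64)

    # --- tissue: stain-mixture spectra with log-normal brightness ---
    tissue = _tissue_mask(rng_tissue, h, w, config.tissue_fraction, config.tissue_smooth_px)
    n_tissue = int(tissue.sum())
    if n_tissue:
        stains = np.stack(
            [
                gaussian_spectrum(c, s, 1.0, grid)
                for c, s in zip(config.stain_centers_nm, config.stain_sigmas_nm)
            ]
        )
        mix = rng_tissue.uniform(0.0, 1.0, size=n_tissue)
        amps = rng_tissue.lognormal(
            config.tissue_amp_log_mean, config.tissue_amp_log_sigma, size=n_tissue
        )
        spectra = mix[:, None] * stains[0] + (1.0 - mix)[:, None] * stains[1]
        cube[tissue] += amps[:, None] * spectra

    # --- particles: PSF-convolved sub-pixel point sources ---
    pitch = config.vignette.pixel_pitch_nm
    sigma_nm = psf_sigma(config.psf_wavelength_nm, config.psf_numerical_aperture)
    sigma_px = (sigma_nm / pitch[0], sigma_nm / pitch[1])

    interior = np.argwhere(binary_erosion(tissue, iterations=2)) if n_tissue else np.empty((0, 2), int)
    n_np = int(round(config.np_density * n_tissue))
    n_agg = int(round(config.aggregate_fraction * n_np))
    n_single = n_np - n_agg

    positions = _place_particles(rng_np, interior, n_np)
    single_pos, agg_pos = positions[:n_single], positions[n_single:]

    shifted_center = config.np_model.center_nm + config.medium_shift_nm
    np_line = lorentzian_spectrum(
        shifted_center, config.np_model.gamma_nm, config.np_model.amplitude,
        config.np_model.baseline, grid,
    )
    single_w = _stamp_spots((h, w), single_pos, sigma_px)
    cube += single_w[:, :, None] * np_line[None, None, :]

    second_pos = np.empty((0, 2))
    np_second = np.zeros((h, w), dtype=bool)
    if config.second_model is not None:
        second_pos = _place_particles(rng_np, interior, n_np)
        second_line = lorentzian_spectrum(
            config.second_model.center_nm + config.medium_shift_nm,
            config.second_model.gamma_nm,
            config.second_model.amplitude,
            config.second_model.baseline,
            grid,
        )
        second_w = _stamp_spots((h, w), second_pos, sigma_px)
        cube += second_w[:, :, None] * second_line[None, None, :]
        np_second = second_w > TRUTH_WEIGHT_THRESHOLD

    agg_w = np.zeros((h, w))
    if len(agg_pos):
        shifted_model = replace(
            config.np_model,
            center_nm=shifted_center,
            amplitude=config.np_model.amplitude * 1.5,
        )
        hybrid = hybridized_spectrum(
            shifted_model, config.hybrid_blue_shift_nm, config.hybrid_split_sep_nm, grid
        )
        agg_w = _stamp_spots((h, w), agg_pos, (sigma_px[0] * 1.5, sigma_px[1] * 1.5))
        cube += agg_w[:, :, None] * hybrid[None, None, :]

    # --- chromatic-aberration edge artifacts on the tissue boundary ---
    boundary = tissue & ~binary_erosion(tissue)
    edge_mask = np.zeros((h, w), dtype=bool)
    edge_pixels = np.argwhere(boundary)
    n_edge = int(round(config.edge_artifact_rate * len(edge_pixels)))
    if n_edge:
        idx = rng_edge.choice(len(edge_pixels), size=n_edge, replace=False)
        edge_mask[tuple(edge_pixels[idx].T)] = True
        edge_line = lorentzian_spectrum(
            config.edge_model.center_nm + config.medium_shift_nm,
            config.edge_model.gamma_nm,
            config.edge_model.amplitude,
            config.edge_model.baseline,
            grid,
        )
        cube[edge_mask] += edge_line

    # --- optics and sensor ---
    cube *= config.vignette.attenuation((h, w))[:, :, None]
    if config.poisson_noise:
        cube = rng_noise.poisson(np.maximum(cube, 0.0)).astype(np.float64)
    sigma = config.noise_sigma_rel * config.np_model.amplitude
    if sigma > 0:
        cube += rng_noise.normal(0.0, sigma, size=cube.shape)
    np.clip(cube, 0.0, None, out=cube)

    np_single = single_w > TRUTH_WEIGHT_THRESHOLD
    np_aggregate = agg_w > TRUTH_WEIGHT_THRESHOLD
    np_single &= ~np_aggregate
    np_second &= ~np_single & ~np_aggregate
    total_w = single_w + agg_w
    if config.second_model is not None:
        total_w = total_w + second_w
    np_halo = (total_w > HALO_WEIGHT_THRESHOLD) & ~np_single & ~np_aggregate & ~np_second
    truth = PhantomTruth(
        background=~tissue,
        tissue=tissue,
        np_single=np_single,
        np_second=np_second,
        np_aggregate=np_aggregate,
        np_halo=np_halo,
        edge_artifact=edge_mask,
        np_positions=single_pos,
        np_second_positions=second_pos,
        shifted_np_center_nm=shifted_center,
    )
    return HyperCube(cube.astype(np.float32), grid), truth


def preset_config(name: str, seed: int = 0, height: int = 256, width: int = 256, **overrides) -> PhantomConfig:
    """Named study conditions.

    ``lgnr``     narrow ~900 nm nanorod-like line in stained tissue (default).
    ``nanoshell`` broad ~800 nm shell-like line in stained tissue.
    ``gns``      ~550 nm nanosphere-like line, unstained-tissue surrogate.
    ``mixture``  two particle types (narrow 900 + broad 800) on a bare slide.
    ``control``  nanoparticle-free tissue with edge artifacts (negative control).
    """
    base = dict(height=height, width=width, seed=seed)
    if name == "lgnr":
        cfg = PhantomConfig(**base)
    elif name == "nanoshell":
        cfg = PhantomConfig(
            np_model=SpectrumModel(center_nm=720.0, gamma_nm=100.0, amplitude=8000.0), **base
        )
    elif name == "gns":
        cfg = PhantomConfig(
            np_model=SpectrumModel(center_nm=470.0, gamma_nm=50.0, amplitude=8000.0),
            stain_centers_nm=(600.0,),
            stain_sigmas_nm=(150.0,),
            **base,
        )
    elif name == "mixture":
        cfg = PhantomConfig(
            tissue_fraction=0.5,
            tissue_amp_log_mean=float(np.log(1.0)),  # negligible substrate
            tissue_amp_log_sigma=0.1,
            np_model=SpectrumModel(center_nm=820.0, gamma_nm=30.0, amplitude=8000.0),
            second_model=SpectrumModel(center_nm=720.0, gamma_nm=100.0, amplitude=8000.0),
            np_density=0.02,
            aggregate_fraction=0.0,
            edge_artifact_rate=0.0,
            **base,
        )
    elif name == "control":
        cfg = PhantomConfig(np_density=0.0, aggregate_fraction=0.0, **base)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides) if overrides else cfg
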