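"""Spectral cluster library learning.

Candidate pixels pooled from training images are clustered with standard
k-means (k-means++ initialization, multiple restarts, fixed seed).  One of
the learned centroids carries the nanoparticle plasmon peak and is selected
automatically by the location of its spectral maximum; an optional extra
centroid — the chromatic-aberration cluster, averaged from pixels falsely
detected in nanoparticle-free control images — is appended manually to
absorb red-shifted edge artifacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

from .errors import EmptyTrainingError, NPClusterSelectionError
from .io_envi import HyperCube
from .preprocess import Label
from .spectral_core import (
    BandWindow,
    NP_BAND,
    PreprocessConfig,
    WavelengthGrid,
    band_mean,
    preprocess_spectra,
)

__all__ = [
    "SpectralClusterLibrary",
    "collect_training_pixels",
    "train_kmeans",
    "build_aberration_cluster",
    "assemble_library",
]

ROLES = ("stain", "intermediate", "np", "aberration")


@dataclass
class SpectralClusterLibrary:
    """Ordered, max-normalized centroid spectra with role tags.

    ``centroids`` is an (m, bands) array on the truncated grid; ``np_index``
    points at the nanoparticle centroid.  ``metadata`` records how the
    library was trained (k, seed, cutoff) for provenance.
    """

    centroids: np.ndarray
    roles: list
    np_index: int
    grid: WavelengthGrid
    preprocess: PreprocessConfig
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.centroids = np.atleast_2d(np.asarray(self.centroids, dtype=float))
        if len(self.roles) != self.centroids.shape[0]:
            raise ValueError("one role per centroid required")
        if not 0 <= self.np_index < self.centroids.shape[0]:
            raise ValueError(f"np_index {self.np_index} out of range")
        if self.centroids.shape[1] != self.grid.n_samples:
            raise ValueError("centroid length does not match grid")
        peaks = self.centroids.max(axis=1)
        if not np.allclose(peaks, 1.0, atol=1e-9):
            raise ValueError("centroids must be max-normalized")

    @property
    def n_clusters(self) -> int:
        return self.centroids.shape[0]

    @property
    def aberration_indices(self) -> list:
        return [i for i, r in enumerate(self.roles) if r == "aberration"]

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "cutoff_nm": self.preprocess.cutoff_nm,
            "sg_window": self.preprocess.sg_window,
            "sg_order": self.preprocess.sg_order,
            "np_index": int(self.np_index),
            "centroids": [
                {"role": role, "values": row.tolist()}
                for role, row in zip(self.roles, self.centroids)
            ],
            **{k: v for k, v in self.metadata.items() if k in ("k", "seed")},
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "SpectralClusterLibrary":
        pp = PreprocessConfig(
            cutoff_nm=float(d.get("cutoff_nm", 566.0)),
            sg_window=int(d.get("sg_window", 11)),
            sg_order=int(d.get("sg_order", 3)),
        )
        return cls(
            centroids=np.array([c["values"] for c in d["centroids"]], dtype=float),
            roles=[c["role"] for c in d["centroids"]],
            np_index=int(d["np_index"]),
            grid=WavelengthGrid.from_dict(d["grid"]),
            preprocess=pp,
            metadata={k: d[k] for k in ("k", "seed") if k in d},
        )

    @classmethod
    def load(cls, path) -> "SpectralClusterLibrary":
        return cls.from_dict(json.loads(Path(path).read_text()))


def collect_training_pixels(cubes, segmaps, preprocess_config: PreprocessConfig):
    """Pool preprocessed candidate-pixel spectra from training images.

    Rows are candidate pixels in raster order within each image, images in
    the given order, each preprocessed truncate -> smooth -> normalize.
    Returns ``(matrix, subgrid)``.

    Raises
    ------
    EmptyTrainingError
        If no image contributes a single candidate pixel.
    """
    cubes = list(cubes)
    segmaps = list(segmaps)
    if len(cubes) != len(segmaps):
        raise ValueError("need one segmentation map per cube")
    blocks = []
    subgrid = None
    for cube, segmap in zip(cubes, segmaps):
        segmap = np.asarray(segmap)
        if segmap.shape != cube.data.shape[:2]:
            raise ValueError("segmentation map shape does not match cube")
        mask = segmap == Label.CANDIDATE
        if not mask.any():
            continue
        raw = cube.data[mask].astype(float)
        processed, subgrid = preprocess_spectra(raw, cube.grid, preprocess_config)
        blocks.append(processed)
    if not blocks:
        raise EmptyTrainingError("no candidate pixels in any training image")
    return np.vstack(blocks), subgrid


def train_kmeans(pixel_matrix, k: int, seed: int = 0, n_restarts: int = 10) -> np.ndarray:
    """Standard k-means on preprocessed pixel spectra.

    k-means++ initialization with ``n_restarts`` restarts; deterministic for
    a given seed.  Centroids are re-normalized to unit maximum after
    averaging and returned sorted by peak wavelength index (ascending) so the
    ordering does not depend on initialization.
    """
    X = np.atleast_2d(np.asarray(pixel_matrix, dtype=float))
    if X.shape[0] < k:
        raise ValueError(f"{X.shape[0]} pixels < k={k}")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    km.fit(X)
    centroids = km.cluster_centers_
    centroids = centroids / centroids.max(axis=1, keepdims=True)
    order = np.argsort(centroids.argmax(axis=1), kind="stable")
    return centroids[order]


def assemble_library(
    kmeans_centroids,
    grid: WavelengthGrid,
    preprocess_config: PreprocessConfig,
    manual_clusters=(),
    np_band: BandWindow = NP_BAND,
    np_index: int | None = None,
    metadata: dict | None = None,
) -> SpectralClusterLibrary:
    """Concatenate k-means and manual centroids into a classification library.

    The nanoparticle centroid is auto-selected among the k-means centroids
    whose spectral argmax lies inside ``np_band``: single-particle plasmon
    lines are narrow while chromatic-aberration spectra peaking in the same
    band are much broader, so when several centroids peak in the band the
    one with the smallest full width at half maximum wins (remaining ties
    broken by the larger band mean).  Other in-band k-means centroids are
    tagged with role ``"aberration"`` — they exist to absorb red-shifted
    edge artifacts and count as negative at detection time.  Pass
    ``np_index`` to override the automatic choice.  Manual clusters (the
    averaged false-positive centroid from negative controls) are appended
    after the k-means centroids with role ``"aberration"``.

    Raises
    ------
    NPClusterSelectionError
        If no k-means centroid peaks inside the band and no explicit index
        was given.
    """
    kmeans_centroids = np.atleast_2d(np.asarray(kmeans_centroids, dtype=float))
    if kmeans_centroids.shape[0] < 1:
        raise ValueError("need at least one k-means centroid")
    values = grid.values
    peaks_nm = values[kmeans_centroids.argmax(axis=1)]
    in_band = np.flatnonzero((peaks_nm >= np_band.lo_nm) & (peaks_nm <= np_band.hi_nm))
    if np_index is None:
        if in_band.size == 0:
            raise NPClusterSelectionError(
                "no k-means centroid peaks inside the nanoparticle band; "
                "pass np_index explicitly"
            )
        if in_band.size == 1:
            np_index = int(in_band[0])
        else:
            # narrowest peak = the particle line; broad in-band spectra are
            # chromatic-aberration-like
            widths = (kmeans_centroids[in_band] >= 0.5).sum(axis=1)
            narrowest = widths == widths.min()
            tied = in_band[narrowest]
            if tied.size == 1:
                np_index = int(tied[0])
            else:
                means = band_mean(kmeans_centroids[tied], grid, np_band)
                np_index = int(tied[np.argmax(means)])
    elif not 0 <= np_index < kmeans_centroids.shape[0]:
        raise ValueError("explicit np_index out of range of k-means centroids")

    roles = ["stain"] * kmeans_centroids.shape[0]
    for i in in_band:
        roles[i] = "aberration"
    roles[np_index] = "np"
    manual = [np.asarray(m, dtype=float) for m in manual_clusters]
    centroids = np.vstack([kmeans_centroids] + manual) if manual else kmeans_centroids
    roles += ["aberration"] * len(manual)
    return SpectralClusterLibrary(
        centroids=centroids,
        roles=roles,
        np_index=np_index,
        grid=grid,
        preprocess=preprocess_config,
        metadata=metadata or {},
    )


def build_aberration_cluster(control_cubes, control_segmaps, provisional_library):
    """Average the spectra of pixels falsely detected in control images.

    Control images contain no nanoparticles by construction, so any pixel
    the provisional library assigns to the nanoparticle cluster is a false
    positive; their preprocessed spectra are averaged and max-normalized
    into the chromatic-aberration centroid.  Returns ``None`` when the
    controls yield no false positives (library left unchanged by caller).
    """
    from .classify import classify_nearest_centroid  # local: avoid cycle

    false_spectra = []
    for cube, segmap in zip(control_cubes, control_segmaps):
        detection = classify_nearest_centroid(cube, segmap, provisional_library)
        mask = detection.np_mask
        if not mask.any():
            continue
        raw = cube.data[mask].astype(float)
        processed, _ = preprocess_spectra(raw, cube.grid, provisional_library.preprocess)
        false_spectra.append(processed)
    if not false_spectra:
        return None
    mean = np.vstack(false_spectra).mean(axis=0)
    return mean / mean.max()
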