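"""Per-pixel classification of candidate pixels.

The adaptive classifier assigns each candidate pixel to the nearest library
centroid in Euclidean distance on identically preprocessed spectra; a pixel
is nanoparticle-positive iff it lands on the nanoparticle centroid.  A
Spectral Angle Mapper (SAM) baseline — thresholding the angle to a single
reference spectrum — is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGridError
from .io_envi import HyperCube
from .preprocess import Label
from .spectral_core import PreprocessConfig, preprocess_spectra

__all__ = ["DetectionMap", "classify_nearest_centroid", "classify_sam"]

#: sentinel cluster codes in DetectionMap.assignments
UNCLASSIFIED_BACKGROUND = -2
UNCLASSIFIED_TISSUE = -1


@dataclass
class DetectionMap:
    """Per-pixel cluster assignment derived from a segmentation map.

    ``assignments`` holds -2 for background, -1 for tissue, and the cluster
    index (>= 0) for candidate pixels.  ``np_index`` identifies which cluster
    is the nanoparticle one; for SAM results the codes are 0 (negative) and
    1 (positive) with ``np_index`` 1.
    """

    assignments: np.ndarray
    np_index: int
    aberration_indices: tuple = ()
    n_excluded: int = 0

    @property
    def np_mask(self) -> np.ndarray:
        return self.assignments == self.np_index

    @property
    def candidate_mask(self) -> np.ndarray:
        return self.assignments >= 0

    @property
    def background_mask(self) -> np.ndarray:
        return self.assignments == UNCLASSIFIED_BACKGROUND

    @property
    def aberration_mask(self) -> np.ndarray:
        mask = np.zeros(self.assignments.shape, dtype=bool)
        for idx in self.aberration_indices:
            mask |= self.assignments == idx
        return mask

    def cluster_counts(self, n_clusters: int) -> dict:
        """Pixel count per cluster index, plus background/tissue counts."""
        counts = {f"cluster_{i}": int((self.assignments == i).sum()) for i in range(n_clusters)}
        counts["background"] = int(self.background_mask.sum())
        counts["tissue"] = int((self.assignments == UNCLASSIFIED_TISSUE).sum())
        return counts


def classify_nearest_centroid(cube: HyperCube, segmap, library) -> DetectionMap:
    """Assign every candidate pixel to its nearest library centroid.

    Candidate spectra are preprocessed exactly as during training (the
    library carries its own preprocessing config), then assigned by minimum
    Euclidean distance; ties go to the lowest centroid index.
    """
    segmap = np.asarray(segmap)
    if segmap.shape != cube.data.shape[:2]:
        raise ValueError("segmentation map shape does not match cube")
    assignments = np.full(segmap.shape, UNCLASSIFIED_TISSUE, dtype=np.int16)
    assignments[segmap == Label.BACKGROUND] = UNCLASSIFIED_BACKGROUND

    mask = segmap == Label.CANDIDATE
    if mask.any():
        raw = cube.data[mask].astype(float)
        processed, subgrid = preprocess_spectra(raw, cube.grid, library.preprocess)
        if subgrid.n_samples != library.grid.n_samples or not np.isclose(
            subgrid.start_nm, library.grid.start_nm
        ):
            raise InvalidGridError("cube grid does not match library grid after truncation")
        # pairwise squared distances; argmin ties resolve to lowest index
        d2 = (
            (processed**2).sum(axis=1, keepdims=True)
            - 2.0 * processed @ library.centroids.T
            + (library.centroids**2).sum(axis=1)[None, :]
        )
        assignments[mask] = np.argmin(d2, axis=1).astype(np.int16)
    return DetectionMap(
        assignments=assignments,
        np_index=library.np_index,
        aberration_indices=tuple(library.aberration_indices),
    )


def classify_sam(
    cube: HyperCube,
    segmap,
    reference_spectrum,
    angle_tol_rad: float,
    preprocess_config: PreprocessConfig = PreprocessConfig(),
) -> DetectionMap:
    """Spectral Angle Mapper baseline on preprocessed candidate spectra.

    A candidate pixel is positive iff the angle between its preprocessed
    spectrum and the (preprocessed-scale) reference is at most
    ``angle_tol_rad``.  Zero-norm spectra are excluded and counted in
    ``n_excluded``.
    """
    if not 0 < angle_tol_rad < np.pi / 2:
        raise ValueError("angular tolerance must lie in (0, pi/2)")
    segmap = np.asarray(segmap)
    assignments = np.full(segmap.shape, UNCLASSIFIED_TISSUE, dtype=np.int16)
    assignments[segmap == Label.BACKGROUND] = UNCLASSIFIED_BACKGROUND

    reference = np.asarray(reference_spectrum, dtype=float)
    ref_norm = np.linalg.norm(reference)
    if ref_norm == 0:
        raise ValueError("reference spectrum has zero norm")

    n_excluded = 0
    mask = segmap == Label.CANDIDATE
    if mask.any():
        raw = cube.data[mask].astype(float)
        processed, _ = preprocess_spectra(raw, cube.grid, preprocess_config)
        norms = np.linalg.norm(processed, axis=1)
        ok = norms > 0
        n_excluded = int((~ok).sum())
        cosine = np.zeros(processed.shape[0])
        cosine[ok] = processed[ok] @ reference / (norms[ok] * ref_norm)
        angles = np.arccos(np.clip(cosine, -1.0, 1.0))
        positive = ok & (angles <= angle_tol_rad)
        assignments[mask] = positive.astype(np.int16)
    return DetectionMap(assignments=assignments, np_index=1, n_excluded=n_excluded)
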