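"""Nearest-centroid classification and the SAM baseline."""

import numpy as np
import pytest

from hsmad.classify import classify_nearest_centroid, classify_sam
from hsmad.cluster_train import assemble_library
from hsmad.io_envi import HyperCube
from hsmad.preprocess import Label
from hsmad.spectral_core import DEFAULT_GRID, PreprocessConfig, preprocess_spectra
from hsmad.synthetic import gaussian_spectrum, lorentzian_spectrum


@pytest.fixture(scope="module")
def toy_library():
    stain = gaussian_spectrum(600, 90, 1.0, DEFAULT_GRID)
    npline = lorentzian_spectrum(900, 30, 1.0, 0.0, DEFAULT_GRID)
    config = PreprocessConfig()
    centroids, subgrid = preprocess_spectra(np.vstack([stain, npline]), DEFAULT_GRID, config)
    return assemble_library(centroids, subgrid, config, np_index=1)


def _one_pixel_cube(spectrum):
    cube = HyperCube(spectrum[None, None, :].astype(float), DEFAULT_GRID)
    segmap = np.full((1, 1), Label.CANDIDATE, dtype=np.uint8)
    return cube, segmap


class TestNearestCentroid:
    def test_np_spectrum_detected(self, toy_library):
        cube, segmap = _one_pixel_cube(lorentzian_spectrum(900, 30, 500.0, 0.0, DEFAULT_GRID))
        detection = classify_nearest_centroid(cube, segmap, toy_library)
        assert detection.np_mask[0, 0]

    def test_stain_spectrum_not_detected(self, toy_library):
        cube, segmap = _one_pixel_cube(gaussian_spectrum(600, 90, 500.0, DEFAULT_GRID))
        detection = classify_nearest_centroid(cube, segmap, toy_library)
        assert not detection.np_mask[0, 0]
        assert detection.assignments[0, 0] == 0

    def test_scale_invariance_of_assignment(self, toy_library, rng):
        spectrum = lorentzian_spectrum(890, 40, 1.0, 0.05, DEFAULT_GRID)
        a = classify_nearest_centroid(*_one_pixel_cube(spectrum), toy_library)
        b = classify_nearest_centroid(*_one_pixel_cube(spectrum * 137.0), toy_library)
        assert a.assignments[0, 0] == b.assignments[0, 0]

    def test_equidistant_tie_goes_to_lower_index(self):
        config = PreprocessConfig(sg_window=3, sg_order=1)
        grid = DEFAULT_GRID
        flat = np.ones(361)
        bump = flat.copy()
        bump[200] = 2.0
        centroids, subgrid = preprocess_spectra(np.vstack([bump, bump]), grid, config)
        lib = assemble_library(centroids, subgrid, config, np_index=1)
        cube, segmap = _one_pixel_cube(flat * 10)
        detection = classify_nearest_centroid(cube, segmap, lib)
        assert detection.assignments[0, 0] == 0
        assert not detection.np_mask[0, 0]

    def test_background_and_tissue_pass_through(self, toy_library, rng):
        cube = HyperCube(rng.uniform(1, 2, (2, 2, 361)), DEFAULT_GRID)
        segmap = np.array([[Label.BACKGROUND, Label.TISSUE], [Label.TISSUE, Label.BACKGROUND]], dtype=np.uint8)
        detection = classify_nearest_centroid(cube, segmap, toy_library)
        assert detection.background_mask.sum() == 2
        assert not detection.candidate_mask.any()

    def test_training_pixels_self_consistent(self, benchmark_small):
        """Re-classifying the training candidates lands almost every pixel on
        its own converged k-means cluster (centroid re-normalization can move
        a handful of boundary pixels)."""
        from sklearn.cluster import KMeans

        lib = benchmark_small["library"]
        # reconstruct a training-like pixel set from the held-out detection
        det = benchmark_small["detection"]
        cube = benchmark_small["cube"]
        mask = det.candidate_mask
        X, _ = preprocess_spectra(cube.data[mask].astype(float), cube.grid, lib.preprocess)
        d2 = ((X[:, None, :] - lib.centroids[None, :, :]) ** 2).sum(axis=2)
        assert np.array_equal(np.argmin(d2, axis=1), det.assignments[mask])


class TestSAM:
    def test_reference_itself_always_positive(self, toy_library):
        ref = toy_library.centroids[1]
        spectrum = lorentzian_spectrum(900, 30, 500.0, 0.0, DEFAULT_GRID)
        cube, segmap = _one_pixel_cube(spectrum)
        detection = classify_sam(cube, segmap, ref, angle_tol_rad=0.01)
        assert detection.np_mask[0, 0]

    def test_orthogonal_spectrum_negative(self):
        # disjoint support after truncation -> angle pi/2
        config = PreprocessConfig(sg_window=3, sg_order=1)
        ref = np.zeros(261)
        ref[:100] = 1.0
        x = np.zeros(361)
        x[-50:] = 5.0
        cube, segmap = _one_pixel_cube(x)
        detection = classify_sam(cube, segmap, ref, angle_tol_rad=1.5, preprocess_config=config)
        assert not detection.np_mask[0, 0]

    def test_positive_count_monotone_in_tolerance(self, benchmark_small):
        cube = benchmark_small["cube"]
        det = benchmark_small["detection"]
        lib = benchmark_small["library"]
        segmap = np.where(det.background_mask, Label.BACKGROUND,
                          np.where(det.candidate_mask, Label.CANDIDATE, Label.TISSUE)).astype(np.uint8)
        ref = lib.centroids[lib.np_index]
        counts = [
            classify_sam(cube, segmap, ref, tol, lib.preprocess).np_mask.sum()
            for tol in (0.05, 0.1, 0.2, 0.4, 0.8)
        ]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_adaptive_detection_dominates_sam_somewhere(self, benchmark_small):
        """At some tolerance the adaptive classifier is at least as good as
        SAM on both sensitivity and specificity (and better on one)."""
        from hsmad.diagnostics import confusion_from_truth, sens_spec

        cube, det, lib = (benchmark_small[k] for k in ("cube", "detection", "library"))
        truth = benchmark_small["truth"]
        segmap = np.where(det.background_mask, Label.BACKGROUND,
                          np.where(det.candidate_mask, Label.CANDIDATE, Label.TISSUE)).astype(np.uint8)
        eval_mask = det.candidate_mask & ~truth.np_aggregate & ~truth.np_halo
        ours = sens_spec(confusion_from_truth(det, truth.np_single, eval_mask))
        ref = lib.centroids[lib.np_index]
        dominated = False
        for tol in (0.05, 0.1, 0.2, 0.4):
            sam = classify_sam(cube, segmap, ref, tol, lib.preprocess)
            res = sens_spec(confusion_from_truth(sam, truth.np_single, eval_mask))
            if ours.sensitivity >= res.sensitivity and ours.specificity >= res.specificity:
                dominated = True
        assert dominated
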