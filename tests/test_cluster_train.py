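"""Spectral library learning: k-means, NP-cluster selection, aberration."""

from itertools import product

import numpy as np
import pytest

from hsmad.cluster_train import (
    SpectralClusterLibrary,
    assemble_library,
    build_aberration_cluster,
    collect_training_pixels,
    train_kmeans,
)
from hsmad.errors import EmptyTrainingError, NPClusterSelectionError
from hsmad.io_envi import HyperCube
from hsmad.preprocess import Label
from hsmad.spectral_core import DEFAULT_GRID, PreprocessConfig, preprocess_spectra
from hsmad.synthetic import gaussian_spectrum, lorentzian_spectrum


def brute_force_kmeans_objective(points, k):
    """Exhaustive-partition optimum of the k-means SSE on a tiny instance."""
    n = len(points)
    best = np.inf
    for labels in product(range(k), repeat=n):
        if len(set(labels)) < k:
            continue
        sse = 0.0
        for c in range(k):
            members = points[np.array(labels) == c]
            sse += ((members - members.mean(axis=0)) ** 2).sum()
        best = min(best, sse)
    return best


class TestTrainKmeans:
    def test_k1_centroid_is_normalized_mean(self, rng):
        X = rng.uniform(0.5, 1.0, (20, 30))
        X /= X.max(axis=1, keepdims=True)
        centroid = train_kmeans(X, k=1, seed=0)[0]
        mean = X.mean(axis=0)
        np.testing.assert_allclose(centroid, mean / mean.max(), rtol=1e-12)

    def test_tiny_instance_matches_exhaustive_optimum(self, rng):
        """8 points in two groups, k=2: restarts find the global SSE optimum."""
        X = np.vstack([rng.normal(0.0, 0.5, (4, 3)), rng.normal(2.0, 0.5, (4, 3))])
        expected = brute_force_kmeans_objective(X, 2)
        from sklearn.cluster import KMeans

        inertia = KMeans(n_clusters=2, init="k-means++", n_init=10, random_state=0).fit(X).inertia_
        assert inertia == pytest.approx(expected, rel=1e-9)
        # and the packaged entry point runs on the same instance
        assert train_kmeans(X, k=2, seed=0).shape == (2, 3)

    def test_recovers_two_planted_templates(self, rng):
        narrow = lorentzian_spectrum(900, 30, 1.0, 0.0, DEFAULT_GRID)
        broad = lorentzian_spectrum(800, 100, 1.0, 0.0, DEFAULT_GRID)
        X = np.vstack(
            [narrow + rng.normal(0, 0.01, 361) for _ in range(40)]
            + [broad + rng.normal(0, 0.01, 361) for _ in range(40)]
        )
        X, subgrid = preprocess_spectra(X, DEFAULT_GRID, PreprocessConfig())
        centroids = train_kmeans(X, k=2, seed=0)
        peaks = subgrid.values[centroids.argmax(axis=1)]
        # centroids come back sorted by peak wavelength
        assert abs(peaks[0] - 800) <= subgrid.spacing_nm
        assert abs(peaks[1] - 900) <= subgrid.spacing_nm

    def test_deterministic_given_seed(self, rng):
        X = rng.uniform(0.1, 1.0, (50, 20))
        a = train_kmeans(X, k=3, seed=7)
        b = train_kmeans(X, k=3, seed=7)
        np.testing.assert_array_equal(a, b)

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            train_kmeans(np.ones((2, 5)), k=3)


class TestCollectTrainingPixels:
    def _cube_segmap(self, rng, n_candidates):
        cube = HyperCube(rng.uniform(0.5, 2.0, (5, 5, 361)), DEFAULT_GRID)
        segmap = np.full((5, 5), Label.TISSUE, dtype=np.uint8)
        flat = rng.choice(25, size=n_candidates, replace=False)
        segmap[np.unravel_index(flat, (5, 5))] = Label.CANDIDATE
        return cube, segmap

    def test_row_count_matches_candidates(self, rng):
        cube, segmap = self._cube_segmap(rng, 7)
        matrix, _ = collect_training_pixels([cube], [segmap], PreprocessConfig())
        assert matrix.shape[0] == 7

    def test_rows_match_per_pixel_oracle(self, rng):
        cube, segmap = self._cube_segmap(rng, 4)
        config = PreprocessConfig()
        matrix, _ = collect_training_pixels([cube], [segmap], config)
        rows = np.argwhere(segmap == Label.CANDIDATE)
        for row_idx, (i, j) in enumerate(rows):
            expected, _ = preprocess_spectra(cube.data[i, j], cube.grid, config)
            np.testing.assert_allclose(matrix[row_idx], expected, rtol=1e-12)

    def test_no_candidates_errors(self, rng):
        cube, _ = self._cube_segmap(rng, 1)
        all_tissue = np.full((5, 5), Label.TISSUE, dtype=np.uint8)
        with pytest.raises(EmptyTrainingError):
            collect_training_pixels([cube], [all_tissue], PreprocessConfig())


class TestAssembleLibrary:
    def _centroids(self, peaks_gammas):
        rows = [
            lorentzian_spectrum(c, g, 1.0, 0.0, DEFAULT_GRID) for c, g in peaks_gammas
        ]
        X = np.vstack(rows)
        return X / X.max(axis=1, keepdims=True)

    def test_selects_centroid_peaking_in_band(self):
        cents = self._centroids([(560, 60), (610, 60), (650, 60), (900, 30)])
        lib = assemble_library(cents, DEFAULT_GRID, PreprocessConfig())
        assert lib.np_index == 3
        assert lib.roles[3] == "np"

    def test_narrow_line_beats_broad_aberration(self):
        """Both peak in the band; the particle line is the narrow one."""
        cents = self._centroids([(560, 60), (915, 80), (900, 30)])
        lib = assemble_library(cents, DEFAULT_GRID, PreprocessConfig())
        assert lib.np_index == 2
        assert lib.roles[1] == "aberration"

    def test_no_in_band_centroid_requires_explicit_index(self):
        cents = self._centroids([(560, 60), (650, 60)])
        with pytest.raises(NPClusterSelectionError):
            assemble_library(cents, DEFAULT_GRID, PreprocessConfig())
        lib = assemble_library(cents, DEFAULT_GRID, PreprocessConfig(), np_index=1)
        assert lib.np_index == 1

    def test_json_round_trip(self, tmp_path):
        cents = self._centroids([(560, 60), (900, 30)])
        lib = assemble_library(cents, DEFAULT_GRID, PreprocessConfig(), metadata={"k": 2, "seed": 5})
        lib.save(tmp_path / "lib.json")
        back = SpectralClusterLibrary.load(tmp_path / "lib.json")
        np.testing.assert_allclose(back.centroids, lib.centroids, rtol=1e-12)
        assert back.np_index == lib.np_index
        assert back.roles == lib.roles
        assert back.preprocess == lib.preprocess


class TestAberrationCluster:
    def test_identical_false_positives_average_to_themselves(self):
        grid = DEFAULT_GRID
        edge = lorentzian_spectrum(915, 60, 3000.0, 0.0, grid)
        stain = gaussian_spectrum(600, 90, 1.0, grid)
        npline = lorentzian_spectrum(900, 30, 1.0, 0.0, grid)
        config = PreprocessConfig()
        centroids, subgrid = preprocess_spectra(np.vstack([stain, npline]), grid, config)
        lib = assemble_library(centroids, subgrid, config, np_index=1)

        cube = HyperCube(np.broadcast_to(edge, (3, 3, 361)).copy(), grid)
        segmap = np.full((3, 3), Label.CANDIDATE, dtype=np.uint8)
        aberration = build_aberration_cluster([cube], [segmap], lib)
        expected, _ = preprocess_spectra(edge, grid, config)
        np.testing.assert_allclose(aberration, expected, rtol=1e-9)

    def test_phantom_controls_yield_broad_red_peak(self, control_phantom):
        """Control-image false positives average into a centroid peaking
        within 10 nm of the planted artifact line and broader than the
        particle template."""
        from hsmad.pipeline import PipelineConfig, segment_cube

        cube, truth = control_phantom
        config = PipelineConfig()
        corrected, segmap, _ = segment_cube(cube, config)

        grid = DEFAULT_GRID
        stain = gaussian_spectrum(600, 90, 1.0, grid)
        npline = lorentzian_spectrum(900, 30, 1.0, 0.0, grid)
        centroids, subgrid = preprocess_spectra(np.vstack([stain, npline]), grid, config.preprocess)
        provisional = assemble_library(centroids, subgrid, config.preprocess, np_index=1)

        aberration = build_aberration_cluster([corrected], [segmap], provisional)
        assert aberration is not None
        peak_nm = subgrid.values[np.argmax(aberration)]
        assert abs(peak_nm - 915.0) <= 10.0
        fwhm = (aberration >= 0.5).sum()
        np_fwhm = (centroids[1] >= 0.5).sum()
        assert fwhm > np_fwhm

    def test_no_false_positives_returns_none(self):
        grid = DEFAULT_GRID
        stain = gaussian_spectrum(600, 90, 1.0, grid)
        npline = lorentzian_spectrum(900, 30, 1.0, 0.0, grid)
        config = PreprocessConfig()
        centroids, subgrid = preprocess_spectra(np.vstack([stain, npline]), grid, config)
        lib = assemble_library(centroids, subgrid, config, np_index=1)
        cube = HyperCube(np.broadcast_to(stain * 100, (3, 3, 361)).copy(), grid)
        segmap = np.full((3, 3), Label.CANDIDATE, dtype=np.uint8)
        assert build_aberration_cluster([cube], [segmap], lib) is None
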