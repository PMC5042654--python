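"""Confusion counts, log-method confidence intervals, PSF checks."""

import numpy as np
import pytest

from hsmad.classify import DetectionMap, UNCLASSIFIED_TISSUE
from hsmad.diagnostics import (
    ConfusionCounts,
    PsfModel,
    confusion_from_truth,
    log_method_ci,
    psf_sigma,
    sens_spec,
    single_particle_check,
)
from hsmad.io_envi import HyperCube
from hsmad.spectral_core import BandWindow, build_grid

NIR_BAND = BandWindow(833, 988)


def _detection_from_bool(pred):
    assignments = np.where(pred, 0, UNCLASSIFIED_TISSUE).astype(np.int16)
    return DetectionMap(assignments=assignments, np_index=0)


class TestConfusion:
    def test_perfect_detection(self, rng):
        truth = rng.random((8, 8)) < 0.3
        det = _detection_from_bool(truth)
        counts = confusion_from_truth(det, truth, np.ones((8, 8), bool))
        assert counts.fp == counts.fn == 0

    def test_inverted_detection(self, rng):
        truth = rng.random((8, 8)) < 0.3
        det = _detection_from_bool(~truth)
        counts = confusion_from_truth(det, truth, np.ones((8, 8), bool))
        assert counts.tp == counts.tn == 0

    def test_matches_loop_oracle(self, rng):
        truth = rng.random((5, 10)) < 0.4
        pred = rng.random((5, 10)) < 0.5
        eval_mask = rng.random((5, 10)) < 0.9
        det = _detection_from_bool(pred)
        counts = confusion_from_truth(det, truth, eval_mask)
        tp = fp = tn = fn = 0
        for i in range(5):
            for j in range(10):
                if not eval_mask[i, j]:
                    continue
                if pred[i, j] and truth[i, j]:
                    tp += 1
                elif pred[i, j]:
                    fp += 1
                elif truth[i, j]:
                    fn += 1
                else:
                    tn += 1
        assert (counts.tp, counts.fp, counts.tn, counts.fn) == (tp, fp, tn, fn)

    def test_empty_eval_mask_rejected(self):
        det = _detection_from_bool(np.zeros((3, 3), bool))
        with pytest.raises(ValueError):
            confusion_from_truth(det, np.zeros((3, 3), bool), np.zeros((3, 3), bool))


class TestSensSpec:
    @pytest.mark.parametrize(
        "counts,sens,spec",
        [
            (ConfusionCounts(90, 0, 0, 10), 0.90, None),
            (ConfusionCounts(0, 3, 997, 0), None, 0.997),
            (ConfusionCounts(0, 0, 0, 5), 0.0, None),
        ],
    )
    def test_point_estimates(self, counts, sens, spec):
        result = sens_spec(counts)
        if sens is None:
            assert result.sensitivity is None
        else:
            assert result.sensitivity == pytest.approx(sens)
        if spec is None:
            assert result.specificity is None
        else:
            assert result.specificity == pytest.approx(spec)

    def test_perfect_detection_gives_ones(self):
        result = sens_spec(ConfusionCounts(10, 0, 20, 0))
        assert result.sensitivity == 1.0 and result.specificity == 1.0


class TestLogMethodCI:
    def test_worked_example(self):
        lo, hi = log_method_ci(90, 100, z=1.96)
        assert lo == pytest.approx(0.843, abs=5e-4)
        assert hi == pytest.approx(0.961, abs=5e-4)

    def test_certainty_degenerates(self):
        assert log_method_ci(50, 50) == (1.0, 1.0)

    def test_zero_numerator_rule_of_three(self):
        lo, hi = log_method_ci(0, 60)
        assert lo == 0.0 and hi == pytest.approx(3.0 / 60.0)

    def test_width_decreases_with_n(self):
        widths = [np.diff(log_method_ci(9 * m, 10 * m))[0] for m in (1, 5, 25, 125)]
        assert all(b < a for a, b in zip(widths, widths[1:]))

    def test_monte_carlo_coverage(self):
        """95% CI coverage at p=0.95, n=200 over 2000 replicates."""
        rng = np.random.default_rng(2024)
        covered = 0
        reps = 2000
        for _ in range(reps):
            a = rng.binomial(200, 0.95)
            if a == 0:
                continue
            lo, hi = log_method_ci(a, 200)
            covered += lo <= 0.95 <= hi
        assert 0.92 <= covered / reps <= 0.98


class TestPsf:
    def test_printed_instrument_sigma(self):
        sigma = psf_sigma(910.0, 0.75)
        assert sigma == pytest.approx(254.8)
        assert round(sigma / 1000.0, 2) == 0.25

    def test_linearity_in_wavelength(self):
        assert psf_sigma(1000, 0.6) == pytest.approx(2 * psf_sigma(500, 0.6))

    def test_second_example(self):
        assert psf_sigma(500, 0.5) == pytest.approx(210.0)

    @pytest.mark.parametrize("args", [(910, 0), (910, 2.0), (-1, 0.75)])
    def test_invalid_arguments(self, args):
        with pytest.raises(ValueError):
            psf_sigma(*args)


class TestSingleParticleCheck:
    grid = build_grid(833, 988, 8)

    def _spot_cube(self, sigma_scale=1.0, noise=0.0, seed=0):
        model = PsfModel()
        h = w = 15
        rows = np.arange(h)[:, None]
        cols = np.arange(w)[None, :]
        s_r = sigma_scale * model.sigma_nm / model.pixel_pitch_nm[0]
        s_c = sigma_scale * model.sigma_nm / model.pixel_pitch_nm[1]
        spot = np.exp(-0.5 * (((rows - 7) / s_r) ** 2 + ((cols - 7) / s_c) ** 2))
        data = np.repeat(spot[:, :, None], 8, axis=2)
        if noise:
            data = data + np.random.default_rng(seed).normal(0, noise, data.shape)
        cube = HyperCube(np.clip(data, 0, None), self.grid)
        pred = np.zeros((h, w), bool)
        pred[7, 7] = True
        return cube, _detection_from_bool(pred), model

    def test_exact_model_spot_is_consistent(self):
        cube, det, model = self._spot_cube()
        report = single_particle_check(cube, det, (7, 7), model, band=NIR_BAND)
        assert report["isolated"] and report["consistent"]
        assert report["rmse_h"] == pytest.approx(0.0, abs=1e-7)

    def test_noisy_model_spot_still_consistent(self):
        cube, det, model = self._spot_cube(noise=0.02, seed=3)
        report = single_particle_check(cube, det, (7, 7), model, band=NIR_BAND)
        assert report["consistent"]

    def test_triple_width_blob_rejected(self):
        cube, det, model = self._spot_cube(sigma_scale=3.0)
        report = single_particle_check(cube, det, (7, 7), model, band=NIR_BAND)
        assert report["isolated"] and not report["consistent"]

    def test_non_isolated_pixel_not_applicable(self):
        cube, det, model = self._spot_cube()
        det.assignments[7, 9] = 0  # second positive 2 px away
        report = single_particle_check(cube, det, (7, 7), model, band=NIR_BAND)
        assert report["isolated"] is False and report["consistent"] is None
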