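"""End-to-end orchestration: one config object, train/detect/quantify runs.

Two acquisition protocols are supported:

* the *tissue* protocol — vignette-correct, three-way segment
  (background / tissue / candidate), classify candidates against a library;
* the *slide* protocol for pure-particle preparations — there is no tissue
  class, so every above-background pixel is a potential particle.

``run_pipeline`` chains the stages on ENVI inputs and writes a deterministic
artifact tree; the benchmark helpers rebuild the full study (train on
phantoms, test on held-out phantoms) and are what the test-suite and the
acceptance script run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classify import classify_nearest_centroid
from .cluster_train import (
    SpectralClusterLibrary,
    assemble_library,
    build_aberration_cluster,
    collect_training_pixels,
    train_kmeans,
)
from .diagnostics import confusion_from_truth, sens_spec
from .io_envi import HyperCube, read_envi
from .preprocess import (
    Label,
    ThresholdParams,
    VignetteModel,
    adaptive_thresholds,
    mean_intensity,
    segment,
    vignette_correct,
)
from .quantify import relative_np_signal
from .spectral_core import BandWindow, NP_BAND, PreprocessConfig

__all__ = [
    "PipelineConfig",
    "segment_cube",
    "segment_slide",
    "train_library",
    "detect",
    "run_pipeline",
    "phantom_benchmark",
    "two_particle_benchmark",
]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters in one serializable document."""

    preprocess: PreprocessConfig = PreprocessConfig()
    thresholds: ThresholdParams = ThresholdParams()
    vignette: VignetteModel = VignetteModel()
    np_band: BandWindow = NP_BAND
    k: int = 4
    seed: int = 0
    n_restarts: int = 10

    def to_dict(self) -> dict:
        return {
            "version": 1,
            "cutoff_nm": self.preprocess.cutoff_nm,
            "sg_window": self.preprocess.sg_window,
            "sg_order": self.preprocess.sg_order,
            "n_bins": self.thresholds.n_bins,
            "resample_step": self.thresholds.resample_step,
            "alpha": self.thresholds.alpha,
            "beta": self.thresholds.beta,
            "d_mm": self.vignette.d_mm,
            "pixel_pitch_nm": list(self.vignette.pixel_pitch_nm),
            "np_band": [self.np_band.lo_nm, self.np_band.hi_nm],
            "k": self.k,
            "seed": self.seed,
            "n_restarts": self.n_restarts,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            preprocess=PreprocessConfig(
                cutoff_nm=float(d.get("cutoff_nm", 566.0)),
                sg_window=int(d.get("sg_window", 11)),
                sg_order=int(d.get("sg_order", 3)),
            ),
            thresholds=ThresholdParams(
                n_bins=int(d.get("n_bins", 510)),
                resample_step=float(d.get("resample_step", 5.0)),
                alpha=float(d.get("alpha", 1.05)),
                beta=float(d.get("beta", 1.5)),
            ),
            vignette=VignetteModel(
                d_mm=float(d.get("d_mm", 2.0)),
                pixel_pitch_nm=tuple(d.get("pixel_pitch_nm", (410.0, 408.0))),
            ),
            np_band=BandWindow(*d.get("np_band", (833.0, 988.0))),
            k=int(d.get("k", 4)),
            seed=int(d.get("seed", 0)),
            n_restarts=int(d.get("n_restarts", 10)),
        )


def segment_cube(cube: HyperCube, config: PipelineConfig):
    """Tissue protocol: vignette-correct, then adaptive 3-way segmentation.

    Returns ``(corrected_cube, segmap, (bg_thr, cand_thr))``.
    """
    corrected = vignette_correct(cube, config.vignette)
    image = mean_intensity(corrected)
    thresholds = adaptive_thresholds(image, config.thresholds)
    return corrected, segment(image, thresholds), thresholds


def segment_slide(cube: HyperCube, config: PipelineConfig):
    """Slide protocol: everything above the background threshold is a
    potential particle (pure-particle preparations have no tissue class)."""
    corrected = vignette_correct(cube, config.vignette)
    image = mean_intensity(corrected)
    bg_thr, _ = adaptive_thresholds(image, config.thresholds)
    segmap = np.where(image < bg_thr, Label.BACKGROUND, Label.CANDIDATE).astype(np.uint8)
    return corrected, segmap, (bg_thr, bg_thr)


def train_library(
    training_cubes,
    config: PipelineConfig,
    control_cubes=(),
    np_index=None,
    segmenter=segment_cube,
) -> SpectralClusterLibrary:
    """Learn a cluster library from training images, plus the aberration
    cluster from nanoparticle-free controls when provided."""
    corrected, segmaps = [], []
    for cube in training_cubes:
        c, s, _ = segmenter(cube, config)
        corrected.append(c)
        segmaps.append(s)
    matrix, subgrid = collect_training_pixels(corrected, segmaps, config.preprocess)
    centroids = train_kmeans(matrix, config.k, seed=config.seed, n_restarts=config.n_restarts)
    library = assemble_library(
        centroids,
        subgrid,
        config.preprocess,
        np_band=config.np_band,
        np_index=np_index,
        metadata={"k": config.k, "seed": config.seed, "n_training_pixels": matrix.shape[0]},
    )
    if control_cubes:
        ctrl_corrected, ctrl_segmaps = [], []
        for cube in control_cubes:
            c, s, _ = segmenter(cube, config)
            ctrl_corrected.append(c)
            ctrl_segmaps.append(s)
        aberration = build_aberration_cluster(ctrl_corrected, ctrl_segmaps, library)
        if aberration is not None:
            library = assemble_library(
                library.centroids[: config.k],
                subgrid,
                config.preprocess,
                manual_clusters=[aberration],
                np_band=config.np_band,
                np_index=library.np_index,
                metadata=library.metadata,
            )
    return library


def detect(cube: HyperCube, library: SpectralClusterLibrary, config: PipelineConfig,
           segmenter=segment_cube):
    """Segment + classify one field of view.

    Returns ``(corrected_cube, segmap, detection_map)``.
    """
    corrected, segmap, _ = segmenter(cube, config)
    detection = classify_nearest_centroid(corrected, segmap, library)
    return corrected, segmap, detection


def run_pipeline(config: PipelineConfig, training_paths=(), input_paths=(),
                 control_paths=(), library_path=None, out_dir="hsmad_run"):
    """File-level pipeline: ENVI inputs in, artifact tree out.

    Either ``library_path`` (a saved library JSON) or ``training_paths``
    (ENVI headers to train on) must be given.  For every input image the run
    directory receives the detection map (.npy), per-cluster counts and the
    relative NP signal (JSON), plus the merged effective config.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=1))

    if library_path is not None:
        library = SpectralClusterLibrary.load(library_path)
    elif training_paths:
        training = [read_envi(p) for p in training_paths]
        controls = [read_envi(p) for p in control_paths]
        library = train_library(training, config, control_cubes=controls)
    else:
        raise ValueError("need a library file or training inputs")
    library.save(out / "library.json")

    results = {}
    for path in input_paths:
        cube = read_envi(path)
        corrected, segmap, detection = detect(cube, library, config)
        name = Path(path).stem
        np.save(out / f"{name}_detection.npy", detection.assignments)
        results[name] = {
            "relative_np_signal": relative_np_signal(corrected, detection, config.np_band),
            **detection.cluster_counts(library.n_clusters),
        }
    (out / "results.json").write_text(json.dumps(results, indent=1))
    return out


# ---------------------------------------------------------------------------
# phantom benchmarks (desk-scale stand-ins for the instrument studies)
# ---------------------------------------------------------------------------

def phantom_benchmark(seed: int = 0, size: int = 256, n_train: int = 3, config=None):
    """Train on ``n_train`` phantom seeds + controls, test on a held-out seed.

    Measures per-pixel sensitivity on single-particle pixels and specificity
    on tissue + edge-artifact pixels (candidate pixels only are scored;
    aggregate pixels are excluded from both).  The edge-artifact false
    positive rate is reported with the aberration cluster enabled and
    disabled.
    """
    from .synthetic import generate_phantom, preset_config

    config = config or PipelineConfig(seed=seed)
    train_cubes, controls = [], []
    for i in range(n_train):
        cube, _ = generate_phantom(preset_config("lgnr", seed=seed + i, height=size, width=size))
        train_cubes.append(cube)
    for i in range(2):
        cube, _ = generate_phantom(
            preset_config("control", seed=seed + 100 + i, height=size, width=size)
        )
        controls.append(cube)

    library = train_library(train_cubes, config, control_cubes=controls)
    if not library.aberration_indices:
        raise RuntimeError("no aberration cluster was learned or built")
    # aberration handling disabled: strip every aberration-role centroid
    keep = [i for i, r in enumerate(library.roles) if r != "aberration"]
    library_plain = assemble_library(
        library.centroids[keep],
        library.grid,
        config.preprocess,
        np_band=config.np_band,
        np_index=keep.index(library.np_index),
    )

    test_cfg = preset_config("lgnr", seed=seed + n_train, height=size, width=size)
    test_cube, truth = generate_phantom(test_cfg)
    corrected, segmap, detection = detect(test_cube, library, config)
    detection_plain = classify_nearest_centroid(corrected, segmap, library_plain)

    candidates = detection.candidate_mask
    excl = truth.np_aggregate | truth.np_halo
    sens_mask = candidates & truth.np_single & ~excl
    spec_mask = candidates & ~truth.np_single & ~excl
    counts = confusion_from_truth(detection, truth.np_single, sens_mask | spec_mask)
    result = sens_spec(counts)

    def edge_fp_rate(det):
        scored = det.candidate_mask & truth.edge_artifact & ~truth.np_single & ~excl
        if not scored.any():
            return 0.0, 0
        return float((det.np_mask & scored).sum() / scored.sum()), int(scored.sum())

    fp_with, n_edge = edge_fp_rate(detection)
    fp_without, _ = edge_fp_rate(detection_plain)
    return {
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "counts": counts,
        "edge_fp_rate_with_aberration": fp_with,
        "edge_fp_rate_without_aberration": fp_without,
        "n_edge_scored": n_edge,
        "library": library,
        "detection": detection,
        "truth": truth,
        "cube": corrected,
    }


def linearity_study(seed: int = 0, size: int = 128,
                    densities=(0.002, 0.005, 0.01, 0.02, 0.03), n_fov: int = 3):
    """Relative NP signal versus planted particle count.

    Trains one library, then for each particle density measures the mean
    relative NP signal over ``n_fov`` fields of view (the same per-field
    tissue geometry is reused across densities, so only the particle count
    varies).  Returns planted counts, mean signals, and the R^2 of the
    linear fit of signal on count.
    """
    from .quantify import aggregate_fovs, relative_np_signal
    from .synthetic import generate_phantom, preset_config

    config = PipelineConfig(seed=seed)
    train_cubes = [
        generate_phantom(preset_config("lgnr", seed=seed + i, height=size, width=size))[0]
        for i in range(3)
    ]
    controls = [
        generate_phantom(preset_config("control", seed=seed + 100, height=size, width=size))[0]
    ]
    library = train_library(train_cubes, config, control_cubes=controls)

    counts, signals = [], []
    for density in densities:
        sigs, ns = [], []
        for j in range(n_fov):
            cube, truth = generate_phantom(
                preset_config(
                    "lgnr", seed=seed + 50 + 7 * j, height=size, width=size,
                    np_density=density, aggregate_fraction=0.0, edge_artifact_rate=0.0,
                )
            )
            corrected, _, detection = detect(cube, library, config)
            sigs.append(relative_np_signal(corrected, detection, config.np_band))
            ns.append(len(truth.np_positions))
        counts.append(float(np.mean(ns)))
        signals.append(aggregate_fovs(sigs)[0])
    counts, signals = np.asarray(counts), np.asarray(signals)
    r2 = float(np.corrcoef(counts, signals)[0, 1] ** 2)
    return {"counts": counts, "signals": signals, "r_squared": r2, "library": library}


def two_particle_benchmark(seed: int = 0, size: int = 128):
    """Two-template unmixing on slide phantoms (narrow ~900 vs broad ~800 nm).

    Trains a 2-cluster library on one mixture slide and cross-classifies a
    second; reports the cosine similarity of each learned centroid to its
    planted template (after identical preprocessing) and the per-pixel
    accuracy over truth-labeled candidate pixels.
    """
    from .spectral_core import normalize_max, preprocess_spectra
    from .synthetic import generate_phantom, lorentzian_spectrum, preset_config

    config = PipelineConfig(k=2, seed=seed)
    train_cfg = preset_config("mixture", seed=seed, height=size, width=size)
    cube_train, _ = generate_phantom(train_cfg)
    library = train_library([cube_train], config, segmenter=segment_slide)

    # planted templates through the same preprocessing as the pixels
    grid = cube_train.grid
    narrow = lorentzian_spectrum(
        train_cfg.np_model.center_nm + train_cfg.medium_shift_nm,
        train_cfg.np_model.gamma_nm, 1.0, 0.0, grid,
    )
    broad = lorentzian_spectrum(
        train_cfg.second_model.center_nm + train_cfg.medium_shift_nm,
        train_cfg.second_model.gamma_nm, 1.0, 0.0, grid,
    )
    templates, _ = preprocess_spectra(np.stack([broad, narrow]), grid, config.preprocess)

    def cosine(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    # centroids are sorted by peak wavelength: index 0 ~ broad 800, 1 ~ narrow 900
    cos_broad = cosine(library.centroids[0], templates[0])
    cos_narrow = cosine(library.centroids[1], templates[1])

    test_cube, truth = generate_phantom(
        preset_config("mixture", seed=seed + 1, height=size, width=size)
    )
    corrected, segmap, detection = detect(test_cube, library, config, segmenter=segment_slide)
    scored = detection.candidate_mask & (truth.np_single | truth.np_second)
    pred_narrow = detection.assignments == 1
    correct = (truth.np_single & pred_narrow) | (truth.np_second & ~pred_narrow)
    accuracy = float(correct[scored].sum() / scored.sum())
    return {
        "cosine_narrow": cos_narrow,
        "cosine_broad": cos_broad,
        "accuracy": accuracy,
        "n_scored": int(scored.sum()),
        "library": library,
    }
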