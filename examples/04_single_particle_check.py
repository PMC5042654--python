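"""Check whether an isolated detection is consistent with a single particle.

The diffraction-limited spot of a point scatterer through the 40x objective
is approximated by a Gaussian of sigma = 0.21 * lambda / NA (~0.25 um at
910 nm, NA 0.75).  For an isolated NP-positive pixel the horizontal and
vertical plasmon-band intensity profiles are compared with that Gaussian;
low RMSE means the detection is the size of a single point source.
"""

import numpy as np

from hsmad import (
    PipelineConfig,
    PsfModel,
    detect,
    generate_phantom,
    preset_config,
    psf_sigma,
    single_particle_check,
    train_library,
)

model = PsfModel()
print(f"model PSF: sigma = {psf_sigma(model.wavelength_nm, model.numerical_aperture):.1f} nm "
      f"= {psf_sigma(model.wavelength_nm, model.numerical_aperture) / 1000:.2f} um")

size = 128
config = PipelineConfig(seed=0)
training = [generate_phantom(preset_config("lgnr", seed=s, height=size, width=size))[0]
            for s in (0, 1, 2)]
controls = [generate_phantom(preset_config("control", seed=100, height=size, width=size))[0]]
library = train_library(training, config, control_cubes=controls)

cube, truth = generate_phantom(
    preset_config("lgnr", seed=9, height=size, width=size,
                  np_density=0.005, aggregate_fraction=0.0)
)
corrected, segmap, detection = detect(cube, library, config)

n_isolated = n_consistent = shown = 0
for row, col in np.argwhere(detection.np_mask):
    report = single_particle_check(corrected, detection, (row, col), model)
    if not report["isolated"]:
        continue
    n_isolated += 1
    n_consistent += bool(report["consistent"])
    if shown < 5:
        shown += 1
        print(f"pixel ({row}, {col}): RMSE h/v = {report['rmse_h']:.3f}/{report['rmse_v']:.3f}, "
              f"peak offset {report['peak_offset_px']} px -> "
              f"{'single-particle-like' if report['consistent'] else 'off-center or extended'}")
print(f"{n_consistent} of {n_isolated} isolated detections match the pixel-centered "
      "Gaussian spot; the rest are the off-center pixels of sub-pixel particles, "
      "whose profiles the fixed-center model does not fit.")
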