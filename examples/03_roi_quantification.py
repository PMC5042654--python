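"""Quantify nanoparticle uptake per region of interest and across fields.

Splits a phantom field into two ROIs (left / right halves of the tissue),
reports the NP-positive pixel coverage per ROI, and aggregates the relative
NP signal over several fields the way a whole-organ measurement would
(mean +- standard error over fields of view).
"""

import numpy as np

from hsmad import (
    PipelineConfig,
    aggregate_fovs,
    detect,
    generate_phantom,
    pixel_coverage,
    preset_config,
    relative_np_signal,
    train_library,
)

size = 128
config = PipelineConfig(seed=0)
training = [generate_phantom(preset_config("lgnr", seed=s, height=size, width=size))[0]
            for s in (0, 1, 2)]
library = train_library(training, config)

signals = []
for seed in (10, 11, 12, 13):
    cube, truth = generate_phantom(preset_config("lgnr", seed=seed, height=size, width=size))
    corrected, segmap, detection = detect(cube, library, config)
    signals.append(relative_np_signal(corrected, detection, config.np_band))
    if seed == 10:
        roi = np.zeros((size, size), dtype=int)
        roi[:, : size // 2] = 1
        roi[:, size // 2 :] = 2
        for label, name in ((1, "left"), (2, "right")):
            cov = pixel_coverage(detection, roi, label)
            print(f"ROI {name}: pixel coverage {100 * cov:.2f}% of non-background pixels")

mean, sd, sem = aggregate_fovs(signals)
print(f"relative NP signal over {len(signals)} fields: "
      f"{100 * mean:.2f}% +- {100 * sem:.2f}% (mean +- s.e.m.)")
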