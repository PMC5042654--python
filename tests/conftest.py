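"""Shared fixtures: small phantoms and the trained-pipeline benchmark.

The expensive end-to-end study (train on three phantom fields plus controls,
test on a held-out field) is computed once per session and shared between
the pipeline property tests and the acceptance checks.
"""

import numpy as np
import pytest

from hsmad import PipelineConfig, generate_phantom, preset_config
from hsmad.pipeline import phantom_benchmark


@pytest.fixture(scope="session")
def small_phantom():
    """One 96x96 default (nanorod-like) phantom with truth masks."""
    return generate_phantom(preset_config("lgnr", seed=11, height=96, width=96))


@pytest.fixture(scope="session")
def control_phantom():
    """Nanoparticle-free phantom (edge artifacts only)."""
    return generate_phantom(preset_config("control", seed=12, height=96, width=96))


@pytest.fixture(scope="session")
def benchmark_full():
    """Full-scale end-to-end benchmark: 256x256x361, train 3 seeds + controls,
    test a held-out seed.  Wall time is recorded alongside the metrics."""
    import time

    t0 = time.perf_counter()
    result = phantom_benchmark(seed=0, size=256)
    result["elapsed_s"] = time.perf_counter() - t0
    return result


@pytest.fixture(scope="session")
def benchmark_small():
    """Fast end-to-end benchmark for property tests that only need the
    trained library and a detection, not the full-scale study."""
    return phantom_benchmark(seed=1, size=128)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
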