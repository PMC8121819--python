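import numpy as np
import pytest
from hypothesis import settings

from livedead import MicrographFrame, PreprocessParams, SynthSpec

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def default_params():
    return PreprocessParams()


@pytest.fixture
def small_params():
    # small rolling ball keeps tests on tiny images meaningful and fast
    return PreprocessParams(ball_radius=20)


@pytest.fixture
def clean_spec():
    """Moderate-density spec with clean imaging (no haze, mild noise)."""
    return SynthSpec(n_cells=40, frac_dead=0.4, haze_amplitude=0.0,
                     illumination_gradient=0.0, noise_sd=5.0, seed=11)


def random_frame(rng, shape=(32, 32), bit_depth=8):
    hi = (1 << bit_depth) - 1
    dtype = np.uint8 if bit_depth == 8 else np.uint16
    return MicrographFrame(
        green=rng.integers(0, hi + 1, shape, dtype=dtype),
        red=rng.integers(0, hi + 1, shape, dtype=dtype),
        bit_depth=bit_depth,
        source_id="random",
    )
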