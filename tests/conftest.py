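import numpy as np
import pytest

from cervreg.phantom import PhantomConfig, generate_sequence


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free 64x64 phantom with known rigid misalignments."""
    cfg = PhantomConfig(seed=7, noise_sigma=0.0, illumination_jitter=0.0)
    frames, truth = generate_sequence(cfg)
    return cfg, frames, truth


@pytest.fixture(scope="session")
def tiny_phantom():
    """32x32, 5-frame phantom for fast trainer/pipeline tests."""
    cfg = PhantomConfig(
        height=32,
        width=32,
        n_frames=5,
        cervix_axes=(11.0, 9.0),
        os_axes=(3.5, 2.5),
        max_translation=3.0,
        max_rotation=3.0,
        seed=5,
    )
    frames, truth = generate_sequence(cfg)
    return cfg, frames, truth
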