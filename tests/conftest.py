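import numpy as np
import pytest

from invquant import synthetic as syn


@pytest.fixture
def cfg():
    return syn.SynthConfig(seed=42, noise_sd=0.0, frame_interval=1.0, n_samples=50)


@pytest.fixture
def rush_cfg():
    # paper-scale secretory imaging: one frame every 2 min, 80 min total
    return syn.SynthConfig(seed=42, noise_sd=0.0, frame_interval=2.0, n_samples=40)


@pytest.fixture
def small_scene():
    return syn.gen_em_scene(
        n_vesicles=20, diameter_mean=30.0, diameter_sd=9.4, mito_shape=None,
        capture_fraction=1.0, scale=1.0, cfg=syn.SynthConfig(seed=3),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
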