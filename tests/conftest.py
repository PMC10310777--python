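import numpy as np
import pytest

from cyclect import phantom, preprocess


@pytest.fixture(scope="session")
def small_phantom_cfg():
    """Noise-free, jitter-free phantom small enough for fast unit tests."""
    return phantom.PhantomConfig(
        grid_shape=(24, 24, 24),
        contrast_delta_hu=300.0,
        noise_sd_hu=0.0,
        geometry_jitter=0.0,
        n_vessels=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_pair(small_phantom_cfg):
    return phantom.generate_phantom_pair(small_phantom_cfg, seed=3)


@pytest.fixture(scope="session")
def tiny_cohorts():
    """Two tiny normalized cohorts plus the hidden registry."""
    cfg = phantom.PhantomConfig(
        grid_shape=(24, 24, 24), contrast_delta_hu=300.0, noise_sd_hu=10.0, n_vessels=2, seed=5
    )
    a, b, registry = phantom.generate_cohorts(cfg, 2, 2, seed=1)
    norm_a = [preprocess.clip_scale_hu(v) for v in a]
    norm_b = [preprocess.clip_scale_hu(v) for v in b]
    return norm_a, norm_b, registry


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
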