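import numpy as np
import pytest

from angio4d.core import SignalParams
from angio4d.phantom import generate_vessel_tree, make_cohort, rasterize_tree, simulate_dynamics


@pytest.fixture(scope="session")
def small_tree():
    return generate_vessel_tree(3, 0.9, fov_mm=(32.0, 32.0, 24.0), seed=11)


@pytest.fixture(scope="session")
def small_phantom():
    """Noise-free small phantom: (mask, att, volume)."""
    tree = generate_vessel_tree(3, 0.9, fov_mm=(32.0, 32.0, 24.0), seed=11)
    mask, att = rasterize_tree(tree, (32, 32, 16), (1.0, 1.0, 1.5))
    params = SignalParams(noise_sigma=0.0)
    vol = simulate_dynamics(mask, att, params, seed=0, spacing=(1.0, 1.0, 1.5))
    return mask, att, vol


@pytest.fixture(scope="session")
def noisy_cohort():
    return make_cohort(3, (64, 64, 16), SignalParams(), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
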