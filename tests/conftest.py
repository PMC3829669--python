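import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from yeastcount import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def noiseless_scene():
    """10 live + 5 dead + 3 debris, no sensor noise: exact ground truth."""
    spec = SceneSpec(n_live=10, n_dead=5, n_debris=3, noise_sigma=0.0, seed=11)
    return generate_scene(spec)


@pytest.fixture(scope="session")
def noisy_scene():
    """Default-noise 25/25 scene."""
    spec = SceneSpec(n_live=25, n_dead=25, height=384, width=384, seed=7)
    return generate_scene(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
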