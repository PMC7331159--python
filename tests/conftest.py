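import numpy as np
import pytest

from cartstrain.synthetic import ShoulderSpec, make_shoulder


@pytest.fixture(scope="session")
def shoulder():
    """Default-resolution shoulder with the study's thickness statistics."""
    return make_shoulder(ShoulderSpec(seed=1))


@pytest.fixture(scope="session")
def uniform_shoulder():
    """Uniform 0.8 mm layers on a 10 mm head: closed-form oracles apply."""
    return make_shoulder(
        ShoulderSpec(
            humeral_head_radius=10.0,
            cartilage_thickness_mean=0.8,
            cartilage_thickness_sd=0.0,
            seed=2,
        )
    )


@pytest.fixture(scope="session")
def coarse_shoulder():
    """Low-resolution uniform shoulder for the expensive perturbation loops."""
    return make_shoulder(
        ShoulderSpec(
            humeral_head_radius=10.0,
            cartilage_thickness_mean=0.8,
            cartilage_thickness_sd=0.0,
            n_polar=10,
            n_azimuth=20,
            seed=3,
        )
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
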