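import numpy as np
import pytest
from hypothesis import settings

from swarminfer import ModelParams, ModelSpec

settings.register_profile("stable", deadline=None, derandomize=True)
settings.load_profile("stable")


@pytest.fixture
def geometric_spec():
    return ModelSpec()


@pytest.fixture
def reference_params():
    """The bundled reference parameter set (mill-forming)."""
    return ModelParams(
        attraction_weight=0.9,
        alignment_weight=0.15,
        interaction_radius=5.0,
        blind_angle=np.pi / 3,
        noise_sd=0.1,
        speed=0.3,
        arena_size=10.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
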