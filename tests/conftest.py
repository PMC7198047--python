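import numpy as np
import pytest

from woundmetrics.config import PipelineConfig
from woundmetrics.synthetic_fixtures import make_phantom


@pytest.fixture(scope="session")
def fast_config() -> PipelineConfig:
    """Coarse pipeline settings for quick end-to-end tests."""
    return PipelineConfig(som_grid=(24, 24), som_epochs=4, som_conv_epochs=2,
                          chanvese_max_iter=150)


@pytest.fixture(scope="session")
def phantom_a():
    return make_phantom("A")


@pytest.fixture(scope="session")
def phantom_c():
    return make_phantom("C")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
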