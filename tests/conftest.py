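import numpy as np
import pytest
from hypothesis import settings

from kymoquant.config import ExperimentConfig, OpticsConfig

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture
def optics():
    return OpticsConfig()


@pytest.fixture
def optics_no_bleach():
    return OpticsConfig(bleach_rate_at_reference=0.0)


@pytest.fixture
def experiment():
    return ExperimentConfig(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
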