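import numpy as np
import pytest

from ortune.imaging_io import PROTOCOL_PRESETS
from ortune.synthetic import BleachModel, SimulationConfig


@pytest.fixture
def bee_protocol():
    return PROTOCOL_PRESETS["bee"]


@pytest.fixture
def fly_protocol():
    return PROTOCOL_PRESETS["fly"]


@pytest.fixture
def clean_config():
    """Noiseless, bleach-free acquisition: the identity-pipeline condition."""
    return SimulationConfig(noise_sd=0.0, bleach=BleachModel(kind="none"))


@pytest.fixture
def bleached_config():
    """Noiseless recording with the default logarithmic bleach decay."""
    return SimulationConfig(noise_sd=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
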