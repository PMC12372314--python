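import numpy as np
import pytest

from socialbrain import SimConfig, generate_templates


@pytest.fixture(scope="session")
def default_config():
    return SimConfig(seed=11)


@pytest.fixture(scope="session")
def templates(default_config):
    return generate_templates(default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(202)
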