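import numpy as np
import pytest

from remapseq import AgentConfig


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def config():
    return AgentConfig()


@pytest.fixture
def small_config():
    # a small context selector keeps unit tests snappy; the Hebbian
    # constants scale with it automatically
    return AgentConfig(n_context=120, d_stim=20, n_hippocampus=40)
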