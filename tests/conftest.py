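import numpy as np
import pytest

from dedscreen.synthetic_fundus import SynthConfig, generate_fundus


@pytest.fixture(scope="session")
def synth_config() -> SynthConfig:
    return SynthConfig(seed=7)


@pytest.fixture(scope="session")
def dme_fundus(synth_config):
    """One mild-DME synthetic fundus with ground truth (session-cached)."""
    return generate_fundus(synth_config, "mild_dme")


@pytest.fixture(scope="session")
def normal_fundus(synth_config):
    return generate_fundus(synth_config, "normal")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
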