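import numpy as np
import pytest

from dryanfis import GeneratorConfig, generate

FEATURES = ["time_min", "temperature_C", "pretreatment_min"]


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic drying dataset (noise sd 0.01, seed 0)."""
    records, truth = generate(GeneratorConfig(seed=0))
    return records, truth


@pytest.fixture(scope="session")
def noiseless_dataset():
    records, truth = generate(GeneratorConfig(noise_sd=0.0))
    return records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
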