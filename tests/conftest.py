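import numpy as np
import pytest

from swardseg import fixtures, sig


@pytest.fixture(scope="session")
def fixture_config():
    return fixtures.FixtureConfig(image_size=(64, 64), sample_size=28)


@pytest.fixture(scope="session")
def library(fixture_config):
    """A small train-role sample library shared across tests."""
    return fixtures.make_sample_library((8, 8, 2), fixture_config, seed=7, role="train")


@pytest.fixture(scope="session")
def sig_config():
    return sig.SigConfig(n_samples_range=(2, 10))


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
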