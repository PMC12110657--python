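import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from fnirspeech.montage import paper_montage
from fnirspeech.simulate import mini_config, simulate_participant


@pytest.fixture(scope="session")
def paper_map():
    return paper_montage()


@pytest.fixture(scope="session")
def mini_sim():
    """One deterministic mini-profile participant with default noise."""
    return simulate_participant(mini_config(), seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
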