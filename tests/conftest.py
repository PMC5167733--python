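import pytest

from somadcm.nmm import build_model, simulate_sources
from somadcm.observation import synthetic_gain
from somadcm.preprocess import epoch_times


@pytest.fixture(scope="session")
def epoch_grid():
    """The 500 Hz epoch time axis, [-50, 300] ms."""
    return epoch_times()


@pytest.fixture(scope="session")
def model_c():
    return build_model("C")


@pytest.fixture(scope="session")
def gain102():
    return synthetic_gain(seed=0)


@pytest.fixture(scope="session")
def sources_c(model_c, epoch_grid):
    """Noiseless source simulation of architecture C on the epoch grid."""
    return simulate_sources(model_c, epoch_grid)
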