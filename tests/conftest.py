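import numpy as np
import pytest

from cvrpipe.config import PipelineConfig
from cvrpipe.paradigm import ParadigmSpec, build_paradigm


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()


@pytest.fixture(scope="session")
def paradigm():
    """Default challenge at the physiological sampling rate."""
    return build_paradigm(ParadigmSpec(), 100.0, seed=0)


@pytest.fixture(scope="session")
def volume_times(config):
    """Acquisition times of the retained BOLD volumes (after discard)."""
    n_ret = 480 - config.n_discard_volumes
    return config.n_discard_volumes * config.tr + np.arange(n_ret) * config.tr


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
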