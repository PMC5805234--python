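import numpy as np
import pytest

import glucoloop as gl


@pytest.fixture(scope="session")
def ngr_preset():
    return gl.condition_preset("NGR")


@pytest.fixture(scope="session")
def t2dm_preset():
    return gl.condition_preset("T2DM")


@pytest.fixture(scope="session")
def default_config():
    return gl.SimulationConfig(duration=1000.0)


@pytest.fixture(scope="session")
def ngr_trajectory(ngr_preset, default_config):
    """Full 1000-min NGR closed-loop run, shared across tests."""
    return gl.simulate(ngr_preset, default_config)


@pytest.fixture(scope="session")
def t2dm_trajectory(t2dm_preset, default_config):
    """Matched 1000-min T2DM run."""
    return gl.simulate(t2dm_preset, default_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
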