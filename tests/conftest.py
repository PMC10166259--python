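import numpy as np
import pytest

from freilick.agents import make_agent
from freilick.synthetic import gen_validation_scene
from freilick.task import TaskConfig, run_session


@pytest.fixture(scope="session")
def validation_scene():
    """Small detector-validation fixture: 60 well-separated licks, SNR 10."""
    return gen_validation_scene(n_licks=60, seed=11)


@pytest.fixture(scope="session")
def perfect_session():
    """Four-block session driven by the oracle agent."""
    cfg = TaskConfig(n_blocks=4, seed=5)
    return run_session(cfg, make_agent("perfect", seed=5), max_trials=80)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
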