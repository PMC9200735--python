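import copy

import numpy as np
import pytest

from baymix.engine import run
from baymix.synthetic import generate_config, generate_observations


@pytest.fixture(scope="session")
def tiny_truth():
    """A tiny truth configuration (fixed seed) shared across tests."""
    return generate_config(1, "tiny")


@pytest.fixture(scope="session")
def tiny_store(tiny_truth):
    return run(tiny_truth)


@pytest.fixture(scope="session")
def tiny_obs(tiny_truth, tiny_store):
    """Noise-free observation bundle from the tiny truth run."""
    return generate_observations(tiny_store, tiny_truth)


@pytest.fixture()
def tiny_config(tiny_truth):
    """A mutable copy of the tiny truth configuration."""
    return copy.deepcopy(tiny_truth)


@pytest.fixture(scope="session")
def calibration_start(tiny_truth):
    """The truth config with accessibilities reset to the calibration start."""
    cfg = copy.deepcopy(tiny_truth)
    for s in cfg.stocks.values():
        if s.accessibility is not None:
            s.accessibility = np.where(s.accessibility > 0, 0.5, 0.0)
    return cfg
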