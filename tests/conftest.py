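import numpy as np
import pytest

from claw_cbgt.config import default_config
from claw_cbgt.simulate import run_experiment


@pytest.fixture(scope="session")
def base_config():
    return default_config()


@pytest.fixture(scope="session")
def small_trial_set(base_config):
    """12 trials of the default network, shared across tests."""
    _, trials = run_experiment(base_config, 12, seed=42)
    return trials


@pytest.fixture(scope="session")
def scripted_thresholds():
    """Hand-set binarization thresholds for scripted-trace fixtures."""
    thr = {}
    for name in ("dSPN-L", "dSPN-R", "iSPN-L", "iSPN-R",
                 "GPi-L", "GPi-R", "GPeP-L", "GPeP-R"):
        thr[name] = 20.0
    thr["Th-L"] = 15.0
    thr["Th-R"] = 15.0
    return thr


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
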