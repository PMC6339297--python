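import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gridpick as gp

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def sim_dataset():
    """One deterministic synthetic micrograph: 25 well-separated particles on 512x512.

    Returns (cfg, truth, noisy, pmap); shared read-only across tests.
    """
    cfg = gp.SimConfig(seed=11)
    truth, noisy, pmap = gp.simulate_micrograph(cfg, n_lobes=1)
    return cfg, truth, noisy, pmap
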