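import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vsperf.phantom import PhantomConfig, simulate_both_modes, simulate_series

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_config() -> PhantomConfig:
    return PhantomConfig().with_seed(1)


@pytest.fixture(scope="session")
def sim_results(default_config):
    """Conventional and velocity-selective series from one seed."""
    return simulate_both_modes(default_config)


@pytest.fixture(scope="session")
def noiseless_results():
    """Both modes with noise switched off (for round-trip checks)."""
    import dataclasses

    cfg = PhantomConfig()
    cfg = dataclasses.replace(
        cfg, protocol=dataclasses.replace(cfg.protocol, noise_sigma=0.0, seed=7))
    return simulate_both_modes(cfg)
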