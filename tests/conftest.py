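import numpy as np
import pytest

import hpfret as hp


@pytest.fixture(scope="session")
def neat_scheme() -> hp.KineticScheme:
    """Two-state hairpin at the neat-buffer rates: k_f = 7.5, k_u = 3.13 s^-1."""
    return hp.two_state_scheme(7.5, 3.13)


@pytest.fixture(scope="session")
def quiet_acq() -> hp.AcquisitionConfig:
    """Contaminant-free acquisition for tests that track a single species."""
    return hp.AcquisitionConfig(contaminant_fractions=(0.0, 0.0))


@pytest.fixture(scope="session")
def symmetric_bursts(neat_scheme, quiet_acq) -> hp.BurstSet:
    """10k bursts from an equal open/closed population (shared across tests)."""
    return hp.simulate_bursts(
        [0.5, 0.5], neat_scheme, 10_000, 100.0, quiet_acq, seed=1234
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
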