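import numpy as np
import pytest

from leafgm import DrydownScenario, FvCBParams, generate_observations


@pytest.fixture(scope="session")
def fvcb_params():
    """The worked-example FvCB parameter set (round numbers)."""
    return FvCBParams(Vcmax=100.0, Rd=1.0, gamma_star=40.0, Kc=270.0,
                      Ko=165.0, O=210.0, Jmax=160.0)


@pytest.fixture(scope="session")
def default_scenario():
    return DrydownScenario(seed=7)


@pytest.fixture(scope="session")
def zero_noise_tables(default_scenario):
    """Noiseless default drydown (no A/Ci curves; shared across tests)."""
    return generate_observations(default_scenario.zero_noise(), include_aci=False)


@pytest.fixture(scope="session")
def noisy_tables(default_scenario):
    """Default-noise drydown with A/Ci curves (shared across tests)."""
    return generate_observations(default_scenario, include_aci=True)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
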