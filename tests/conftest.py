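import warnings

import pytest

from chemobalance.presets import (
    reference_cell_counts,
    reference_config,
    reference_state,
)
from chemobalance.trophic import allocate_fluxes


@pytest.fixture(scope="session")
def ref_config():
    return reference_config()


@pytest.fixture(scope="session")
def ref_state():
    return reference_state()


@pytest.fixture(scope="session")
def ref_counts():
    return reference_cell_counts()


@pytest.fixture(scope="session")
def ref_fluxes(ref_state, ref_config):
    # the measured steady state is electron-overcommitted by design, so the
    # donor-capacity warning is expected here
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return allocate_fluxes(ref_state, ref_config)


@pytest.fixture(scope="session")
def sim_result():
    """Default community trajectory, shared across tests (deterministic)."""
    from chemobalance.simulate import default_scenario, simulate_scenario

    return simulate_scenario(default_scenario(), seed=1)
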