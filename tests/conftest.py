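import numpy as np
import pytest

from erfate import (
    ModelParameters,
    constant_stress,
    resting_state,
    simulate_ensemble,
)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def rest(params):
    return resting_state(params)


@pytest.fixture(scope="session")
def ens_s5(params):
    """Shared 20-cell ensemble at S0 = 5 (the high-stress condition)."""
    return simulate_ensemble(params, constant_stress(5.0, 240.0), n_cells=20, master_seed=7)


@pytest.fixture(scope="session")
def ens_s1(params):
    """Shared 20-cell ensemble at S0 = 1 (the low-stress condition)."""
    return simulate_ensemble(params, constant_stress(1.0, 240.0), n_cells=20, master_seed=7)
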