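import numpy as np
import pytest

from kinetoswitch import ModelParams, SIMULATION_PARAMS, simulate_trajectory


@pytest.fixture(scope="session")
def params():
    """Reference oscillatory parameter set."""
    return SIMULATION_PARAMS


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free, switch-free variant for deterministic dynamics."""
    return SIMULATION_PARAMS.with_(s2=0.0, p_incoherent=0.0, p_coherent=0.0)


@pytest.fixture(scope="session")
def sim_traj(params):
    """One 150-frame simulated trajectory with truth."""
    return simulate_trajectory(params, n_frames=150, seed=42)
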