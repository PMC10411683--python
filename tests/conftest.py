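import numpy as np
import pytest

from thetaconflict import simulate as sim
from thetaconflict import task_design as td


@pytest.fixture(scope="session")
def characteristic_sets():
    return sim.default_characteristics()


@pytest.fixture(scope="session")
def small_trials(characteristic_sets):
    pos, neg = characteristic_sets
    return td.build_trial_sequence(pos, neg, n_blocks=1, rng_seed=7)


@pytest.fixture(scope="session")
def quiet_config():
    """Artifact-free, ERP-free configuration for signal-level checks."""
    return sim.SimConfig(n_participants=1, n_blocks=1, artifact_rate=0.0,
                         erp_components=(), seed=42)


@pytest.fixture(scope="session")
def simulated_participant(quiet_config, small_trials):
    return sim.simulate_recording(quiet_config, small_trials, "P00")


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
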