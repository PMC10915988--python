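import numpy as np
import pytest

from swdsim.engine import PerturbationEvent, SimulationConfig, run_simulation
from swdsim.network import build_default_network

DESK_SCALE = 5.0


@pytest.fixture(scope="session")
def desk_network():
    return build_default_network(seed=1, scale=DESK_SCALE)


@pytest.fixture(scope="session")
def full_network():
    return build_default_network(seed=1, scale=1.0)


@pytest.fixture(scope="session")
def short_run(desk_network):
    """A 6 s unperturbed desk-scale run shared across engine tests."""
    cfg = SimulationConfig(duration=6000.0, seed=7)
    return run_simulation(desk_network, cfg)


@pytest.fixture(scope="session")
def tonic_seizure_runs(desk_network):
    """The increased-tonic-inhibition scenario at desk scale, three seeds.

    These runs back the ictal analyses; they are 120 s each, matching the
    desk-scale protocol of the scenario catalogue.
    """
    perts = [PerturbationEvent("TC_FO", "g_KL", 1.05, onset=5000.0)]
    out = []
    for seed in (1, 2, 3):
        cfg = SimulationConfig(duration=60000.0, seed=seed)
        out.append(run_simulation(desk_network, cfg, perts))
    return out
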