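import numpy as np
import pytest

from sealmito.protocols import default_protocols
from sealmito.respirometry import OxygenTrace, TitrationEvent
from sealmito.synthetic import TraceSpec, simulate_trace

TRUE_FLUXES = {"Ln": 5.0, "OXPHOS": 40.0, "LOmy": 8.0, "ETS": 55.0,
               "CI": 30.0, "CII": 25.0}


@pytest.fixture(scope="session")
def protocols():
    return default_protocols()


@pytest.fixture
def linear_trace():
    """Conc declining 1 nmol ml^-1 s^-1; volume 2 ml, mass 2 mg."""
    t = np.arange(0.0, 120.0, 1.0)
    conc = 400.0 - 1.0 * t
    return OxygenTrace(
        run_id="lin", animal_id="a1", timepoint="pre", protocol_id="B",
        t=t, conc=conc, chamber_volume=2.0, tissue_mass=2.0,
    )


@pytest.fixture
def constant_trace():
    t = np.arange(0.0, 120.0, 1.0)
    return OxygenTrace(
        run_id="const", animal_id="a1", timepoint="pre", protocol_id="B",
        t=t, conc=np.full_like(t, 300.0), chamber_volume=2.0, tissue_mass=2.0,
    )


@pytest.fixture
def noiseless_b_run(protocols):
    """Protocol B trace with known plateaus and its ground truth."""
    spec = TraceSpec(protocol_id="B", true_state_fluxes=TRUE_FLUXES,
                     noise_sd=0.0, seed=7)
    return simulate_trace(spec, protocols)


def make_events(times_agents):
    return [TitrationEvent(t=t, agent=a) for t, a in times_agents]
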