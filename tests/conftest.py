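import numpy as np
import pytest

from hopdyn.md import EngineSet, InitialCondition, PhaseSpaceState
from hopdyn.qmmm import partition_system
from hopdyn.surfaces import SurfaceEngine, make_avoided_crossing_model, zero_engine


@pytest.fixture(scope="session")
def two_state_model():
    return make_avoided_crossing_model(2)


@pytest.fixture(scope="session")
def three_state_model():
    return make_avoided_crossing_model(3)


def gas_phase_engines(model) -> EngineSet:
    """EngineSet for a bare solute: the low-level engine contributes nothing."""
    return EngineSet(surface=model, high=SurfaceEngine(model), low=zero_engine)


def solute_state(model, x, v) -> PhaseSpaceState:
    part = partition_system(model.n_dof, range(model.n_dof))
    return PhaseSpaceState(
        positions=np.atleast_1d(np.asarray(x, float)),
        velocities=np.atleast_1d(np.asarray(v, float)),
        masses=model.masses,
        time=0.0,
        partition=part,
    )


def excited_init(model, x=-2.0, v=0.02, surface=None) -> InitialCondition:
    surface = model.n_states - 1 if surface is None else surface
    return InitialCondition(
        state=solute_state(model, x, v),
        start_surface=surface,
        excitation_energy=1.0,
        transition_strength=0.1,
    )
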