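"""Classical nuclear propagation, solvent-only Andersen thermostat, ground-state
sampling and initial-condition selection for the excited-state swarm.

The nuclear equations of motion are integrated with velocity Verlet, with forces
taken as the negative gradient of the subtractive QM/MM energy on the occupied
electronic surface.  An Andersen thermostat couples *only* the solvent (MM)
degrees of freedom to a heat bath: each masked DOF has its velocity redrawn from
the Maxwell-Boltzmann distribution with probability ``1 - exp(-nu * dt)`` per
step, which drives the bath to the canonical distribution while leaving the
chromophore untouched.

Ground-state sampling runs store strided snapshots together with the vertical
excitation energies and surrogate oscillator strengths at each stored geometry;
initial conditions for the hopping swarm are then the snapshots whose target
excitation energy falls in a chosen window (criterion a) and whose transition
strength exceeds a threshold (criterion b).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .qmmm import Engine, RegionPartition, subtractive_energy_and_gradient
from .surfaces import ModelSurface, evaluate_surface, maxwell_boltzmann_velocities
from .units import EV_PER_AMU_ANG2_FS2, KB_EV, kinetic_energy

__all__ = [
    "PhaseSpaceState",
    "SamplingConfig",
    "Snapshot",
    "InitialCondition",
    "EngineSet",
    "velocity_verlet_step",
    "andersen_thermostat",
    "run_ground_state_md",
    "select_initial_conditions",
]


@dataclass(frozen=True)
class PhaseSpaceState:
    """Positions/velocities/masses over all DOFs (A, A/fs, amu) plus the region split."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    time: float
    partition: RegionPartition

    def __post_init__(self) -> None:
        for name in ("positions", "velocities", "masses"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite entries in {name}")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if self.positions.size != self.partition.total_dof:
            raise ValueError("state size does not match partition")

    def kinetic_energy(self) -> float:
        return kinetic_energy(self.masses, self.velocities)


@dataclass(frozen=True)
class SamplingConfig:
    """Run parameters for ground-state sampling and hopping dynamics.

    ``dt_ground`` and ``dt_hopping`` are the nuclear time steps (fs) of the
    ground-state and surface-hopping stages; ``t_ground_ps`` the length of the
    phase-space search; ``stride`` the snapshot spacing in ground-state steps
    (decorrelates initial conditions); ``collision_frequency`` the Andersen
    collision rate (1/fs) on solvent DOFs.
    """

    dt_ground: float = 0.5
    dt_hopping: float = 0.1
    t_ground_ps: float = 10.0
    temperature: float = 298.0
    collision_frequency: float = 0.01
    stride: int = 10
    seed: int = 0
    energy_bound: float = 1.0e3

    def __post_init__(self) -> None:
        if self.dt_ground <= 0 or self.dt_hopping <= 0:
            raise ValueError("time steps must be positive")
        if self.t_ground_ps * 1000.0 < self.dt_ground:
            raise ValueError("t_ground must cover at least one step")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass(frozen=True)
class Snapshot:
    """A stored ground-state geometry with its vertical excitation data."""

    state: PhaseSpaceState
    energies: np.ndarray  # adiabatic solute energies (eV)
    excitation_energies: np.ndarray  # E_alpha - E_0 for alpha >= 1 (eV)
    oscillator_strengths: np.ndarray  # per excited state alpha >= 1


@dataclass(frozen=True)
class InitialCondition:
    """A selected swarm starting point: geometry, target surface, excitation data."""

    state: PhaseSpaceState
    start_surface: int
    excitation_energy: float
    transition_strength: float

    def __post_init__(self) -> None:
        if self.start_surface < 1:
            raise ValueError("hopping dynamics must start on an excited surface")


@dataclass(frozen=True)
class EngineSet:
    """High- and low-level engines plus the model surface behind the high level."""

    surface: ModelSurface
    high: Engine
    low: Engine

    def ground_force(self, partition: RegionPartition, x: np.ndarray) -> np.ndarray:
        comb = subtractive_energy_and_gradient(partition, self.high, self.low, x, state=0)
        return comb.forces


def _accelerations(forces: np.ndarray, masses: np.ndarray) -> np.ndarray:
    return forces / (masses * EV_PER_AMU_ANG2_FS2)


def velocity_verlet_step(
    state: PhaseSpaceState,
    force_fn: Callable[[np.ndarray], np.ndarray],
    dt: float,
    force0: np.ndarray | None = None,
    return_force: bool = False,
):
    """One velocity-Verlet step; pass ``force0`` to reuse the force at the current geometry.

    With ``return_force=True`` the force at the new geometry is returned as well,
    so propagation loops evaluate each force exactly once.
    """
    if dt == 0:
        raise ValueError("dt must be nonzero")
    f0 = force_fn(state.positions) if force0 is None else force0
    if not np.all(np.isfinite(f0)):
        raise RuntimeError(f"non-finite force at t={state.time} fs; geometry: {state.positions!r}")
    a0 = _accelerations(f0, state.masses)
    x1 = state.positions + state.velocities * dt + 0.5 * a0 * dt * dt
    f1 = force_fn(x1)
    if not np.all(np.isfinite(f1)):
        raise RuntimeError(f"non-finite force at t={state.time + dt} fs; geometry: {x1!r}")
    a1 = _accelerations(f1, state.masses)
    v1 = state.velocities + 0.5 * (a0 + a1) * dt
    new = replace(state, positions=x1, velocities=v1, time=state.time + dt)
    return (new, f1) if return_force else new


def andersen_thermostat(
    state: PhaseSpaceState,
    solvent_mask: np.ndarray,
    temperature: float,
    collision_frequency: float,
    dt: float,
    rng: np.random.Generator,
) -> PhaseSpaceState:
    """Resample masked (solvent) DOF velocities with collision probability 1 - exp(-nu dt).

    The mask must not touch the QM region: the thermostat acts on the solvent
    only, and chromophore velocities pass through bit-identically.
    """
    mask = np.asarray(solvent_mask, dtype=bool)
    if mask.shape != state.velocities.shape:
        raise ValueError("solvent mask must cover every DOF")
    if np.any(mask[state.partition.qm_indices]):
        raise ValueError("thermostat mask touches the QM region")
    if collision_frequency < 0:
        raise ValueError("collision frequency must be >= 0")
    if collision_frequency == 0 or not mask.any():
        return state
    p_collide = 1.0 - np.exp(-collision_frequency * dt)
    hit = mask & (rng.random(mask.size) < p_collide)
    if not hit.any():
        return state
    v = state.velocities.copy()
    v[hit] = maxwell_boltzmann_velocities(state.masses[hit], temperature, rng)
    return replace(state, velocities=v)


def run_ground_state_md(
    initial: PhaseSpaceState,
    engines: EngineSet,
    config: SamplingConfig,
    rng: np.random.Generator | None = None,
) -> list[Snapshot]:
    """Thermostatted ground-state run storing strided snapshots with excitation data.

    Every stored snapshot re-evaluates the model surface at the solute geometry
    to attach vertical excitation energies and oscillator strengths — the raw
    material for swarm initial-condition selection.  If the combined energy
    exceeds ``config.energy_bound`` the run truncates with a warning rather than
    propagating a blow-up.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    part = initial.partition
    mask = part.solvent_mask()
    force_fn = lambda x: engines.ground_force(part, x)  # noqa: E731

    n_steps = int(round(config.t_ground_ps * 1000.0 / config.dt_ground))
    snapshots: list[Snapshot] = []
    state = initial
    force = force_fn(state.positions)
    for step in range(1, n_steps + 1):
        state, force = velocity_verlet_step(
            state, force_fn, config.dt_ground, force0=force, return_force=True
        )
        state = andersen_thermostat(
            state, mask, config.temperature, config.collision_frequency, config.dt_ground, rng
        )
        if step % config.stride == 0:
            res = evaluate_surface(engines.surface, state.positions[part.qm_indices])
            comb = subtractive_energy_and_gradient(part, engines.high, engines.low, state.positions, 0)
            if abs(comb.e_total) > config.energy_bound:
                warnings.warn(
                    f"energy bound exceeded at t={state.time:.1f} fs "
                    f"(E={comb.e_total:.3g} eV); truncating ground-state run",
                    RuntimeWarning,
                    stacklevel=2,
                )
                break
            snapshots.append(
                Snapshot(
                    state=state,
                    energies=res.energies,
                    excitation_energies=res.energies[1:] - res.energies[0],
                    oscillator_strengths=res.oscillator_strengths[1:],
                )
            )
    return snapshots


def select_initial_conditions(
    snapshots: Sequence[Snapshot],
    energy_window: tuple[float, float],
    strength_threshold: float,
    target_surface: int = 2,
) -> list[InitialCondition]:
    """Filter snapshots by the two swarm-selection criteria.

    A snapshot survives when (a) its vertical excitation energy to
    ``target_surface`` lies inside ``energy_window`` (inclusive) and (b) its
    transition strength exceeds ``strength_threshold``.  The filter is pure:
    output is an order-preserving subset of the input, and applying it twice
    changes nothing.  An empty selection warns loudly rather than failing
    silently.
    """
    lo, hi = energy_window
    if lo > hi:
        raise ValueError("energy window must satisfy lo <= hi")
    out: list[InitialCondition] = []
    for snap in snapshots:
        idx = target_surface - 1
        if idx >= snap.excitation_energies.size:
            raise ValueError(
                f"snapshot has no excitation data for surface {target_surface}"
            )
        de = float(snap.excitation_energies[idx])
        f = float(snap.oscillator_strengths[idx])
        if lo <= de <= hi and f > strength_threshold:
            out.append(
                InitialCondition(
                    state=snap.state,
                    start_surface=target_surface,
                    excitation_energy=de,
                    transition_strength=f,
                )
            )
    if not out:
        warnings.warn(
            "initial-condition selection is empty: no snapshot satisfies the "
            "energy window and strength threshold",
            UserWarning,
            stacklevel=2,
        )
    return out
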