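"""Nuclear propagation, thermostat contract, ground-state sampling and selection."""

import warnings

import numpy as np
import pytest

from hopdyn.md import (
    EngineSet,
    PhaseSpaceState,
    SamplingConfig,
    Snapshot,
    andersen_thermostat,
    run_ground_state_md,
    select_initial_conditions,
    velocity_verlet_step,
)
from hopdyn.qmmm import partition_system
from hopdyn.surfaces import SurfaceEngine, make_avoided_crossing_model, zero_engine
from hopdyn.units import EV_PER_AMU_ANG2_FS2, KB_EV

from conftest import gas_phase_engines, solute_state


def _free_state(n=3):
    part = partition_system(n, [0])
    return PhaseSpaceState(
        positions=np.linspace(0, 1, n),
        velocities=np.full(n, 0.3),
        masses=np.full(n, 2.0),
        time=0.0,
        partition=part,
    )


def test_free_particle_moves_uniformly():
    state = _free_state()
    zero = lambda x: np.zeros_like(x)  # noqa: E731
    out = state
    for _ in range(10):
        out = velocity_verlet_step(out, zero, 0.5)
    assert np.allclose(out.positions, state.positions + 0.3 * 5.0, atol=1e-14)
    assert np.array_equal(out.velocities, state.velocities)
    assert out.time == pytest.approx(5.0)


def test_harmonic_oscillator_energy_drift():
    """10^4 velocity-Verlet steps at dt = T/100 keep the energy to < 1e-4 relative."""
    k, m = 0.5, 4.0  # eV/A^2, amu
    part = partition_system(1, [0])
    state = PhaseSpaceState(
        positions=np.array([0.8]), velocities=np.array([0.0]), masses=np.array([m]),
        time=0.0, partition=part,
    )
    omega = np.sqrt(k / (m * EV_PER_AMU_ANG2_FS2))
    dt = (2 * np.pi / omega) / 100.0
    force = lambda x: -k * x  # noqa: E731

    def energy(s):
        return s.kinetic_energy() + 0.5 * k * float(s.positions @ s.positions)

    e0 = energy(state)
    f = force(state.positions)
    for _ in range(10_000):
        state, f = velocity_verlet_step(state, force, dt, force0=f, return_force=True)
    assert abs(energy(state) - e0) / e0 < 1e-4


def test_velocity_verlet_is_time_reversible():
    k = 0.3
    force = lambda x: -k * x  # noqa: E731
    state = _free_state()
    forward = state
    for _ in range(50):
        forward = velocity_verlet_step(forward, force, 0.4)
    back = forward
    for _ in range(50):
        back = velocity_verlet_step(back, force, -0.4)
    assert np.allclose(back.positions, state.positions, atol=1e-10)
    assert np.allclose(back.velocities, state.velocities, atol=1e-10)


def test_nve_energy_drift_scales_as_dt_squared():
    """Halving the hopping-scale time step cuts the subtractive-energy drift ~4x."""
    model = make_avoided_crossing_model(2)
    engines = gas_phase_engines(model)
    part = partition_system(1, [0])

    def drift(dt):
        state = solute_state(model, -2.0, 0.03)
        force = lambda x: engines.ground_force(part, x)  # noqa: E731
        e0 = state.kinetic_energy() + engines.high(state.positions, 0)[0]
        f = force(state.positions)
        worst = 0.0
        for _ in range(int(40.0 / dt)):
            state, f = velocity_verlet_step(state, force, dt, force0=f, return_force=True)
            e = state.kinetic_energy() + engines.high(state.positions, 0)[0]
            worst = max(worst, abs(e - e0))
        return worst

    ratio = drift(0.4) / drift(0.2)
    assert 2.5 < ratio < 6.0


def test_non_finite_force_aborts_with_geometry():
    state = _free_state()
    bad = lambda x: np.full_like(x, np.nan)  # noqa: E731
    with pytest.raises(RuntimeError, match="non-finite force"):
        velocity_verlet_step(state, bad, 0.1)


# ---------------------------------------------------------------------------
# Andersen thermostat
# ---------------------------------------------------------------------------


def _bath_state(n_solvent=20):
    total = 1 + n_solvent
    part = partition_system(total, [0])
    rng = np.random.default_rng(1)
    return PhaseSpaceState(
        positions=rng.normal(0, 1, total),
        velocities=rng.normal(0, 0.01, total),
        masses=np.full(total, 18.0),
        time=0.0,
        partition=part,
    )


def test_zero_collision_frequency_is_identity():
    state = _bath_state()
    out = andersen_thermostat(
        state, state.partition.solvent_mask(), 298.0, 0.0, 0.5, np.random.default_rng(0)
    )
    assert out is state


def test_solute_velocities_bit_identical():
    state = _bath_state()
    rng = np.random.default_rng(3)
    out = state
    for _ in range(200):
        out = andersen_thermostat(out, out.partition.solvent_mask(), 298.0, 0.5, 0.5, rng)
    assert out.velocities[0] == state.velocities[0]
    assert not np.array_equal(out.velocities[1:], state.velocities[1:])


def test_mask_touching_qm_region_rejected():
    state = _bath_state()
    mask = np.ones(state.positions.size, dtype=bool)
    with pytest.raises(ValueError, match="QM region"):
        andersen_thermostat(state, mask, 298.0, 0.1, 0.5, np.random.default_rng(0))


def test_thermostatted_harmonic_bath_equipartition():
    """NVT run of tethered solvent DOFs: mean KE per masked DOF -> kT/2 within 3%."""
    T, k, dt, nu = 298.0, 0.08, 1.0, 0.05
    state = _bath_state(n_solvent=20)
    mask = state.partition.solvent_mask()
    force = lambda x: -k * x  # noqa: E731
    rng = np.random.default_rng(21)
    samples = []
    f = force(state.positions)
    n_steps = 9000
    for step in range(n_steps):
        state, f = velocity_verlet_step(state, force, dt, force0=f, return_force=True)
        state = andersen_thermostat(state, mask, T, nu, dt, rng)
        if step > 1000:
            v = state.velocities[mask]
            samples.append(0.5 * EV_PER_AMU_ANG2_FS2 * np.mean(18.0 * v * v))
    assert len(samples) * int(mask.sum()) > 100_000
    assert np.mean(samples) == pytest.approx(0.5 * KB_EV * T, rel=0.03)


# ---------------------------------------------------------------------------
# ground-state sampling and selection
# ---------------------------------------------------------------------------


def test_snapshot_count_arithmetic():
    """t_ground / (dt * stride) snapshots, e.g. 10 ps at 0.5 fs stride 10 -> 2000."""
    model = make_avoided_crossing_model(2)
    engines = gas_phase_engines(model)
    cfg = SamplingConfig(dt_ground=0.5, t_ground_ps=0.05, stride=10, collision_frequency=0.0)
    snaps = run_ground_state_md(solute_state(model, -2.0, 0.0), engines, cfg)
    assert len(snaps) == int(0.05 * 1000 / (0.5 * 10))
    # the full-scale setting follows the same arithmetic
    assert int(10.0 * 1000 / (0.5 * 10)) == 2000


def test_ground_state_md_deterministic():
    model = make_avoided_crossing_model(2)
    engines = gas_phase_engines(model)
    cfg = SamplingConfig(dt_ground=0.5, t_ground_ps=0.02, stride=4, seed=5)
    a = run_ground_state_md(solute_state(model, -2.0, 0.01), engines, cfg)
    b = run_ground_state_md(solute_state(model, -2.0, 0.01), engines, cfg)
    assert len(a) == len(b)
    for sa, sb in zip(a, b):
        assert np.array_equal(sa.state.positions, sb.state.positions)
        assert np.array_equal(sa.excitation_energies, sb.excitation_energies)


def _toy_snapshots():
    model = make_avoided_crossing_model(2)
    base = solute_state(model, 0.0, 0.0)
    energies = [3.9, 4.1, 4.3, 4.5, 4.7]
    strengths = [0.2, 0.0, 0.3, 0.4, 0.0]
    return [
        Snapshot(
            state=base,
            energies=np.array([0.0, de]),
            excitation_energies=np.array([de]),
            oscillator_strengths=np.array([f]),
        )
        for de, f in zip(energies, strengths)
    ]


def test_selection_hand_enumeration():
    """Window [4.0, 4.6] eV with threshold 0.1 keeps exactly the 4.3 and 4.5 snapshots."""
    out = select_initial_conditions(_toy_snapshots(), (4.0, 4.6), 0.1, target_surface=1)
    assert [ic.excitation_energy for ic in out] == [4.3, 4.5]
    assert [ic.transition_strength for ic in out] == [0.3, 0.4]
    assert all(ic.start_surface == 1 for ic in out)


def test_selection_vacuous_filter_keeps_all():
    snaps = _toy_snapshots()
    out = select_initial_conditions(snaps, (-np.inf, np.inf), -1.0, target_surface=1)
    assert len(out) == len(snaps)


def test_selection_overtight_filter_warns_and_returns_empty():
    with pytest.warns(UserWarning, match="empty"):
        out = select_initial_conditions(_toy_snapshots(), (4.0, 4.6), 1.0, target_surface=1)
    assert out == []


def test_selection_is_a_pure_order_preserving_filter():
    snaps = _toy_snapshots()
    out = select_initial_conditions(snaps, (4.0, 4.8), 0.1, target_surface=1)
    kept = [s for s in snaps if 4.0 <= s.excitation_energies[0] <= 4.8 and s.oscillator_strengths[0] > 0.1]
    assert [ic.excitation_energy for ic in out] == [float(s.excitation_energies[0]) for s in kept]
    # idempotence: re-filtering the survivors' snapshots changes nothing
    again = select_initial_conditions(kept, (4.0, 4.8), 0.1, target_surface=1)
    assert [ic.excitation_energy for ic in again] == [ic.excitation_energy for ic in out]
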