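"""Amplitude propagation, Tully probabilities, hop mechanics and full trajectories."""

import math
import warnings

import numpy as np
import pytest
from scipy.linalg import expm

from hopdyn.fssh import (
    AmplitudeNormError,
    CouplingSnapshot,
    ElectronicAmplitudes,
    HoppingConfig,
    attempt_hop,
    hop_probabilities,
    propagate_amplitudes,
    run_hopping_trajectory,
)
from hopdyn.md import PhaseSpaceState
from hopdyn.qmmm import partition_system
from hopdyn.surfaces import (
    DiabaticState,
    GaussianCoupling,
    ModelSurface,
    make_avoided_crossing_model,
)
from hopdyn.units import EV_PER_AMU_ANG2_FS2, HBAR_EV_FS

from conftest import excited_init, gas_phase_engines, solute_state


def _snap(E, sigma):
    E = np.asarray(E, float)
    n = E.size
    S = np.zeros((n, n))
    if sigma:
        for (b, a), v in sigma.items():
            S[b, a] = v
            S[a, b] = -v
    return CouplingSnapshot(energies=E, tdc=S)


def test_uncoupled_states_evolve_as_pure_phases():
    E = [0.3, 1.7]
    snap = _snap(E, {})
    amps = ElectronicAmplitudes(np.array([0.6, 0.8], dtype=complex), 0)
    out = amps
    t = 0.0
    for _ in range(50):
        out = propagate_amplitudes(out, snap, snap, 0.1)
        t += 0.1
    expected = amps.c * np.exp(-1j * np.array(E) * t / HBAR_EV_FS)
    assert np.allclose(out.c, expected, atol=1e-10)
    assert np.allclose(out.populations, amps.populations, atol=1e-12)


def test_amplitude_norm_conserved_each_step():
    rng = np.random.default_rng(14)
    for _ in range(30):
        E0 = np.sort(rng.uniform(0, 3, 3))
        E1 = E0 + rng.normal(0, 0.05, 3)
        s0 = {(0, 1): rng.normal(0, 0.3), (1, 2): rng.normal(0, 0.3), (0, 2): rng.normal(0, 0.1)}
        s1 = {k: v + rng.normal(0, 0.02) for k, v in s0.items()}
        c = rng.normal(size=3) + 1j * rng.normal(size=3)
        c /= np.linalg.norm(c)
        amps = ElectronicAmplitudes(c, 1)
        out = propagate_amplitudes(amps, _snap(E0, s0), _snap(E1, s1), 0.1)
        assert abs(out.norm - 1.0) <= 1e-8


def test_propagation_matches_matrix_exponential():
    """Constant 2x2 Hamiltonian + coupling over one step vs expm, < 1e-6."""
    E = np.array([0.0, 1.2])
    snap = _snap(E, {(0, 1): 0.05})
    c0 = np.array([0.8, 0.6j])
    amps = ElectronicAmplitudes(c0, 0)
    out = propagate_amplitudes(amps, snap, snap, 0.1)
    A = -1j / HBAR_EV_FS * np.diag(E) - snap.tdc
    ref = expm(A * 0.1) @ c0
    assert np.max(np.abs(out.c - ref)) < 1e-6


def test_norm_blowup_aborts():
    snap_bad = CouplingSnapshot(
        energies=np.array([0.0, 1.0]), tdc=np.array([[0.0, 1e4], [-1e4, 0.0]])
    )
    amps = ElectronicAmplitudes(np.array([1.0, 0.0], dtype=complex), 0)
    with pytest.raises(AmplitudeNormError):
        propagate_amplitudes(amps, snap_bad, snap_bad, 1.0, n_substeps=1, adaptive=False)


def test_hop_probabilities_zero_for_uncoupled_states():
    amps = ElectronicAmplitudes(np.array([0.7, 0.5, math.sqrt(1 - 0.74)], dtype=complex), 2)
    g = hop_probabilities(amps, _snap([0, 1, 2], {}), 0.1)
    assert np.array_equal(g, np.zeros(3))


def test_hop_probability_hand_value_and_rectification():
    c = np.array([0.8, 0.6 * np.exp(-1j * 0.2)])
    amps = ElectronicAmplitudes(c, 0)
    snap = _snap([0.0, 1.0], {(0, 1): 0.01})
    dt = 0.1
    g = hop_probabilities(amps, snap, dt)
    manual = 2 * dt * float(np.real(c[1] * np.conj(c[0]) * 0.01)) / abs(c[0]) ** 2
    assert manual > 0
    assert g[1] == pytest.approx(manual, abs=1e-15)
    assert g[0] == 0.0
    # flipping the coupling sign makes the raw expression negative -> clamped to 0
    g_neg = hop_probabilities(amps, _snap([0.0, 1.0], {(0, 1): -0.01}), dt)
    assert g_neg[1] == 0.0


def test_hop_probabilities_warn_on_collapsed_amplitude():
    amps = ElectronicAmplitudes(np.array([1e-9, 1.0], dtype=complex), 0)
    with pytest.warns(RuntimeWarning, match="collapsed"):
        g = hop_probabilities(amps, _snap([0, 1], {(0, 1): 0.1}), 0.1)
    assert np.array_equal(g, np.zeros(2))


def _hop_state(v):
    part = partition_system(1, [0])
    return PhaseSpaceState(
        positions=np.zeros(1), velocities=np.array([v]), masses=np.array([10.0]),
        time=3.0, partition=part,
    )


def _hop_snap(gap):
    nac = np.zeros((2, 2, 1))
    nac[0, 1, 0] = 1.0
    nac[1, 0, 0] = -1.0
    return CouplingSnapshot(energies=np.array([0.0, gap]), tdc=np.zeros((2, 2)), nac_vectors=nac)


def test_zero_probability_never_hops():
    rng = np.random.default_rng(0)
    for _ in range(100):
        out = attempt_hop(np.zeros(2), rng, _hop_state(0.01), _hop_snap(1.0), 1)
        assert out.new_surface == 1 and out.event is None


def test_downhill_hop_conserves_total_energy():
    state = _hop_state(0.005)
    snap = _hop_snap(0.8)
    rng = np.random.default_rng(2)
    out = attempt_hop(np.array([1.0, 0.0]), rng, state, snap, 1)
    assert out.event is not None and out.event.accepted
    e_before = 0.5 * EV_PER_AMU_ANG2_FS2 * 10.0 * state.velocities[0] ** 2 + snap.energies[1]
    e_after = 0.5 * EV_PER_AMU_ANG2_FS2 * 10.0 * out.velocities[0] ** 2 + snap.energies[0]
    assert e_after == pytest.approx(e_before, abs=1e-8)


def test_uphill_hop_without_kinetic_energy_is_frustrated():
    state = _hop_state(0.002)  # KE ~ 0.002 eV << 0.8 eV gap
    snap = _hop_snap(0.8)
    out = attempt_hop(np.array([0.0, 1.0]), np.random.default_rng(0), state, snap, 0)
    assert out.event is not None and out.event.frustrated and not out.event.accepted
    assert out.new_surface == 0
    assert np.array_equal(out.velocities, state.velocities)


def test_frustrated_reverse_policy_reflects_velocity():
    state = _hop_state(0.002)
    out = attempt_hop(
        np.array([0.0, 1.0]), np.random.default_rng(0), state, _hop_snap(0.8), 0,
        frustrated_policy="reverse",
    )
    assert out.velocities[0] == pytest.approx(-state.velocities[0])


# ---------------------------------------------------------------------------
# full trajectories
# ---------------------------------------------------------------------------


def _decoupled_model():
    # coupling parked far outside the visited region: no decay channel in practice
    m = make_avoided_crossing_model(2)
    far = (GaussianCoupling(0, 1, 0.05, np.array([500.0]), 1.0),)
    return ModelSurface(
        n_states=2, n_dof=1, masses=m.masses, diabats=m.diabats,
        couplings=far, transition_dipoles=m.transition_dipoles,
    )


def test_trajectory_without_coupling_stays_on_start_surface():
    model = _decoupled_model()
    engines = gas_phase_engines(model)
    traj = run_hopping_trajectory(
        excited_init(model), engines, HoppingConfig(t_max_fs=50.0, seed=3)
    )
    assert np.all(traj.surface_history == 1)
    assert traj.hop_events == []
    assert traj.termination == "t_max"


def test_trajectory_deterministic_under_fixed_seed():
    model = make_avoided_crossing_model(2, {"coupling_amplitude": 0.02})
    engines = gas_phase_engines(model)
    cfg = HoppingConfig(t_max_fs=120.0, seed=11)
    a = run_hopping_trajectory(excited_init(model), engines, cfg)
    b = run_hopping_trajectory(excited_init(model), engines, cfg)
    assert np.array_equal(a.surface_history, b.surface_history)
    assert np.array_equal(a.total_energy, b.total_energy)


def test_trajectory_conserves_energy_including_hops():
    """NVE total energy stays O(dt^2)-flat across the run, hops included."""
    model = make_avoided_crossing_model(2, {"coupling_amplitude": 0.02})
    engines = gas_phase_engines(model)
    hops = 0
    for seed in range(6):
        traj = run_hopping_trajectory(
            excited_init(model), engines, HoppingConfig(t_max_fs=150.0, seed=seed)
        )
        hops += sum(ev.accepted for ev in traj.hop_events)
        drift = np.max(np.abs(traj.total_energy - traj.total_energy[0]))
        assert drift < 5e-6
    assert hops > 0  # the check above covered trajectories with real hops


def test_times_increase_by_dt_and_surface_changes_only_at_hops():
    model = make_avoided_crossing_model(2, {"coupling_amplitude": 0.02})
    engines = gas_phase_engines(model)
    traj = run_hopping_trajectory(
        excited_init(model), engines, HoppingConfig(t_max_fs=100.0, seed=2)
    )
    assert np.allclose(np.diff(traj.times), 0.1, atol=1e-9)
    changes = np.nonzero(np.diff(traj.surface_history))[0]
    accepted_times = sorted(ev.time for ev in traj.hop_events if ev.accepted)
    assert len(changes) == len(accepted_times)
    for idx, t_ev in zip(changes, accepted_times):
        assert traj.times[idx + 1] == pytest.approx(t_ev, abs=1e-9)


def test_quiescence_termination_after_reaching_ground_state():
    model = make_avoided_crossing_model(2, {"coupling_amplitude": 0.02})
    engines = gas_phase_engines(model)
    for seed in range(8):
        traj = run_hopping_trajectory(
            excited_init(model), engines,
            HoppingConfig(t_max_fs=300.0, seed=seed, quiescence_fs=20.0),
        )
        if traj.termination == "quiescent_s0":
            assert traj.surface_history[-1] == 0
            return
    pytest.fail("no trajectory reached the ground state in 300 fs across 8 seeds")


def _landau_zener_model(v12, width=20.0):
    slope = 0.1
    diabats = (
        DiabaticState(0.0, np.zeros(1), np.array([slope]), np.zeros(1)),
        DiabaticState(0.0, np.zeros(1), np.array([-slope]), np.zeros(1)),
    )
    return ModelSurface(
        n_states=2, n_dof=1, masses=np.array([6.0]), diabats=diabats,
        couplings=(GaussianCoupling(0, 1, v12, np.zeros(1), width),),
        transition_dipoles=np.array([[0.0, 1.0], [1.0, 0.0]]),
    )


def test_single_passage_statistics_near_landau_zener():
    """One fast passage through an avoided crossing: hop fraction within a wide
    band of the Landau-Zener transition probability."""
    v12, v0, dF = 0.0383, 0.1, 0.2
    p_lz = math.exp(-2 * math.pi * v12**2 / (HBAR_EV_FS * v0 * dF))
    model = _landau_zener_model(v12)
    engines = gas_phase_engines(model)
    n, hopped = 120, 0
    for seed in range(n):
        traj = run_hopping_trajectory(
            excited_init(model, x=-3.0, v=v0), engines,
            HoppingConfig(t_max_fs=60.0, dt=0.1, seed=seed),
        )
        hopped += int(traj.surface_history[-1] == 0)
    assert hopped / n == pytest.approx(p_lz, abs=0.15)
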