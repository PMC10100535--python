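"""Fewest-switches surface hopping: coupled electron-nuclear propagation.

Nuclei move classically on one adiabatic surface while the electronic
amplitudes ``c_alpha(t)`` are integrated along the trajectory from

    i hbar dc_alpha/dt = E_alpha c_alpha - i hbar sum_beta sigma_alpha_beta c_beta,

where ``sigma_alpha_beta = R' . d_alpha_beta`` is the time-derivative coupling
(nuclear velocity dotted into the nonadiabatic coupling vector).  At every
nuclear step Tully's fewest-switches probability of leaving the occupied
surface ``alpha`` for ``beta`` is

    g_{alpha->beta} = max(0, 2 dt Re(c_beta c_alpha^* sigma_alpha_beta) / |c_alpha|^2),

the prescription that makes ensemble surface populations track the amplitude
populations with the minimal number of switches.  An accepted hop rescales the
velocity component along the coupling vector so total energy is conserved
exactly; an attempted upward hop without enough kinetic energy along that
direction is *frustrated* — recorded, surface unchanged.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .md import EngineSet, InitialCondition, PhaseSpaceState, andersen_thermostat, velocity_verlet_step
from .qmmm import subtractive_energy_and_gradient
from .surfaces import HopTimeRecord
from .units import EV_PER_AMU_ANG2_FS2, HBAR_EV_FS

__all__ = [
    "ElectronicAmplitudes",
    "CouplingSnapshot",
    "HopEvent",
    "HopResult",
    "HoppingConfig",
    "HoppingTrajectory",
    "AmplitudeNormError",
    "propagate_amplitudes",
    "hop_probabilities",
    "attempt_hop",
    "run_hopping_trajectory",
]


class AmplitudeNormError(RuntimeError):
    """Raised when the electronic norm drifts beyond the soundness bound in one step."""


@dataclass(frozen=True)
class ElectronicAmplitudes:
    """Complex coefficients on the adiabatic basis plus the occupied surface index."""

    c: np.ndarray
    current_surface: int

    @property
    def populations(self) -> np.ndarray:
        return np.abs(self.c) ** 2

    @property
    def norm(self) -> float:
        return float(np.sum(np.abs(self.c) ** 2))

    @classmethod
    def pure(cls, n_states: int, surface: int) -> "ElectronicAmplitudes":
        c = np.zeros(n_states, dtype=complex)
        c[surface] = 1.0
        return cls(c=c, current_surface=surface)


@dataclass(frozen=True)
class CouplingSnapshot:
    """Electronic data at one trajectory time: adiabatic energies, scalar
    time-derivative couplings (antisymmetric, zero diagonal) and coupling vectors."""

    energies: np.ndarray  # (n_states,), eV
    tdc: np.ndarray  # (n_states, n_states), 1/fs, sigma[b, a] = R' . d_ba
    nac_vectors: np.ndarray | None = None  # (n_states, n_states, n_qm_dof), 1/A


@dataclass(frozen=True)
class HopEvent:
    time: float
    source: int
    target: int
    accepted: bool
    frustrated: bool


@dataclass(frozen=True)
class HopResult:
    new_surface: int
    velocities: np.ndarray
    event: HopEvent | None


def propagate_amplitudes(
    amps: ElectronicAmplitudes,
    snapshot_t: CouplingSnapshot,
    snapshot_t_plus_dt: CouplingSnapshot,
    dt: float,
    n_substeps: int = 20,
    norm_tol: float = 1e-8,
    abort_tol: float = 1e-4,
    adaptive: bool = True,
) -> ElectronicAmplitudes:
    """Integrate the amplitude equations across one nuclear step.

    Energies and time-derivative couplings are interpolated linearly between the
    step endpoints and the linear ODE ``dc/dt = A(t) c`` with
    ``A = -i/hbar diag(E) - sigma`` is integrated by classical RK4 over
    ``n_substeps`` substeps (doubled adaptively, up to 16x, while the norm drift
    of the step exceeds 1e-10).  The norm is renormalized only when its drift
    exceeds ``norm_tol`` (warned), and a drift beyond ``abort_tol`` raises
    :class:`AmplitudeNormError` — such a trajectory is numerically unsound.
    """
    if n_substeps < 1:
        raise ValueError("n_substeps must be >= 1")
    n = amps.c.size
    A0 = -1j / HBAR_EV_FS * np.diag(snapshot_t.energies) - snapshot_t.tdc
    A1 = -1j / HBAR_EV_FS * np.diag(snapshot_t_plus_dt.energies) - snapshot_t_plus_dt.tdc
    dA = A1 - A0

    nsub = n_substeps
    max_sub = n_substeps * 16
    eye = np.eye(n, dtype=complex)
    while True:
        # A at the half-substep grid f = 0, 1/(2 nsub), ..., 1, built in one shot;
        # the ODE is linear, so each RK4 substep is a matrix map assembled batched.
        fracs = np.linspace(0.0, 1.0, 2 * nsub + 1)
        A = A0[None, :, :] + fracs[:, None, None] * dA[None, :, :]
        Aa, Am, Ab = A[0:-1:2], A[1::2], A[2::2]
        h = dt / nsub
        K1 = Aa
        K2 = Am @ (eye + 0.5 * h * K1)
        K3 = Am @ (eye + 0.5 * h * K2)
        K4 = Ab @ (eye + h * K3)
        M = eye + (h / 6.0) * (K1 + 2.0 * K2 + 2.0 * K3 + K4)
        c = amps.c.astype(complex)
        for k in range(nsub):
            c = M[k] @ c
        drift = abs(float(np.sum(np.abs(c) ** 2)) - 1.0)
        if adaptive and drift > 1e-10 and nsub < max_sub:
            nsub *= 2
            continue
        break

    if drift > abort_tol:
        raise AmplitudeNormError(
            f"electronic norm drifted by {drift:.3e} in one nuclear step "
            f"(limit {abort_tol:.0e}); trajectory numerically unsound"
        )
    if drift > norm_tol:
        warnings.warn(
            f"renormalizing electronic amplitudes (norm drift {drift:.3e})",
            RuntimeWarning,
            stacklevel=2,
        )
        c = c / math.sqrt(float(np.sum(np.abs(c) ** 2)))
    return replace(amps, c=c)


def hop_probabilities(
    amps: ElectronicAmplitudes, snapshot: CouplingSnapshot, dt: float
) -> np.ndarray:
    """Tully fewest-switches probabilities of leaving the occupied surface this step.

    Negative raw values are rectified to zero (that is the fewest-switches
    choice); if the probabilities sum above 1 the vector is scaled back onto the
    simplex.  A collapsed occupied amplitude (|c_alpha|^2 < 1e-12) yields zeros
    with a warning rather than a division blow-up.
    """
    a = amps.current_surface
    pop_a = float(np.abs(amps.c[a]) ** 2)
    n = amps.c.size
    if pop_a < 1e-12:
        warnings.warn(
            "occupied-state amplitude collapsed; hop probabilities set to zero",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros(n)
    # g_b = 2 dt Re(c_b c_a^* sigma_ab) / |c_a|^2
    raw = 2.0 * dt * np.real(amps.c * np.conj(amps.c[a]) * snapshot.tdc[a, :]) / pop_a
    g = np.maximum(raw, 0.0)
    g[a] = 0.0
    total = float(g.sum())
    if total > 1.0:
        g /= total
    return g


def attempt_hop(
    g: np.ndarray,
    rng: np.random.Generator,
    state: PhaseSpaceState,
    snapshot: CouplingSnapshot,
    current_surface: int,
    frustrated_policy: str = "keep",
) -> HopResult:
    """Draw the stochastic hop and, if one fires, rescale velocities along the coupling.

    A single uniform draw is compared against the cumulative probability bins.
    On a hop from ``alpha`` to ``beta`` the velocity component along the
    nonadiabatic coupling vector ``d_beta_alpha`` (zero-padded onto the full
    system: the environment carries no electronic coupling) is adjusted so that
    kinetic plus potential energy is exactly conserved.  If the quadratic for
    the scaling has no real root the hop is frustrated: surface and velocities
    unchanged (``frustrated_policy="keep"``), or the velocity component along
    the coupling reversed (``"reverse"``).
    """
    u = float(rng.random())
    cum = np.cumsum(g)
    targets = np.nonzero(u < cum)[0]
    if targets.size == 0:
        return HopResult(current_surface, state.velocities, None)
    beta = int(targets[0])

    dE = float(snapshot.energies[beta] - snapshot.energies[current_surface])
    d_full = np.zeros(state.positions.size)
    if snapshot.nac_vectors is not None:
        d_full[state.partition.qm_indices] = snapshot.nac_vectors[beta, current_surface]
    v = state.velocities
    m = state.masses
    a_coef = float(np.sum(d_full * d_full / m))
    b_coef = float(np.sum(v * d_full))

    if a_coef < 1e-16:
        # no usable coupling direction: isotropic rescale as fallback
        kin = 0.5 * EV_PER_AMU_ANG2_FS2 * float(np.sum(m * v * v))
        if kin <= dE:
            return HopResult(
                current_surface, v, HopEvent(state.time, current_surface, beta, False, True)
            )
        v_new = v * math.sqrt(1.0 - dE / kin)
        return HopResult(beta, v_new, HopEvent(state.time, current_surface, beta, True, False))

    disc = b_coef * b_coef - 2.0 * a_coef * dE / EV_PER_AMU_ANG2_FS2
    if disc < 0.0:
        v_out = v
        if frustrated_policy == "reverse":
            # reflect the velocity component along the coupling direction
            v_out = v - 2.0 * (b_coef / a_coef) * (d_full / m)
        return HopResult(
            current_surface, v_out, HopEvent(state.time, current_surface, beta, False, True)
        )
    root = math.sqrt(disc)
    gamma = (b_coef - root) / a_coef if b_coef >= 0 else (b_coef + root) / a_coef
    v_new = v - gamma * d_full / m
    return HopResult(beta, v_new, HopEvent(state.time, current_surface, beta, True, False))


@dataclass(frozen=True)
class HoppingConfig:
    """Parameters of one surface-hopping trajectory.

    ``t_max_fs`` is mandatory (the horizon); ``dt`` defaults to the fine 0.1 fs
    hopping step.  ``collision_frequency`` > 0 switches the solvent-only
    Andersen thermostat on during the hopping run (off by default so the
    between-hop dynamics is NVE).  ``decoherence_constant_ev`` enables the
    optional energy-based decoherence damping (off by default — none is applied
    in the reference protocol).  ``quiescence_fs`` stops the trajectory that
    long after it reaches the ground state.
    """

    t_max_fs: float
    dt: float = 0.1
    n_substeps: int = 20
    frustrated_policy: str = "keep"
    collision_frequency: float = 0.0
    temperature: float = 298.0
    decoherence_constant_ev: float | None = None
    quiescence_fs: float | None = None
    amplitude_stride: int = 0  # 0: do not store amplitude history
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_max_fs <= 0 or self.dt <= 0:
            raise ValueError("t_max and dt must be positive")
        if self.frustrated_policy not in ("keep", "reverse"):
            raise ValueError("frustrated_policy must be 'keep' or 'reverse'")


@dataclass
class HoppingTrajectory:
    """Full record of one surface-hopping trajectory."""

    times: np.ndarray
    surface_history: np.ndarray
    total_energy: np.ndarray
    hop_events: list[HopEvent]
    termination: str
    amplitude_times: np.ndarray | None = None
    amplitude_history: np.ndarray | None = None  # (n_rec, n_states), complex
    geometry_history: np.ndarray | None = None  # (n_rec, n_dof), same stride
    start_surface: int = 2

    def hop_time_record(self, trajectory_id: int = 0) -> HopTimeRecord:
        """First-passage times out of the initial surface and into the ground state."""
        surf = self.surface_history
        t = self.times
        below = np.nonzero(surf < self.start_surface)[0]
        t21 = float(t[below[0]]) if below.size else None
        ground = np.nonzero(surf == 0)[0]
        t10 = float(t[ground[0]]) if ground.size else None
        if t21 is None:
            t10 = None
        elif t10 is not None and t10 <= t21:
            t21 = t10  # direct hop to the ground state
        return HopTimeRecord(
            trajectory_id=trajectory_id, t_hop_21=t21, t_hop_10=t10, t_max=float(t[-1])
        )


def _apply_decoherence(
    amps: ElectronicAmplitudes, snapshot: CouplingSnapshot, kinetic: float, dt: float, c_param: float
) -> ElectronicAmplitudes:
    """Energy-based exponential damping of unoccupied amplitudes (optional)."""
    a = amps.current_surface
    c = amps.c.copy()
    for b in range(c.size):
        if b == a:
            continue
        gap = abs(float(snapshot.energies[b] - snapshot.energies[a]))
        if gap <= 0:
            continue
        tau = HBAR_EV_FS / gap * (1.0 + c_param / max(kinetic, 1e-12))
        c[b] *= math.exp(-dt / tau)
    pop_other = float(np.sum(np.abs(np.delete(c, a)) ** 2))
    pop_a = max(1.0 - pop_other, 0.0)
    if abs(c[a]) > 0:
        c[a] *= math.sqrt(pop_a) / abs(c[a])
    return replace(amps, c=c)


def run_hopping_trajectory(
    init: InitialCondition,
    engines: EngineSet,
    config: HoppingConfig,
    rng: np.random.Generator | None = None,
) -> HoppingTrajectory:
    """Propagate one FSSH trajectory from its initial condition.

    Each step: velocity-Verlet nuclear step on the occupied surface (forces from
    the subtractive QM/MM combination), electronic amplitude propagation across
    the step with endpoint-interpolated couplings, then a fewest-switches hop
    attempt.  Nonadiabatic coupling vectors have their sign tracked for
    continuity (flipped when the overlap with the previous step is negative),
    and when the electronic-structure evaluation flags a near-degeneracy the
    previous step's couplings are reused for the flagged pairs — hopping is
    never forbidden by a gap threshold.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    part = init.state.partition
    qm = part.qm_indices
    model = engines.surface
    n_states = model.n_states
    if init.start_surface >= n_states:
        raise ValueError("start surface index exceeds the model's state count")

    surface = init.start_surface
    amps = ElectronicAmplitudes.pure(n_states, surface)
    state = replace(init.state, time=0.0)
    mask = part.solvent_mask()

    def electronic(x_full: np.ndarray):
        if hasattr(engines.high, "evaluate"):
            return engines.high.evaluate(x_full[qm])  # shared cache with force calls
        from .surfaces import evaluate_surface

        return evaluate_surface(model, x_full[qm])

    def combined(x_full: np.ndarray, surf: int):
        return subtractive_energy_and_gradient(part, engines.high, engines.low, x_full, surf)

    res = electronic(state.positions)
    nac_prev = res.nac.copy()
    comb = combined(state.positions, surface)
    force = comb.forces
    e_pot = comb.e_total

    n_steps = int(round(config.t_max_fs / config.dt))
    times = [0.0]
    surfaces = [surface]
    energies_tot = [state.kinetic_energy() + comb.e_total]
    amp_times: list[float] = []
    amp_hist: list[np.ndarray] = []
    geom_hist: list[np.ndarray] = []
    hop_events: list[HopEvent] = []
    if config.amplitude_stride:
        amp_times.append(0.0)
        amp_hist.append(amps.c.copy())
        geom_hist.append(state.positions.copy())

    termination = "t_max"
    t_reached_s0: float | None = 0.0 if surface == 0 else None

    sigma_prev = np.einsum("p,bap->ba", state.velocities[qm], nac_prev)
    snap_prev = CouplingSnapshot(energies=res.energies, tdc=sigma_prev, nac_vectors=nac_prev)

    for step in range(1, n_steps + 1):
        last = {}

        def force_fn(x, _surf=surface):
            comb = combined(x, _surf)
            last["comb"] = comb
            return comb.forces

        state, force = velocity_verlet_step(
            state, force_fn, config.dt, force0=force, return_force=True
        )
        e_pot = last["comb"].e_total
        res = electronic(state.positions)
        nac = res.nac.copy()
        # near-degeneracy: reuse previous couplings for the flagged pairs
        for (b, a) in res.degenerate_pairs:
            nac[b, a] = nac_prev[b, a]
            nac[a, b] = nac_prev[a, b]
        # sign continuity of the coupling vectors
        for b in range(n_states):
            for a in range(b + 1, n_states):
                if float(nac[b, a] @ nac_prev[b, a]) < 0.0:
                    nac[b, a] = -nac[b, a]
                    nac[a, b] = -nac[a, b]
        sigma = np.einsum("p,bap->ba", state.velocities[qm], nac)
        snap = CouplingSnapshot(energies=res.energies, tdc=sigma, nac_vectors=nac)

        try:
            amps = propagate_amplitudes(
                amps, snap_prev, snap, config.dt, n_substeps=config.n_substeps
            )
        except AmplitudeNormError:
            termination = "amplitude_norm_abort"
            times.append(state.time)
            surfaces.append(surface)
            energies_tot.append(state.kinetic_energy() + e_pot)
            break

        if config.decoherence_constant_ev is not None:
            amps = _apply_decoherence(
                amps, snap, state.kinetic_energy(), config.dt, config.decoherence_constant_ev
            )

        g = hop_probabilities(replace(amps, current_surface=surface), snap, config.dt)
        hop = attempt_hop(g, rng, state, snap, surface, config.frustrated_policy)
        if hop.event is not None:
            hop_events.append(hop.event)
        if hop.event is not None and hop.event.accepted:
            surface = hop.new_surface
            state = replace(state, velocities=hop.velocities)
            amps = replace(amps, current_surface=surface)
            comb = combined(state.positions, surface)
            force = comb.forces
            e_pot = comb.e_total
            if surface == 0 and t_reached_s0 is None:
                t_reached_s0 = state.time
        elif hop.event is not None and hop.event.frustrated and config.frustrated_policy == "reverse":
            # geometry unchanged, so the force stays valid
            state = replace(state, velocities=hop.velocities)

        if config.collision_frequency > 0:
            state = andersen_thermostat(
                state, mask, config.temperature, config.collision_frequency, config.dt, rng
            )

        nac_prev = nac
        snap_prev = snap
        times.append(state.time)
        surfaces.append(surface)
        energies_tot.append(state.kinetic_energy() + e_pot)
        if config.amplitude_stride and step % config.amplitude_stride == 0:
            amp_times.append(state.time)
            amp_hist.append(amps.c.copy())
            geom_hist.append(state.positions.copy())

        if (
            config.quiescence_fs is not None
            and t_reached_s0 is not None
            and state.time - t_reached_s0 >= config.quiescence_fs
        ):
            termination = "quiescent_s0"
            break

    return HoppingTrajectory(
        times=np.asarray(times),
        surface_history=np.asarray(surfaces, dtype=int),
        total_energy=np.asarray(energies_tot),
        hop_events=hop_events,
        termination=termination,
        amplitude_times=np.asarray(amp_times) if amp_hist else None,
        amplitude_history=np.asarray(amp_hist) if amp_hist else None,
        geometry_history=np.asarray(geom_hist) if geom_hist else None,
        start_surface=init.start_surface,
    )
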