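"""Analytic multi-state model surfaces, a surrogate solvent bath, and a kinetic hop-time sampler.

This module is the synthetic stand-in for the expensive engines a surface-hopping
study normally sits on: a semi-empirical multi-reference electronic-structure code
for the chromophore and a classical water force field for the environment.  The
chromophore is replaced by a smooth real symmetric *diabatic* matrix ``V(R)`` whose
eigendecomposition yields adiabatic energies, Hellmann-Feynman gradients and exact
nonadiabatic coupling vectors at any geometry; the solvent is replaced by a fully
analytic bath of tethered charged particles.  Because every derivative is analytic,
each downstream stage (QM/MM combination, nuclear propagation, amplitude
propagation, hopping statistics, lifetime fitting) can be checked against exact
oracles.

Units: angstrom, femtosecond, eV, amu throughout (see :mod:`hopdyn.units`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import EV_PER_AMU_ANG2_FS2, KB_EV

__all__ = [
    "DiabaticState",
    "GaussianCoupling",
    "ModelSurface",
    "ElectronicStructureResult",
    "SolventBath",
    "SolventBathEngine",
    "SurfaceEngine",
    "zero_engine",
    "HopTimeRecord",
    "make_avoided_crossing_model",
    "evaluate_surface",
    "make_solvent_bath",
    "sample_hop_times",
    "maxwell_boltzmann_velocities",
]

#: adiabatic gap (eV) below which the coupling is considered numerically undefined
DEGENERACY_GAP_EV = 1e-10


@dataclass(frozen=True)
class DiabaticState:
    """One diagonal element of the diabatic matrix: linear-plus-harmonic in R.

    V_ii(R) = e0 + slope . (R - center) + 0.5 * sum_d curvature_d (R_d - center_d)^2
    """

    e0: float
    center: np.ndarray
    slope: np.ndarray
    curvature: np.ndarray

    def value(self, R: np.ndarray) -> float:
        d = R - self.center
        return self.e0 + float(self.slope @ d) + 0.5 * float(self.curvature @ (d * d))

    def gradient(self, R: np.ndarray) -> np.ndarray:
        return self.slope + self.curvature * (R - self.center)


@dataclass(frozen=True)
class GaussianCoupling:
    """Off-diagonal diabatic element V_ij(R) = amplitude * exp(-|R-center|^2 / 2 width^2)."""

    i: int
    j: int
    amplitude: float
    center: np.ndarray
    width: float

    def value(self, R: np.ndarray) -> float:
        d = R - self.center
        return self.amplitude * math.exp(-float(d @ d) / (2.0 * self.width**2))

    def gradient(self, R: np.ndarray) -> np.ndarray:
        d = R - self.center
        return self.value(R) * (-d / self.width**2)


@dataclass(frozen=True)
class ModelSurface:
    """Analytic multi-state model Hamiltonian over ``n_dof`` nuclear coordinates.

    ``transition_dipoles`` is a symmetric zero-diagonal matrix of surrogate diabatic
    transition moments used only to manufacture smooth oscillator strengths; its
    magnitudes are arbitrary by construction.
    """

    n_states: int
    n_dof: int
    masses: np.ndarray
    diabats: tuple[DiabaticState, ...]
    couplings: tuple[GaussianCoupling, ...]
    transition_dipoles: np.ndarray
    f_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("a model surface needs at least two states")
        if len(self.diabats) != self.n_states:
            raise ValueError("one diabatic state per electronic state required")
        if np.any(self.masses <= 0):
            raise ValueError("all masses must be positive")
        if not any(abs(c.amplitude) > 0 for c in self.couplings):
            raise ValueError(
                "all diabatic couplings are identically zero: the model has no "
                "nonadiabatic channel and cannot serve as a hopping surface"
            )

    def diabatic_matrix(self, R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return V(R) (n_states, n_states) and its gradient dV (n_dof, n_states, n_states)."""
        n = self.n_states
        V = np.zeros((n, n))
        dV = np.zeros((self.n_dof, n, n))
        for i, dia in enumerate(self.diabats):
            V[i, i] = dia.value(R)
            dV[:, i, i] = dia.gradient(R)
        for c in self.couplings:
            v = c.value(R)
            g = c.gradient(R)
            V[c.i, c.j] += v
            V[c.j, c.i] += v
            dV[:, c.i, c.j] += g
            dV[:, c.j, c.i] += g
        return V, dV


@dataclass(frozen=True)
class ElectronicStructureResult:
    """Adiabatic electronic structure at one geometry.

    Attributes
    ----------
    energies : (n_states,) adiabatic energies, ascending (eV).
    gradients : (n_states, n_dof) gradient of each adiabatic energy (eV/A).
    nac : (n_states, n_states, n_dof) coupling vectors d_ba = <psi_b|grad psi_a>,
        antisymmetric in (b, a) (1/A).  Entries for degenerate pairs are zeroed
        and the pair is listed in ``degenerate_pairs``.
    oscillator_strengths : (n_states,) surrogate strengths of the 0 -> alpha
        transitions (dimensionless; f_0 = 0).
    degenerate : True when any adiabatic gap fell below the degeneracy threshold;
        the caller must not trust the zeroed couplings for those pairs.
    """

    energies: np.ndarray
    gradients: np.ndarray
    nac: np.ndarray
    oscillator_strengths: np.ndarray
    degenerate: bool = False
    degenerate_pairs: tuple[tuple[int, int], ...] = ()


def _fix_gauge(U: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign convention: largest-|.| component positive."""
    for k in range(U.shape[1]):
        idx = int(np.argmax(np.abs(U[:, k])))
        if U[idx, k] < 0:
            U[:, k] = -U[:, k]
    return U


def evaluate_surface(model: ModelSurface, R: np.ndarray) -> ElectronicStructureResult:
    """Diagonalize V(R) and return energies, gradients, coupling vectors and strengths.

    Gradients and couplings come from the Hellmann-Feynman expressions

        grad E_a = <a| dV |a>,      d_ba = <b| dV |a> / (E_a - E_b)   (b != a),

    which are exact for this model because V and dV are analytic.  Pairs closer
    than ``DEGENERACY_GAP_EV`` get their coupling zeroed and the result flagged;
    a spuriously divergent coupling is never returned.
    """
    R = np.asarray(R, dtype=float)
    if R.shape != (model.n_dof,):
        raise ValueError(f"geometry must have {model.n_dof} components, got shape {R.shape}")
    V, dV = model.diabatic_matrix(R)
    E, U = np.linalg.eigh(V)  # ascending by construction
    U = _fix_gauge(U)

    # <b| dV_p |a> for every DOF p at once
    W = np.einsum("ib,pij,ja->pba", U, dV, U)  # (n_dof, n_states, n_states)
    grads = np.transpose(np.einsum("paa->pa", W))  # (n_states, n_dof)

    n = model.n_states
    nac = np.zeros((n, n, model.n_dof))
    degenerate_pairs: list[tuple[int, int]] = []
    for b in range(n):
        for a in range(b + 1, n):
            gap = E[a] - E[b]
            if gap < DEGENERACY_GAP_EV:
                degenerate_pairs.append((b, a))
                continue
            d_ba = W[:, b, a] / gap
            nac[b, a] = d_ba
            nac[a, b] = -d_ba

    # surrogate oscillator strengths: smooth in the adiabatic mixing through U
    mu_ad = U.T @ model.transition_dipoles @ U
    f = np.zeros(n)
    f[1:] = model.f_scale * np.maximum(E[1:] - E[0], 0.0) * mu_ad[0, 1:] ** 2
    return ElectronicStructureResult(
        energies=E,
        gradients=grads,
        nac=nac,
        oscillator_strengths=f,
        degenerate=bool(degenerate_pairs),
        degenerate_pairs=tuple(degenerate_pairs),
    )


def _crossing_point(d0: DiabaticState, d1: DiabaticState, axis: int, n_dof: int) -> np.ndarray:
    """Geometry (on the given axis, other DOFs zero) where two diabats cross."""
    x = np.linspace(-12.0, 12.0, 4801)
    R = np.zeros((x.size, n_dof))
    R[:, axis] = x
    diff = np.array([d0.value(r) - d1.value(r) for r in R])
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if sign_change.size == 0:
        raise ValueError("diabats do not cross along the scan axis; adjust well parameters")
    i = int(sign_change[0])
    # linear interpolation of the root
    x0 = x[i] - diff[i] * (x[i + 1] - x[i]) / (diff[i + 1] - diff[i])
    out = np.zeros(n_dof)
    out[axis] = x0
    return out


def make_avoided_crossing_model(
    n_states: int,
    params: dict | None = None,
    seed: int | None = None,
) -> ModelSurface:
    """Build a 2- or 3-state avoided-crossing model with localized Gaussian couplings.

    The diabats are tilted harmonic wells displaced along the first coordinate;
    consecutive pairs cross once, and each crossing carries a Gaussian coupling
    centered on it, so the adiabatic gap closes to twice the coupling amplitude
    exactly at the diabatic crossing point and opens up elsewhere — a model
    conical-intersection seam analog.

    Parameters (all overridable through ``params``):

    ``n_dof`` (1), ``mass`` (12 amu), ``curvature`` (0.08 eV/A^2),
    ``well_separation`` (4.0 A between consecutive well minima),
    ``state_offsets`` (0.5 eV between consecutive diabat minima),
    ``coupling_amplitude`` (0.05 eV), ``coupling_width`` (1.0 A),
    ``f_scale`` (1.0).

    ``seed`` only randomizes the surrogate transition-dipole magnitudes; pass
    None for the fixed defaults.
    """
    if n_states not in (2, 3):
        raise ValueError("n_states must be 2 or 3")
    p = {
        "n_dof": 1,
        "mass": 12.0,
        "curvature": 0.08,
        "well_separation": 4.0,
        "state_offsets": 0.5,
        "coupling_amplitude": 0.05,
        "coupling_width": 1.0,
        "f_scale": 1.0,
    }
    if params:
        unknown = set(params) - set(p)
        if unknown:
            raise ValueError(f"unknown model parameters: {sorted(unknown)}")
        p.update(params)
    if p["coupling_amplitude"] == 0.0:
        raise ValueError(
            "coupling_amplitude = 0 produces identically zero coupling everywhere; "
            "such a surface has no nonadiabatic channel"
        )

    n_dof = int(p["n_dof"])
    masses = np.full(n_dof, float(p["mass"]))
    curv = np.full(n_dof, float(p["curvature"]))
    sep = float(p["well_separation"])
    first_center = -0.5 * sep * (n_states - 1)
    diabats = []
    for s in range(n_states):
        center = np.zeros(n_dof)
        center[0] = first_center + s * sep
        diabats.append(
            DiabaticState(
                e0=s * float(p["state_offsets"]),
                center=center,
                slope=np.zeros(n_dof),
                curvature=curv.copy(),
            )
        )

    # a Gaussian coupling at every pairwise diabatic crossing, so no seam in the
    # visited region is silently uncoupled (non-crossing pairs are skipped)
    couplings = []
    for i in range(n_states):
        for j in range(i + 1, n_states):
            try:
                xc = _crossing_point(diabats[i], diabats[j], axis=0, n_dof=n_dof)
            except ValueError:
                continue
            couplings.append(
                GaussianCoupling(
                    i=i,
                    j=j,
                    amplitude=float(p["coupling_amplitude"]),
                    center=xc,
                    width=float(p["coupling_width"]),
                )
            )

    mu = np.zeros((n_states, n_states))
    if seed is None:
        vals = np.linspace(1.0, 0.6, n_states * (n_states - 1) // 2)
    else:
        vals = np.random.default_rng(seed).uniform(0.5, 1.5, n_states * (n_states - 1) // 2)
    k = 0
    for i in range(n_states):
        for j in range(i + 1, n_states):
            mu[i, j] = mu[j, i] = vals[k]
            k += 1

    return ModelSurface(
        n_states=n_states,
        n_dof=n_dof,
        masses=masses,
        diabats=tuple(diabats),
        couplings=tuple(couplings),
        transition_dipoles=mu,
        f_scale=float(p["f_scale"]),
    )


# ---------------------------------------------------------------------------
# surrogate solvent bath
# ---------------------------------------------------------------------------


def maxwell_boltzmann_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Per-DOF Maxwell-Boltzmann draw (A/fs) for per-DOF masses (amu) at T (K)."""
    sigma = np.sqrt(KB_EV * temperature / (np.asarray(masses, float) * EV_PER_AMU_ANG2_FS2))
    return rng.normal(0.0, sigma)


@dataclass
class SolventBath:
    """A cloud of tethered charged particles standing in for explicit solvent.

    Particles are placed without overlap in a shell around the solute region and
    carry alternating partial charges.  ``coupling_strength`` scales the
    solute-bath interaction in :class:`SolventBathEngine`.
    """

    n_particles: int
    positions: np.ndarray  # (n_particles, 3), A
    velocities: np.ndarray  # (n_particles, 3), A/fs
    charges: np.ndarray  # (n_particles,), e
    masses: np.ndarray  # (n_particles,), amu
    coupling_strength: float
    temperature_target: float

    @property
    def n_dof(self) -> int:
        return 3 * self.n_particles

    def dof_masses(self) -> np.ndarray:
        return np.repeat(self.masses, 3)


def make_solvent_bath(
    n_particles: int,
    temperature: float,
    seed: int | np.random.Generator,
    coupling_strength: float = 0.01,
    particle_mass: float = 18.015,
    min_distance: float = 2.6,
    inner_radius: float = 3.0,
    outer_radius: float | None = None,
) -> SolventBath:
    """Place ``n_particles`` water-like particles around the origin, MB velocities at T.

    Placement is rejection sampling in a sphere sized for roughly liquid-like
    spacing; a particle that cannot be placed at least ``min_distance`` from all
    others within a bounded number of attempts raises (packing failure).
    """
    if n_particles < 0:
        raise ValueError("n_particles must be >= 0")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if outer_radius is None:
        outer = inner_radius + 1.3 * min_distance * max(n_particles, 1) ** (1.0 / 3.0)
    else:
        outer = outer_radius
    positions = np.zeros((n_particles, 3))
    for i in range(n_particles):
        for _attempt in range(2000):
            u = rng.uniform(-outer, outer, 3)
            r = float(np.linalg.norm(u))
            if not (inner_radius <= r <= outer):
                continue
            if i == 0 or np.min(np.linalg.norm(positions[:i] - u, axis=1)) >= min_distance:
                positions[i] = u
                break
        else:
            raise RuntimeError(
                f"packing failure: could not place particle {i} of {n_particles} "
                f"with min distance {min_distance} A in radius {outer:.1f} A"
            )

    masses = np.full(n_particles, particle_mass)
    charges = np.where(np.arange(n_particles) % 2 == 0, 0.4, -0.4)
    velocities = maxwell_boltzmann_velocities(
        np.repeat(masses, 3), temperature, rng
    ).reshape(n_particles, 3)
    return SolventBath(
        n_particles=n_particles,
        positions=positions,
        velocities=velocities,
        charges=charges,
        masses=masses,
        coupling_strength=coupling_strength,
        temperature_target=temperature,
    )


class SolventBathEngine:
    """Analytic low-level engine over the full solute+bath system.

    The potential has three terms, all with closed-form gradients:

    * harmonic tethers holding each bath particle near its initial site
      (``k_tether``, eV/A^2) — the surrogate for solvent structure;
    * a soft exponential pair repulsion between bath particles
      (``eps_rep * exp(-r / lambda_rep)``) preventing overlap;
    * a solute-bath coupling ``g * s(R) * sum_j q_j / sqrt(1 + r_j^2)`` where
      ``s(R)`` is the sum of the solute coordinates, ``q_j`` the particle
      charges and ``r_j`` the distance from the solute site at the origin —
      a screened-electrostatic surrogate whose strength ``g`` is the bath's
      ``coupling_strength``.

    Called with a geometry of the *QM-region* length it instead returns a cheap
    harmonic solute term ``0.5 * k_solute_low * |R|^2`` — the low-level view of
    the chromophore used by the subtractive combiner.  Dispatch is on geometry
    length; any other length is an error.
    """

    def __init__(
        self,
        bath: SolventBath,
        n_qm_dof: int,
        k_tether: float = 0.08,
        eps_rep: float = 2.0,
        lambda_rep: float = 0.4,
        k_solute_low: float = 0.05,
    ) -> None:
        self.bath = bath
        self.n_qm_dof = int(n_qm_dof)
        self.n_total_dof = self.n_qm_dof + bath.n_dof
        self.sites = bath.positions.copy()
        self.k_tether = k_tether
        self.eps_rep = eps_rep
        self.lambda_rep = lambda_rep
        self.k_solute_low = k_solute_low

    def __call__(self, x: np.ndarray, state: int = 0) -> tuple[float, np.ndarray]:
        x = np.asarray(x, dtype=float)
        if x.size == self.n_qm_dof:
            return self._qm_region(x)
        if x.size == self.n_total_dof:
            return self._full(x)
        raise ValueError(
            f"geometry length {x.size} matches neither the QM region "
            f"({self.n_qm_dof}) nor the full system ({self.n_total_dof})"
        )

    def _qm_region(self, R: np.ndarray) -> tuple[float, np.ndarray]:
        return 0.5 * self.k_solute_low * float(R @ R), self.k_solute_low * R

    def _full(self, x: np.ndarray) -> tuple[float, np.ndarray]:
        nq = self.n_qm_dof
        R = x[:nq]
        q = x[nq:].reshape(-1, 3)
        grad = np.zeros_like(x)
        gq = np.zeros_like(q)

        e_solute, g_solute = self._qm_region(R)
        grad[:nq] += g_solute

        d = q - self.sites
        e_tether = 0.5 * self.k_tether * float(np.sum(d * d))
        gq += self.k_tether * d

        e_rep = 0.0
        n = q.shape[0]
        if n > 1:
            diff = q[:, None, :] - q[None, :, :]
            r = np.linalg.norm(diff, axis=-1)
            iu = np.triu_indices(n, k=1)
            rij = r[iu]
            e_pair = self.eps_rep * np.exp(-rij / self.lambda_rep)
            e_rep = float(np.sum(e_pair))
            with np.errstate(invalid="ignore", divide="ignore"):
                unit = diff / r[..., None]
            coef = np.zeros((n, n))
            coef[iu] = -e_pair / self.lambda_rep
            coef += coef.T
            gq += np.nansum(coef[..., None] * unit, axis=1)

        e_int = 0.0
        if n > 0 and self.bath.coupling_strength != 0.0:
            g = self.bath.coupling_strength
            s = float(np.sum(R))
            rj = np.linalg.norm(q, axis=1)
            phi = 1.0 / np.sqrt(1.0 + rj * rj)
            e_int = g * s * float(self.bath.charges @ phi)
            grad[:nq] += g * float(self.bath.charges @ phi)
            dphi = -rj * phi**3  # d/dr of (1+r^2)^{-1/2}
            with np.errstate(invalid="ignore", divide="ignore"):
                rad = np.where(rj > 0, dphi / rj, 0.0)
            gq += (g * s * self.bath.charges * rad)[:, None] * q

        grad[nq:] = gq.ravel()
        return e_solute + e_tether + e_rep + e_int, grad


class SurfaceEngine:
    """Adapter exposing a :class:`ModelSurface` through the engine contract
    ``engine(x, state) -> (energy, gradient)``, with a tiny cache so the force
    evaluation and the full electronic-structure snapshot of the same geometry
    cost one diagonalization."""

    def __init__(self, model: ModelSurface) -> None:
        self.model = model
        self._cache_key: bytes | None = None
        self._cache_val: ElectronicStructureResult | None = None

    def evaluate(self, x: np.ndarray) -> ElectronicStructureResult:
        x = np.asarray(x, dtype=float)
        key = x.tobytes()
        if key != self._cache_key:
            self._cache_val = evaluate_surface(self.model, x)
            self._cache_key = key
        return self._cache_val  # type: ignore[return-value]

    def __call__(self, x: np.ndarray, state: int = 0) -> tuple[float, np.ndarray]:
        res = self.evaluate(x)
        return float(res.energies[state]), res.gradients[state].copy()


def zero_engine(x: np.ndarray, state: int = 0) -> tuple[float, np.ndarray]:
    """A low-level engine that contributes nothing: the gas-phase limit."""
    return 0.0, np.zeros_like(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# kinetic hop-time sampler
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HopTimeRecord:
    """First-passage times of one trajectory through the sequential S2 -> S1 -> S0 decay.

    ``None`` marks a transition not observed within the horizon ``t_max``.
    """

    trajectory_id: int
    t_hop_21: float | None
    t_hop_10: float | None
    t_max: float

    def __post_init__(self) -> None:
        if self.t_hop_10 is not None and self.t_hop_21 is None:
            raise ValueError("S1->S0 hop cannot precede S2->S1")
        if (
            self.t_hop_21 is not None
            and self.t_hop_10 is not None
            and not (0.0 <= self.t_hop_21 < self.t_hop_10)
        ):
            raise ValueError("hop times must satisfy 0 <= t21 < t10")

    def state_at(self, t: float) -> int:
        if self.t_hop_21 is None or t < self.t_hop_21:
            return 2
        if self.t_hop_10 is None or t < self.t_hop_10:
            return 1
        return 0


def sample_hop_times(
    tau2_fs: float,
    tau1_ps: float,
    n_traj: int,
    t_max_fs: float,
    seed: int | np.random.Generator,
) -> list[HopTimeRecord]:
    """Draw hop times from the sequential two-step first-order process.

    ``t_hop_21 ~ Exp(mean = tau2)`` and ``t_hop_10 = t_hop_21 + Exp(mean = tau1)``;
    times past ``t_max_fs`` are recorded as absent.  The ensemble-average state
    occupancies of this process solve the sequential kinetic ODE system exactly,
    which makes these records the natural fixture for the fitting stage.
    """
    if tau2_fs <= 0 or tau1_ps <= 0 or t_max_fs <= 0:
        raise ValueError("lifetimes and horizon must be positive")
    if n_traj < 1:
        raise ValueError("need at least one trajectory")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tau1_fs = tau1_ps * 1000.0
    t21 = rng.exponential(tau2_fs, n_traj)
    t10 = t21 + rng.exponential(tau1_fs, n_traj)
    records = []
    for i in range(n_traj):
        a = float(t21[i]) if t21[i] <= t_max_fs else None
        b = float(t10[i]) if (a is not None and t10[i] <= t_max_fs) else None
        records.append(HopTimeRecord(trajectory_id=i, t_hop_21=a, t_hop_10=b, t_max=t_max_fs))
    return records
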