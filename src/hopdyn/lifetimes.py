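"""Swarm population statistics, sequential kinetic lifetime fitting and the
reshuffled-subset 1/N error extrapolation.

A swarm of surface-hopping trajectories yields normalized occupancies
``S2(t), S1(t), S0(t)`` (the fraction of trajectories on each surface).  Their
ensemble dynamics is modelled by the sequential two-step first-order decay

    dS2/dt = -S2/tau2,    dS1/dt = S2/tau2 - S1/tau1,    S0 = 1 - S1 - S2,

with initial conditions S2(0) = 1, S1(0) = 0, whose closed form is

    S2(t) = exp(-t/tau2)
    S1(t) = tau1/(tau1 - tau2) * (exp(-t/tau1) - exp(-t/tau2))      (tau1 != tau2)
    S1(t) = (t/tau) * exp(-t/tau)                                   (tau1 = tau2 = tau).

``tau2`` and ``tau1`` are the mean lifetimes of the second and first excited
states.  Because the swarm is finite, the fit's formal standard errors are
misleadingly tiny; the error estimate instead comes from refitting reshuffled
subsets of the swarm (halves, thirds, ... while more than ``min_subset``
trajectories remain), averaging each division level's spread over repeated
reshuffles, and extrapolating the spread against 1/N down to the full swarm
size.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from .fssh import HoppingTrajectory
from .surfaces import HopTimeRecord

__all__ = [
    "SwarmPopulations",
    "LifetimeFit",
    "SubsetErrorResult",
    "normalized_occupancies",
    "kinetic_model_solution",
    "fit_lifetimes",
    "fit_single_exponential",
    "subset_error_extrapolation",
]


@dataclass(frozen=True)
class SwarmPopulations:
    """Normalized state occupancies of a trajectory swarm on a common time grid (fs)."""

    times: np.ndarray
    s2: np.ndarray
    s1: np.ndarray
    s0: np.ndarray
    n_traj: int

    def __post_init__(self) -> None:
        total = self.s2 + self.s1 + self.s0
        if not np.allclose(total, 1.0, atol=1e-12):
            raise ValueError("occupancies must sum to 1 at every grid point")


@dataclass(frozen=True)
class LifetimeFit:
    """Fitted lifetimes: tau2 in fs, tau1 in ps, with extrapolated standard deviations."""

    tau2_fs: float
    tau1_ps: float
    sigma_tau2_fs: float | None
    sigma_tau1_ps: float | None
    fit_residual: float
    n_traj: int


def _surface_of(traj, t: np.ndarray) -> np.ndarray:
    if isinstance(traj, HopTimeRecord):
        return np.array([traj.state_at(float(x)) for x in t], dtype=int)
    if isinstance(traj, HoppingTrajectory):
        idx = np.clip(np.searchsorted(traj.times, t, side="right") - 1, 0, traj.times.size - 1)
        return traj.surface_history[idx]
    raise TypeError(f"unsupported trajectory type {type(traj).__name__}")


def normalized_occupancies(trajectories: Sequence, grid: np.ndarray) -> SwarmPopulations:
    """Fraction of trajectories occupying each state at every grid time.

    Accepts :class:`HoppingTrajectory` records (surface history sampled by
    last-value interpolation) or :class:`HopTimeRecord` first-passage records.
    The three occupancies form a partition of unity by construction.
    """
    if len(trajectories) == 0:
        raise ValueError("need at least one trajectory")
    grid = np.asarray(grid, dtype=float)
    counts = np.zeros((3, grid.size))
    for traj in trajectories:
        surf = _surface_of(traj, grid)
        for s in (0, 1, 2):
            counts[s] += surf == s
    n = len(trajectories)
    return SwarmPopulations(
        times=grid, s2=counts[2] / n, s1=counts[1] / n, s0=counts[0] / n, n_traj=n
    )


def kinetic_model_solution(
    tau2_fs: float, tau1_fs: float, t: np.ndarray | float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form populations of the sequential decay at time(s) ``t`` (all in fs).

    Handles the degenerate ``tau1 == tau2`` case by its analytic limit
    ``S1 = (t/tau) exp(-t/tau)``.
    """
    if tau2_fs <= 0 or tau1_fs <= 0:
        raise ValueError("lifetimes must be positive")
    t = np.asarray(t, dtype=float)
    s2 = np.exp(-t / tau2_fs)
    if math.isclose(tau1_fs, tau2_fs, rel_tol=1e-12):
        s1 = (t / tau1_fs) * np.exp(-t / tau1_fs)
    else:
        s1 = tau1_fs / (tau1_fs - tau2_fs) * (np.exp(-t / tau1_fs) - np.exp(-t / tau2_fs))
    s0 = 1.0 - s1 - s2
    return s2, s1, s0


def _initial_guess(pops: SwarmPopulations) -> tuple[float, float]:
    """Deterministic starting values: 1/e crossing of s2, and of s1's tail."""
    t = pops.times
    inv_e = 1.0 / math.e
    below = np.nonzero(pops.s2 < inv_e)[0]
    tau2 = float(t[below[0]]) if below.size else float(t[-1]) / 3.0
    tau2 = max(tau2, float(t[1] - t[0]) if t.size > 1 else 1.0)
    peak = int(np.argmax(pops.s1))
    tail = pops.s1[peak:]
    s1_max = float(pops.s1[peak])
    if s1_max > 0:
        below1 = np.nonzero(tail < s1_max * inv_e)[0]
        tau1 = float(t[peak + below1[0]] - t[peak]) if below1.size else float(t[-1] - t[peak])
    else:
        tau1 = float(t[-1]) / 3.0
    tau1 = max(tau1, tau2)
    return tau2, tau1


def fit_single_exponential(populations: SwarmPopulations) -> LifetimeFit:
    """Fit ``s1 = exp(-t/tau1)`` for a swarm with a single excited state.

    This is the ``tau2 -> 0`` limit of the sequential model, used when the model
    has only one excited surface (two-state runs): the occupied excited-state
    fraction decays mono-exponentially.  ``tau2_fs`` is reported as NaN.
    """
    t = populations.times
    below = np.nonzero(populations.s1 < 1.0 / math.e)[0]
    guess = float(t[below[0]]) if below.size else float(t[-1]) / 3.0
    guess = max(guess, float(t[1] - t[0]) if t.size > 1 else 1.0)

    def residual(logtau: np.ndarray) -> np.ndarray:
        return np.exp(-t / np.exp(logtau[0])) - populations.s1

    sol = least_squares(residual, [math.log(guess)], method="lm", xtol=1e-14, ftol=1e-14)
    if not sol.success:
        raise RuntimeError(f"single-exponential fit failed (start {guess}): {sol.message}")
    return LifetimeFit(
        tau2_fs=math.nan,
        tau1_ps=float(np.exp(sol.x[0])) / 1000.0,
        sigma_tau2_fs=None,
        sigma_tau1_ps=None,
        fit_residual=float(2.0 * sol.cost),
        n_traj=populations.n_traj,
    )


def fit_lifetimes(
    populations: SwarmPopulations, x0: tuple[float, float] | None = None
) -> LifetimeFit:
    """Joint unweighted least-squares fit of the s2 and s1 curves for (tau2, tau1).

    The fit is over the logarithms of the lifetimes (positivity enforced by the
    parameterization) and is deterministic given the input and starting values;
    s0 carries no information beyond s2 and s1 and is excluded.  Non-convergence
    raises with the starting values and final residual attached.
    """
    t = populations.times
    if float(populations.s2[-1]) > 1.0 / math.e:
        warnings.warn(
            "s2 has not decayed below 1/e within the grid; tau2 is weakly constrained",
            UserWarning,
            stacklevel=2,
        )
    guess = x0 if x0 is not None else _initial_guess(populations)

    def residual(logtau: np.ndarray) -> np.ndarray:
        tau2, tau1 = np.exp(logtau)
        s2, s1, _ = kinetic_model_solution(tau2, tau1, t)
        return np.concatenate([s2 - populations.s2, s1 - populations.s1])

    sol = least_squares(
        residual, np.log(np.asarray(guess, float)), method="lm", xtol=1e-14, ftol=1e-14
    )
    if not sol.success:
        raise RuntimeError(
            f"lifetime fit failed to converge (start {guess}, residual {sol.cost:.3e}): "
            f"{sol.message}"
        )
    tau2, tau1 = np.exp(sol.x)
    return LifetimeFit(
        tau2_fs=float(tau2),
        tau1_ps=float(tau1) / 1000.0,
        sigma_tau2_fs=None,
        sigma_tau1_ps=None,
        fit_residual=float(2.0 * sol.cost),
        n_traj=populations.n_traj,
    )


@dataclass(frozen=True)
class SubsetErrorResult:
    """Extrapolated standard deviations plus the per-level spread table."""

    sigma_tau2_fs: float
    sigma_tau1_ps: float
    subset_sizes: np.ndarray  # mean trajectories per subset at each division level
    spread_tau2_fs: np.ndarray  # reshuffle-averaged spread at each level
    spread_tau1_ps: np.ndarray
    n_full: int

    def __iter__(self):  # allows tuple-unpacking (sigma_tau2, sigma_tau1)
        return iter((self.sigma_tau2_fs, self.sigma_tau1_ps))


def _default_fit_fn(grid: np.ndarray) -> Callable[[Sequence], tuple[float, float]]:
    def fit(subset: Sequence) -> tuple[float, float]:
        f = fit_lifetimes(normalized_occupancies(subset, grid))
        return f.tau2_fs, f.tau1_ps

    return fit


def subset_error_extrapolation(
    trajectories: Sequence,
    fit_fn: Callable[[Sequence], tuple[float, float]] | None = None,
    n_reshuffles: int = 10,
    min_subset: int = 30,
    rng: np.random.Generator | int | None = None,
    grid: np.ndarray | None = None,
    abscissa: str = "inv_n",
) -> SubsetErrorResult:
    """Estimate lifetime standard deviations by reshuffled-subset extrapolation.

    For each division level k = 2, 3, ... (halves, thirds, ...), kept while a
    subset still holds more than ``min_subset`` trajectories: reshuffle the
    swarm order, split it into k parts, fit each part, and record the sample
    standard deviation of the fitted lifetimes across the parts.  Each level's
    spread is averaged over ``n_reshuffles`` reshuffles, then the spreads are
    fitted linearly against 1/N (N = trajectories per subset) and extrapolated
    to the full swarm size to give the reported sigma.  ``abscissa="inv_sqrt_n"``
    switches to the conventional 1/sqrt(N) scaling of a standard error.
    """
    n = len(trajectories)
    if abscissa not in ("inv_n", "inv_sqrt_n"):
        raise ValueError("abscissa must be 'inv_n' or 'inv_sqrt_n'")
    levels = [k for k in range(2, n + 1) if n // k > min_subset]
    if len(levels) < 2:
        raise ValueError(
            f"swarm of {n} trajectories allows {len(levels)} division level(s) with "
            f"subsets above {min_subset}; need at least 2 for an extrapolation"
        )
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if fit_fn is None:
        if grid is None:
            horizon = max(
                (tr.t_max if isinstance(tr, HopTimeRecord) else float(tr.times[-1]))
                for tr in trajectories
            )
            grid = np.linspace(0.0, horizon, 400)
        fit_fn = _default_fit_fn(np.asarray(grid, float))

    sizes, sp2, sp1 = [], [], []
    order = np.arange(n)
    for k in levels:
        spreads2, spreads1 = [], []
        for _ in range(n_reshuffles):
            perm = rng.permutation(order)
            parts = np.array_split(perm, k)
            taus = np.array([fit_fn([trajectories[i] for i in part]) for part in parts])
            spreads2.append(np.std(taus[:, 0], ddof=1))
            spreads1.append(np.std(taus[:, 1], ddof=1))
        sizes.append(n / k)
        sp2.append(float(np.mean(spreads2)))
        sp1.append(float(np.mean(spreads1)))

    sizes_arr = np.asarray(sizes)
    x = 1.0 / sizes_arr if abscissa == "inv_n" else 1.0 / np.sqrt(sizes_arr)
    x_full = 1.0 / n if abscissa == "inv_n" else 1.0 / math.sqrt(n)
    A = np.vstack([np.ones_like(x), x]).T
    coef2, *_ = np.linalg.lstsq(A, np.asarray(sp2), rcond=None)
    coef1, *_ = np.linalg.lstsq(A, np.asarray(sp1), rcond=None)
    sigma2 = max(float(coef2[0] + coef2[1] * x_full), 0.0)
    sigma1 = max(float(coef1[0] + coef1[1] * x_full), 0.0)
    return SubsetErrorResult(
        sigma_tau2_fs=sigma2,
        sigma_tau1_ps=sigma1,
        subset_sizes=sizes_arr,
        spread_tau2_fs=np.asarray(sp2),
        spread_tau1_ps=np.asarray(sp1),
        n_full=n,
    )
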