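"""End-to-end orchestration: sample -> select -> hop swarm -> fit, seeded and logged.

One master seed spawns a named child stream per stochastic stage (bath setup,
ground-state sampling, the subset-error reshuffles) and one per hopping
trajectory id, so enlarging the swarm never perturbs existing trajectories and
a rerun with the same config is byte-identical.  Every stage writes delimited
text tables plus a JSON run manifest (config echo, seeds, versions) under the
configured output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fssh import HoppingConfig, HoppingTrajectory, run_hopping_trajectory
from .lifetimes import (
    LifetimeFit,
    SubsetErrorResult,
    SwarmPopulations,
    fit_lifetimes,
    fit_single_exponential,
    normalized_occupancies,
    subset_error_extrapolation,
)
from .md import (
    EngineSet,
    InitialCondition,
    PhaseSpaceState,
    SamplingConfig,
    Snapshot,
    run_ground_state_md,
    select_initial_conditions,
)
from .qmmm import partition_system
from .surfaces import (
    ModelSurface,
    SolventBathEngine,
    SurfaceEngine,
    make_avoided_crossing_model,
    make_solvent_bath,
    maxwell_boltzmann_velocities,
    zero_engine,
)
from .xyz import XYZFrame, write_xyz

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "build_system", "state_to_frame"]

# named sub-stream keys under the master seed
_STREAM_BATH = 0
_STREAM_GROUND = 1
_STREAM_SUBSETS = 2
_STREAM_TRAJ = 10


def _rng(master_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=master_seed, spawn_key=key))


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration of a full pipeline run (see ``RunConfig.from_yaml``)."""

    seed: int
    outdir: str
    n_states: int = 3
    model_params: dict = field(default_factory=dict)
    bath_particles: int = 12
    bath_temperature: float = 298.0
    bath_coupling: float = 0.01
    sampling: SamplingConfig = field(default_factory=SamplingConfig)
    energy_window: tuple[float, float] = (0.0, 1.0e9)
    strength_threshold: float = 0.0
    target_surface: int | None = None  # default: highest excited state, capped at 2
    swarm_size: int = 20
    t_max_fs: float = 100.0
    dt_hopping: float = 0.1
    n_substeps: int = 20
    frustrated_policy: str = "keep"
    hop_collision_frequency: float = 0.0
    quiescence_fs: float | None = None
    fit_enabled: bool = True
    grid_points: int = 300
    n_reshuffles: int = 10
    min_subset: int = 30
    abscissa: str = "inv_n"
    write_trajectory_xyz: bool = False

    def __post_init__(self) -> None:
        if self.swarm_size < 1:
            raise ValueError("swarm size must be >= 1")
        if self.n_states not in (2, 3):
            raise ValueError("n_states must be 2 or 3")
        if self.t_max_fs <= 0:
            raise ValueError("t_max must be positive")
        if self.bath_particles < 0:
            raise ValueError("bath_particles must be >= 0")

    @property
    def start_surface(self) -> int:
        if self.target_surface is not None:
            return self.target_surface
        return min(2, self.n_states - 1)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        model = d.pop("model", {})
        bath = d.pop("bath", {})
        sampling = d.pop("sampling", {})
        selection = d.pop("selection", {})
        swarm = d.pop("swarm", {})
        fit = d.pop("fit", {})
        io = d.pop("io", {})
        kwargs: dict = {
            "seed": int(d.pop("seed")),
            "outdir": str(d.pop("outdir", "results/run")),
        }
        if d:
            raise ValueError(f"unknown top-level config keys: {sorted(d)}")
        kwargs["n_states"] = int(model.get("n_states", 3))
        kwargs["model_params"] = dict(model.get("params", {}))
        kwargs["bath_particles"] = int(bath.get("n_particles", 12))
        kwargs["bath_temperature"] = float(bath.get("temperature", 298.0))
        kwargs["bath_coupling"] = float(bath.get("coupling_strength", 0.01))
        kwargs["sampling"] = SamplingConfig(**sampling)
        if "energy_window" in selection:
            kwargs["energy_window"] = tuple(float(x) for x in selection["energy_window"])
        kwargs["strength_threshold"] = float(selection.get("strength_threshold", 0.0))
        if "target_surface" in selection:
            kwargs["target_surface"] = int(selection["target_surface"])
        kwargs["swarm_size"] = int(swarm.get("size", 20))
        kwargs["t_max_fs"] = float(swarm.get("t_max_fs", 100.0))
        kwargs["dt_hopping"] = float(swarm.get("dt", 0.1))
        kwargs["n_substeps"] = int(swarm.get("n_substeps", 20))
        kwargs["frustrated_policy"] = str(swarm.get("frustrated_policy", "keep"))
        kwargs["hop_collision_frequency"] = float(swarm.get("collision_frequency", 0.0))
        if swarm.get("quiescence_fs") is not None:
            kwargs["quiescence_fs"] = float(swarm["quiescence_fs"])
        kwargs["fit_enabled"] = bool(fit.get("enabled", True))
        kwargs["grid_points"] = int(fit.get("grid_points", 300))
        kwargs["n_reshuffles"] = int(fit.get("n_reshuffles", 10))
        kwargs["min_subset"] = int(fit.get("min_subset", 30))
        kwargs["abscissa"] = str(fit.get("abscissa", "inv_n"))
        kwargs["write_trajectory_xyz"] = bool(io.get("write_trajectory_xyz", False))
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PipelineResult:
    snapshots: list[Snapshot]
    initial_conditions: list[InitialCondition]
    trajectories: list[HoppingTrajectory]
    populations: SwarmPopulations
    fit: LifetimeFit | None
    subset_errors: SubsetErrorResult | None
    outdir: Path


def build_system(config: RunConfig):
    """Construct the model surface, bath, engines, partition and the initial state."""
    model = make_avoided_crossing_model(config.n_states, config.model_params or None)
    n_qm = model.n_dof
    bath_rng = _rng(config.seed, _STREAM_BATH)
    bath = make_solvent_bath(
        config.bath_particles,
        config.bath_temperature,
        bath_rng,
        coupling_strength=config.bath_coupling,
    )
    total_dof = n_qm + bath.n_dof
    partition = partition_system(total_dof, range(n_qm))
    high = SurfaceEngine(model)
    low = SolventBathEngine(bath, n_qm) if bath.n_particles > 0 else zero_engine
    engines = EngineSet(surface=model, high=high, low=low)

    positions = np.concatenate([model.diabats[0].center, bath.positions.ravel()])
    masses = np.concatenate([model.masses, bath.dof_masses()])
    ground_rng = _rng(config.seed, _STREAM_GROUND)
    solute_v = maxwell_boltzmann_velocities(model.masses, config.sampling.temperature, ground_rng)
    velocities = np.concatenate([solute_v, bath.velocities.ravel()])
    state = PhaseSpaceState(
        positions=positions, velocities=velocities, masses=masses, time=0.0, partition=partition
    )
    return model, bath, engines, partition, state, ground_rng


def state_to_frame(state: PhaseSpaceState, n_qm: int, comment: dict | None = None) -> XYZFrame:
    """Map a phase-space state onto an XYZ frame: solute DOFs zero-padded into
    pseudo-atom triples (symbol X), bath particles as O."""
    solute = state.positions[:n_qm]
    padded = np.zeros(((n_qm + 2) // 3) * 3)
    padded[:n_qm] = solute
    coords = [padded.reshape(-1, 3)]
    symbols = ["X"] * (padded.size // 3)
    rest = state.positions[n_qm:]
    if rest.size:
        coords.append(rest.reshape(-1, 3))
        symbols += ["O"] * (rest.size // 3)
    return XYZFrame(symbols=symbols, coords=np.vstack(coords), comment=comment or {})


def _populations_table(pops: SwarmPopulations) -> pd.DataFrame:
    return pd.DataFrame(
        {"time_fs": pops.times, "s2": pops.s2, "s1": pops.s1, "s0": pops.s0}
    )


def _fit_table(fit: LifetimeFit) -> pd.DataFrame:
    # Column order mirrors the lifetime summary convention: n, tau2, sigma, tau1, sigma
    return pd.DataFrame(
        [
            {
                "n_traj": fit.n_traj,
                "tau2_fs": fit.tau2_fs,
                "sigma_tau2_fs": fit.sigma_tau2_fs,
                "tau1_ps": fit.tau1_ps,
                "sigma_tau1_ps": fit.sigma_tau1_ps,
            }
        ]
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run the full protocol and write the results bundle under ``config.outdir``.

    Stages: ground-state sampling with strided excitation snapshots; selection
    by energy window and strength threshold; a seeded swarm of hopping
    trajectories starting on the target excited surface; normalized occupancies
    on a common grid; the kinetic fit (sequential for three states,
    single-exponential for two) and, when the swarm is large enough, the
    reshuffled-subset error extrapolation.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    model, bath, engines, partition, state0, ground_rng = build_system(config)

    snapshots = run_ground_state_md(state0, engines, config.sampling, rng=ground_rng)
    if not snapshots:
        raise RuntimeError("stage 'sample': ground-state run produced no snapshots")
    write_xyz(
        outdir / "snapshots.xyz",
        [
            state_to_frame(
                s.state,
                model.n_dof,
                {"time_fs": s.state.time, "e0_ev": float(s.energies[0])},
            )
            for s in snapshots
        ],
    )

    selected = select_initial_conditions(
        snapshots,
        config.energy_window,
        config.strength_threshold,
        target_surface=config.start_surface,
    )
    if not selected:
        raise RuntimeError("stage 'select': no snapshot passed the selection criteria")

    trajectories: list[HoppingTrajectory] = []
    hop_cfg = HoppingConfig(
        t_max_fs=config.t_max_fs,
        dt=config.dt_hopping,
        n_substeps=config.n_substeps,
        frustrated_policy=config.frustrated_policy,
        collision_frequency=config.hop_collision_frequency,
        temperature=config.sampling.temperature,
        quiescence_fs=config.quiescence_fs,
        amplitude_stride=50 if config.write_trajectory_xyz else 0,
    )
    for i in range(config.swarm_size):
        init = selected[i % len(selected)]
        rng_i = _rng(config.seed, _STREAM_TRAJ, i)
        try:
            trajectories.append(run_hopping_trajectory(init, engines, hop_cfg, rng=rng_i))
        except Exception as err:
            raise RuntimeError(f"stage 'hop': trajectory {i} failed: {err}") from err

    grid = np.linspace(0.0, config.t_max_fs, config.grid_points)
    pops = normalized_occupancies(trajectories, grid)
    _populations_table(pops).to_csv(outdir / "populations.tsv", sep="\t", index=False)

    fit: LifetimeFit | None = None
    errors: SubsetErrorResult | None = None
    if config.fit_enabled:
        try:
            fit = (
                fit_lifetimes(pops) if config.n_states >= 3 else fit_single_exponential(pops)
            )
        except Exception as err:
            raise RuntimeError(f"stage 'fit': {err}") from err
        n = len(trajectories)
        if config.n_states >= 3 and any(n // k > config.min_subset for k in (2, 3)):
            try:
                errors = subset_error_extrapolation(
                    trajectories,
                    n_reshuffles=config.n_reshuffles,
                    min_subset=config.min_subset,
                    rng=_rng(config.seed, _STREAM_SUBSETS),
                    grid=grid,
                    abscissa=config.abscissa,
                )
                fit = dataclasses.replace(
                    fit,
                    sigma_tau2_fs=errors.sigma_tau2_fs,
                    sigma_tau1_ps=errors.sigma_tau1_ps,
                )
            except ValueError:
                errors = None  # swarm too small for two division levels
        _fit_table(fit).to_csv(outdir / "fit.tsv", sep="\t", index=False)

    if config.write_trajectory_xyz and trajectories and trajectories[0].geometry_history is not None:
        frames = [
            state_to_frame(
                dataclasses.replace(state0, positions=g, time=float(t)),
                model.n_dof,
                {"time_fs": float(t)},
            )
            for t, g in zip(trajectories[0].amplitude_times, trajectories[0].geometry_history)
        ]
        write_xyz(outdir / "trajectory_000.xyz", frames)

    events = [
        {
            "trajectory": i,
            "time_fs": ev.time,
            "source": ev.source,
            "target": ev.target,
            "accepted": ev.accepted,
            "frustrated": ev.frustrated,
        }
        for i, tr in enumerate(trajectories)
        for ev in tr.hop_events
    ]
    pd.DataFrame(
        events, columns=["trajectory", "time_fs", "source", "target", "accepted", "frustrated"]
    ).to_csv(outdir / "hop_events.tsv", sep="\t", index=False)

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["sampling"] = dataclasses.asdict(config.sampling)
    cfg_json = json.dumps(cfg_dict, sort_keys=True, default=str)
    manifest = {
        "package": "hopdyn",
        "version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "master_seed": config.seed,
        "seed_streams": {
            "bath": [_STREAM_BATH],
            "ground_md": [_STREAM_GROUND],
            "subset_reshuffles": [_STREAM_SUBSETS],
            "trajectory_i": [_STREAM_TRAJ, "i"],
        },
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_snapshots": len(snapshots),
        "n_selected": len(selected),
        "n_trajectories": len(trajectories),
        "terminations": sorted({t.termination for t in trajectories}),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")

    return PipelineResult(
        snapshots=snapshots,
        initial_conditions=selected,
        trajectories=trajectories,
        populations=pops,
        fit=fit,
        subset_errors=errors,
        outdir=outdir,
    )
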