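"""Experiment orchestration: boxes, temperature schedules, observables.

The study conditions are a fixed peptide concentration (1 mM in the
reference setup), a chain count NC, and either a constant reduced
temperature or the two-temperature alternation that switches the thermostat
target every ``half_cycle`` collisions to enhance thermal fluctuations
without a Metropolis exchange step.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .engine import DmdEngine, SystemState, TrajectoryLog
from .forcefield import CompiledSystem
from .structure import Structure
from ._amino import AB17_42

AVOGADRO = 6.02214076e23
_L_PER_A3 = 1.0e-27


def box_length(n_chains: int, concentration: float) -> float:
    """Cubic box edge in Å for *n_chains* at molar *concentration*.

    L = (NC / (c · N_A))^(1/3); use :func:`box_length_rounded` for the
    nearest-integer convenience form used in printed tables.
    """
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    volume_a3 = n_chains / (concentration * AVOGADRO) / _L_PER_A3
    return float(volume_a3 ** (1.0 / 3.0))


def box_length_rounded(n_chains: int, concentration: float) -> int:
    return int(round(box_length(n_chains, concentration)))


def reduced_time(t_physical: float, sigma: float, mass: float,
                 t_star: float) -> float:
    """t* = t · (k_B·T/m)^(1/2) / σ (k_B = 1 in reduced units)."""
    if sigma <= 0 or mass <= 0 or t_star <= 0:
        raise ValueError("sigma, mass and T* must be positive")
    return t_physical * np.sqrt(t_star / mass) / sigma


@dataclasses.dataclass
class TemperatureSchedule:
    """Constant or two-temperature alternating thermostat target."""

    kind: str                      # "constant" | "alternating"
    t1: float
    t2: float | None = None
    half_cycle: int = 5_000_000_000   # collisions per segment (full scale)

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "alternating"):
            raise ValueError("schedule kind must be constant or alternating")
        if self.t2 is None:
            self.t2 = self.t1
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("temperatures must be positive")
        if self.half_cycle <= 0:
            raise ValueError("half_cycle must be positive")
        if self.kind == "constant" and self.t1 != self.t2:
            raise ValueError("constant schedule requires T1 == T2")

    @property
    def initial_temperature(self) -> float:
        return self.t1

    def segments(self, budget: int) -> list[tuple[int, float]]:
        """(end_collision, T*) pairs covering exactly *budget* collisions."""
        if self.kind == "constant" or self.t1 == self.t2:
            return [(budget, self.t1)]
        out = []
        end = 0
        k = 0
        while end < budget:
            end = min(end + self.half_cycle, budget)
            out.append((end, self.t1 if k % 2 == 0 else self.t2))
            k += 1
        return out

    def n_switches(self, budget: int) -> int:
        return max(0, len(self.segments(budget)) - 1)


@dataclasses.dataclass
class RunConfig:
    """One simulation run at fixed concentration."""

    n_chains: int
    schedule: TemperatureSchedule
    concentration: float = 1.0e-3        # mol/L
    sequence: str = AB17_42
    collision_budget: int = 1_000_000
    snapshot_every: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.collision_budget <= 0:
            raise ValueError("collision budget must be positive")

    @property
    def box_length(self) -> float:
        return box_length(self.n_chains, self.concentration)


@dataclasses.dataclass
class RunResult:
    config: RunConfig
    final_state: SystemState
    observables: pd.DataFrame
    log: TrajectoryLog
    engine: DmdEngine

    def final_structure(self) -> Structure:
        return self.engine.as_structure(self.final_state)


def run_schedule(config: RunConfig, system: CompiledSystem,
                 initial_state: SystemState | None = None,
                 track_clusters: bool = True) -> RunResult:
    """Execute one run under *config* and record the observable series.

    Observables per snapshot: time, collision count, total energy (ε_HB),
    kinetic temperature, hydrogen-bond count and largest-cluster size.
    """
    import warnings

    from .conformers import make_random_config
    from .metrics import cluster_chains

    engine = DmdEngine(system)
    if initial_state is None:
        initial_state = make_random_config(
            config.n_chains, config.concentration, config.seed,
            system, temperature=config.schedule.initial_temperature)
    segments = config.schedule.segments(config.collision_budget)
    partial = config.collision_budget % config.snapshot_every
    if partial:
        warnings.warn(
            f"collision budget is not a multiple of the snapshot cadence; "
            f"recording the final partial interval of {partial} collisions",
            stacklevel=2)
    state, log = engine.advance(
        initial_state, config.collision_budget, schedule=segments,
        seed=config.seed, snapshot_every=config.snapshot_every)
    n = state.n_beads
    times = list(log.times)
    colls = list(log.collisions)
    potential = list(log.potential)
    kinetic = list(log.kinetic)
    hb = list(log.hb_counts)
    hb_x = list(log.interchain_hb_counts)
    frames = [log.positions[k] for k in range(log.n_frames)]
    if partial:
        times.append(state.time)
        colls.append(state.collision_count - initial_state.collision_count)
        potential.append(state.potential)
        kinetic.append(0.5 * float((state.velocities ** 2).sum()))
        hb.append(state.n_hydrogen_bonds())
        topo = system.topology
        hb_x.append(sum(
            1 for i, j in enumerate(state.hb_partner)
            if 0 <= j and i < j and topo.chain[i] != topo.chain[j]))
        frames.append(state.positions)
    largest = []
    if track_clusters:
        for pos_frame in frames:
            pos = engine.unwrap_positions(pos_frame, state.box_length)
            s = Structure.from_flat(system.topology, pos)
            sizes = [len(c) for c in cluster_chains(s, system)]
            largest.append(max(sizes) if sizes else 0)
    else:
        largest = [0] * len(frames)
    obs = pd.DataFrame({
        "time": times,
        "collisions": colls,
        "energy": np.asarray(potential) + np.asarray(kinetic),
        "potential": potential,
        "kinetic_T": 2.0 * np.asarray(kinetic) / (3.0 * n),
        "hb_count": hb,
        "interchain_hb": hb_x,
        "largest_cluster": largest,
    })
    return RunResult(config, state, obs, log, engine)


@dataclasses.dataclass
class FibrillizationScan:
    """Outcome of a temperature scan for the fibrillization boundary."""

    boundary: float | None
    flag: str                        # "bracketed" | "above_grid" | "below_grid"
    temperatures: list[float]
    outcomes: list[bool]


def scan_fibrillization_temperature(configs: list[RunConfig],
                                    fibril_criterion,
                                    system: CompiledSystem | None = None,
                                    run_fn=None) -> FibrillizationScan:
    """Bracket the temperature above which the fibril criterion fails.

    *configs* must use constant schedules; they are sorted by temperature
    and each is run (via *run_fn(config)* if given, else
    :func:`run_schedule`).  The boundary is the midpoint of the bracketing
    pair when the criterion flips once from satisfied (low T) to not
    (high T); an all-true or all-false grid returns a flagged, undefined
    boundary rather than raising.  Full-scale scans are cluster-budget
    work; desk use is restricted to toy systems.
    """
    ordered = sorted(configs, key=lambda c: c.schedule.t1)
    temps = [c.schedule.t1 for c in ordered]
    outcomes = []
    for cfg in ordered:
        if run_fn is not None:
            result = run_fn(cfg)
        else:
            if system is None:
                raise ValueError("system required when run_fn is not given")
            result = run_schedule(cfg, system)
        outcomes.append(bool(fibril_criterion(result)))
    if all(outcomes):
        return FibrillizationScan(None, "above_grid", temps, outcomes)
    if not any(outcomes):
        return FibrillizationScan(None, "below_grid", temps, outcomes)
    # first index where the criterion fails after holding
    boundary = None
    for k in range(len(temps) - 1):
        if outcomes[k] and not outcomes[k + 1]:
            boundary = 0.5 * (temps[k] + temps[k + 1])
    return FibrillizationScan(boundary, "bracketed", temps, outcomes)
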