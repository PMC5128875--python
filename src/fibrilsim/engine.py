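"""Event-driven dynamics: states, events and the advance loop.

Between discontinuities every bead moves ballistically; at a discontinuity an
exact impulse is applied: hard cores and bond walls reflect the radial
relative velocity, well boundaries convert potential into kinetic energy (or
reflect when the radial kinetic energy cannot pay for the step — a
"bounce"), and hydrogen-bond wells additionally pass a formation gate and a
single-occupancy registry.  An Andersen-style thermostat resamples one
bead's velocity from the Maxwell–Boltzmann distribution at exponentially
distributed ghost times.

Reduced units throughout: ε_HB = k_B = m_bead = 1, lengths in Å, so
T* = k_B·T/ε_HB and the time unit is τ = Å·(m/ε_HB)^(1/2).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import _kernel
from .forcefield import CompiledSystem, match_hydrogen_bonds, total_energy
from .structure import Structure

EVENT_KIND_NAMES = (
    "core", "well_in", "well_out", "bond_wall", "hb_form", "hb_break",
    "pass", "ghost", "bounce",
)


@dataclasses.dataclass
class SystemState:
    """Instantaneous mechanical state of a periodic bead system."""

    positions: np.ndarray            # (N, 3) Å
    velocities: np.ndarray           # (N, 3) Å/τ
    box_length: float                # Å
    time: float = 0.0                # τ
    collision_count: int = 0
    hb_partner: np.ndarray | None = None   # (N,) bead index or -1
    event_counter: np.ndarray | None = None
    #: exact potential energy maintained by the event loop (ε_HB); None
    #: until the state has been produced by :meth:`DmdEngine.advance`
    potential: float | None = None
    #: engine-owned (N, N) shell index per pair (which region between
    #: discontinuity radii); rebuilt from geometry when None
    pair_shell: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.ascontiguousarray(self.positions, dtype=float)
        self.velocities = np.ascontiguousarray(self.velocities, dtype=float)
        n = self.positions.shape[0]
        if self.hb_partner is None:
            self.hb_partner = np.full(n, -1, dtype=np.int32)
        if self.event_counter is None:
            self.event_counter = np.zeros(n, dtype=np.int64)

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "SystemState":
        return SystemState(self.positions.copy(), self.velocities.copy(),
                           self.box_length, self.time, self.collision_count,
                           self.hb_partner.copy(), self.event_counter.copy(),
                           self.potential,
                           None if self.pair_shell is None
                           else self.pair_shell.copy())

    def n_hydrogen_bonds(self) -> int:
        return int((self.hb_partner >= 0).sum()) // 2


@dataclasses.dataclass
class Event:
    """A predicted discontinuous event (for the single-step API)."""

    time: float
    kind: str                       # core/well_in/well_out/bond_wall/hb/ghost
    pair: tuple[int, int] | int
    radius: float
    counters: tuple[int, int] | None = None


@dataclasses.dataclass
class TrajectoryLog:
    """Snapshots and totals recorded by :meth:`DmdEngine.advance`."""

    times: np.ndarray
    positions: np.ndarray            # (S, N, 3)
    potential: np.ndarray
    kinetic: np.ndarray
    collisions: np.ndarray
    hb_counts: np.ndarray
    interchain_hb_counts: np.ndarray
    event_counts: dict[str, int]

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    def kinetic_temperature(self, n_beads: int) -> np.ndarray:
        return 2.0 * self.kinetic / (3.0 * n_beads)


# ---------------------------------------------------------------------------
# single-step reference operations (pure NumPy; the compiled loop is checked
# against these and against brute-force integration in the tests)


def next_event_time(state: SystemState, i: int, j: int,
                    radius: float) -> float | None:
    """Smallest positive time until |Δr + Δv·t| = radius under minimum image.

    Returns ``None`` when the discontinuity is unreachable.
    """
    L = state.box_length
    d = state.positions[i] - state.positions[j]
    d -= L * np.round(d / L)
    dv = state.velocities[i] - state.velocities[j]
    r2 = float(d @ d)
    b = float(d @ dv)
    v2 = float(dv @ dv)
    if v2 == 0.0:
        return None
    R2 = radius * radius
    if r2 > R2:
        if b >= 0.0:
            return None
        disc = b * b - v2 * (r2 - R2)
        if disc <= 0.0:
            return None
        return (-b - np.sqrt(disc)) / v2
    disc = b * b - v2 * (r2 - R2)
    return (-b + np.sqrt(disc)) / v2


def apply_pair_impulse(state: SystemState, i: int, j: int,
                       du: float) -> str:
    """Resolve a pair event at the current separation with energy step *du*.

    ``du = inf`` is a hard reflection; a finite positive *du* that exceeds
    the radial kinetic energy produces a bounce.  Returns the outcome
    ("reflect", "bounce" or "cross").  Momentum and total energy are
    conserved exactly (unit masses).
    """
    L = state.box_length
    d = state.positions[i] - state.positions[j]
    d -= L * np.round(d / L)
    r2 = float(d @ d)
    dv = state.velocities[i] - state.velocities[j]
    b = float(d @ dv)
    if not np.isfinite(du):
        fac = b / r2
        state.velocities[i] -= fac * d
        state.velocities[j] += fac * d
        return "reflect"
    u = b / np.sqrt(r2)
    crit = u * u - 4.0 * du
    if du > 0.0 and crit <= 0.0:
        fac = b / r2
        state.velocities[i] -= fac * d
        state.velocities[j] += fac * d
        return "bounce"
    u_new = np.sqrt(crit)
    if u < 0.0:
        u_new = -u_new
    half = 0.5 * (u_new - u) / np.sqrt(r2)
    state.velocities[i] += half * d
    state.velocities[j] -= half * d
    return "cross"


def ghost_kick(temperature: float,
               rng: np.random.Generator) -> np.ndarray:
    """Maxwell–Boltzmann velocity resample at reduced temperature T*."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    if temperature == 0.0:
        return np.zeros(3)
    return rng.normal(0.0, np.sqrt(temperature), 3)


def maxwell_velocities(n: int, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    if temperature == 0.0:
        return np.zeros((n, 3))
    return rng.normal(0.0, np.sqrt(temperature), (n, 3))


def kinetic_temperature(state_or_velocities) -> float:
    """T* = 2·KE / (3·N) in reduced units (k_B = m = 1)."""
    v = state_or_velocities.velocities \
        if isinstance(state_or_velocities, SystemState) else \
        np.asarray(state_or_velocities)
    n = v.shape[0]
    if n == 0:
        raise ValueError("state has no beads")
    return float((v ** 2).sum() / (3.0 * n))


# ---------------------------------------------------------------------------


class DmdEngine:
    """Compiled event loop for one system in a periodic cubic box."""

    def __init__(self, system: CompiledSystem, skin: float = 1.5):
        self.system = system
        self.skin = float(skin)
        t = system.table
        self._r2 = np.ascontiguousarray(system.type_radii ** 2)
        self._maxr = system.type_radii.max(axis=1).copy()
        self._level = np.ascontiguousarray(system.type_level)
        self._nd = system.type_nd.astype(np.int8)
        self._is_hb = system.type_is_hb.astype(np.bool_)
        self._kind = system.topology.kind.astype(np.int8)
        self._cos_thresh = float(np.cos(np.deg2rad(t.parallel_max_angle_deg)))
        self._parallel_on = bool(t.parallel_preference)

    def initial_state(self, positions: np.ndarray, velocities: np.ndarray,
                      box_length: float, register_hb: bool = True
                      ) -> SystemState:
        state = SystemState(positions, velocities, float(box_length))
        if register_hb:
            for i, j in match_hydrogen_bonds(self.system, state.positions,
                                             box_length=box_length):
                state.hb_partner[i] = j
                state.hb_partner[j] = i
        return state

    def potential_energy(self, state: SystemState) -> float:
        hb = []
        for i, j in enumerate(state.hb_partner):
            if 0 <= j and i < j:
                hb.append((i, int(j)))
        return total_energy(self.system, state.positions, hb_pairs=hb,
                            box_length=state.box_length)

    def advance(self, state: SystemState, n_collisions: int,
                schedule: list[tuple[int, float]] | None = None,
                seed: int = 0, snapshot_every: int = 0,
                ghost_rate: float | None = None,
                until_time: float | None = None,
                ) -> tuple[SystemState, TrajectoryLog]:
        """Run exactly *n_collisions* pair events from *state*.

        *schedule* is a list of ``(end_collision_count, T*)`` segments; when
        ``None`` the thermostat is off and the dynamics is purely
        Newtonian.  If *until_time* is given the run also stops once the
        clock reaches that absolute reduced time, whichever comes first.
        Deterministic for a fixed seed.
        """
        new = state.copy()
        n = new.n_beads
        if schedule is None:
            seg_end = np.array([n_collisions], dtype=np.int64)
            seg_T = np.array([0.0])
            rate = 0.0
        else:
            seg_end = np.array([s[0] for s in schedule], dtype=np.int64)
            seg_T = np.array([s[1] for s in schedule], dtype=float)
            rate = self.system.table.ghost_rate if ghost_rate is None \
                else float(ghost_rate)
        n_snap_max = (n_collisions // snapshot_every + 2) \
            if snapshot_every > 0 else 1
        snap_pos = np.zeros((n_snap_max, n, 3))
        snap_t = np.zeros(n_snap_max)
        snap_pe = np.zeros(n_snap_max)
        snap_ke = np.zeros(n_snap_max)
        snap_nc = np.zeros(n_snap_max, dtype=np.int64)
        snap_nhb = np.zeros(n_snap_max, dtype=np.int64)
        snap_nhb_x = np.zeros(n_snap_max, dtype=np.int64)
        tb = np.full(n, new.time)
        if new.pair_shell is None:
            new.pair_shell = self._initial_shells(new)
        pe0 = self.potential_energy(new)
        t, ncoll, pe, ke, n_snap, counts = _kernel.run_kernel(
            new.positions, new.velocities, tb,
            new.hb_partner, new.event_counter, new.pair_shell,
            self.system.ptype, self._nd, self._r2, self._level,
            self._is_hb, self._maxr,
            self._kind, self.system.topology.chain,
            self.system.ca_self, self.system.ca_prev,
            self.system.ca_next,
            float(new.box_length), self.skin,
            float(self.system.table.hb_aux_min),
            float(self.system.table.hb_aux_max),
            self._cos_thresh, self._parallel_on,
            float(self.system.table.eps_hb),
            rate, seg_end, seg_T,
            int(n_collisions), int(snapshot_every),
            snap_pos, snap_t, snap_pe, snap_ke, snap_nc, snap_nhb,
            snap_nhb_x,
            float(new.time),
            1.0e300 if until_time is None else float(until_time),
            float(pe0), int(seed) & 0x7FFFFFFF,
        )
        new.time = float(t)
        new.collision_count = state.collision_count + int(ncoll)
        new.potential = float(pe)
        log = TrajectoryLog(
            times=snap_t[:n_snap].copy(),
            positions=snap_pos[:n_snap].copy(),
            potential=snap_pe[:n_snap].copy(),
            kinetic=snap_ke[:n_snap].copy(),
            collisions=snap_nc[:n_snap].copy(),
            hb_counts=snap_nhb[:n_snap].copy(),
            interchain_hb_counts=snap_nhb_x[:n_snap].copy(),
            event_counts={name: int(c) for name, c in
                          zip(EVENT_KIND_NAMES, counts)},
        )
        return new, log

    def _initial_shells(self, state: SystemState) -> np.ndarray:
        """Shell index per pair from current geometry (min image)."""
        pos = state.positions
        L = state.box_length
        n = pos.shape[0]
        ptype = self.system.ptype
        nd = self.system.type_nd
        shells = np.zeros((n, n), dtype=np.int8)
        for i in range(n):
            d = pos - pos[i]
            d -= L * np.round(d / L)
            r2 = (d * d).sum(axis=1)
            trow = ptype[i]
            count = np.zeros(n, dtype=np.int8)
            for k in range(self._r2.shape[1]):
                count += ((k < nd[trow]) & (r2 > self._r2[trow, k]))
            shells[i] = count
        np.fill_diagonal(shells, 0)
        return shells

    # -- analysis helpers -------------------------------------------------
    def unwrap_positions(self, state_or_pos,
                         box_length: float | None = None) -> np.ndarray:
        """Reconnect chains across the periodic boundary.

        Walks each chain's bond graph, placing every bead at its parent's
        position plus the minimum-image bond vector, so intra-chain
        distances are correct even when a chain straddles the box edge.
        """
        if isinstance(state_or_pos, SystemState):
            pos = state_or_pos.positions
            L = state_or_pos.box_length
        else:
            pos = np.asarray(state_or_pos)
            L = box_length
        if L is None:
            raise ValueError("box_length required to unwrap raw positions")
        topo = self.system.topology
        out = pos.copy()
        adj: dict[int, list[int]] = {b: [] for b in range(topo.n_beads)}
        for i, j in topo.bonds:
            adj[int(i)].append(int(j))
            adj[int(j)].append(int(i))
        visited = np.zeros(topo.n_beads, dtype=bool)
        for c in range(topo.n_chains):
            root = int(topo.beads_of_chain(c)[0])
            stack = [root]
            visited[root] = True
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if visited[v]:
                        continue
                    d = pos[v] - out[u]
                    d -= L * np.round(d / L)
                    out[v] = out[u] + d
                    visited[v] = True
                    stack.append(v)
        return out

    def as_structure(self, state: SystemState) -> Structure:
        return Structure.from_flat(self.system.topology,
                                   self.unwrap_positions(state))
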