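"""Discontinuous pair potentials and energy bookkeeping.

Every bead pair of a system maps to one *interaction type*: an ordered list
of discontinuity radii with piecewise-constant energy levels between them
(``inf`` inside a hard core or outside a bond wall, ``-ε`` inside a well, 0
beyond the outermost range).  Types cover

* hard-sphere cores for all non-bonded pairs,
* reduced *squeeze* cores between a side chain and the backbone of its
  sequence neighbours (local sterics, L-isomer support),
* square wells between side chains (20x20 matrix, with the D23-K28 pair
  scaled by the salt-bridge factor κ),
* hard walls at l(1±δ) for covalent and pseudo bonds,
* the directional hydrogen-bond well between NH and CO beads, gated by
  occupancy, auxiliary neighbour distances and the parallel-strand
  preference.

The same compiled tables drive the event engine and the O(n²) energy
enumeration used for audits, so the two can be cross-checked directly.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .params import InteractionTable
from .structure import Structure
from .topology import (
    KIND_CA,
    KIND_CO,
    KIND_NH,
    KIND_SC,
    PeptideTopology,
)

INF = np.inf


class InconsistentStateError(RuntimeError):
    """A state violates a hard constraint of the model."""


@dataclasses.dataclass
class CompiledSystem:
    """Topology + table compiled to flat pair-type arrays."""

    topology: PeptideTopology
    table: InteractionTable
    ptype: np.ndarray          # (N, N) int16 type id, 0 = no interaction
    type_nd: np.ndarray        # (T,) number of discontinuities (<= 3)
    type_radii: np.ndarray     # (T, 3) radii Å, ascending, 0-padded
    type_level: np.ndarray     # (T, 4) energy level per shell, inside-out
    type_is_hb: np.ndarray     # (T,) bool
    type_is_bond: np.ndarray   # (T,) bool
    ca_prev: np.ndarray        # (N,) bead index of CA(res-1) or CA(res)
    ca_next: np.ndarray        # (N,) bead index of CA(res+1) or CA(res)
    ca_self: np.ndarray        # (N,) bead index of own residue's CA

    @property
    def n_beads(self) -> int:
        return self.topology.n_beads

    def pair_type(self, i: int, j: int) -> int:
        return int(self.ptype[i, j])

    def max_range(self) -> float:
        return float(self.type_radii.max())


# ---------------------------------------------------------------------------
# compilation


class _TypeRegistry:
    def __init__(self) -> None:
        self.types: dict[tuple, int] = {}
        self.rows: list[tuple] = []
        # type 0: no interaction
        self.of((), (0.0,), False, False)

    def of(self, radii, levels, is_hb: bool, is_bond: bool) -> int:
        key = (tuple(np.round(radii, 9)), tuple(levels), is_hb, is_bond)
        if key not in self.types:
            self.types[key] = len(self.rows)
            self.rows.append(key)
        return self.types[key]

    def tables(self):
        t = len(self.rows)
        nd = np.zeros(t, dtype=np.int8)
        radii = np.zeros((t, 3))
        level = np.zeros((t, 4))
        is_hb = np.zeros(t, dtype=bool)
        is_bond = np.zeros(t, dtype=bool)
        for k, (r, lv, hb, bd) in enumerate(self.rows):
            nd[k] = len(r)
            radii[k, : len(r)] = r
            level[k, : len(lv)] = lv
            is_hb[k] = hb
            is_bond[k] = bd
        return nd, radii, level, is_hb, is_bond


def _core_type(reg: _TypeRegistry, d: float) -> int:
    return reg.of((d,), (INF, 0.0), False, False)


def _well_type(reg: _TypeRegistry, core: float, rng: float,
               depth: float) -> int:
    if depth == 0.0 or rng <= core:
        return _core_type(reg, core)
    return reg.of((core, rng), (INF, -depth, 0.0), False, False)


def compile_system(topology: PeptideTopology,
                   table: InteractionTable) -> CompiledSystem:
    """Assign an interaction type to every bead pair."""
    n = topology.n_beads
    kind = topology.kind
    aa = topology.aa
    chain = topology.chain
    res = topology.resnum
    reg = _TypeRegistry()

    # bead categories: 0..2 backbone kinds, 3 + aa for side chains
    cat = np.where(kind == KIND_SC, 3 + aa.astype(np.int16),
                   kind.astype(np.int16))
    ncat = 3 + 20
    base = np.zeros((ncat, ncat), dtype=np.int16)
    bb_d = [table.backbone_diameters[k] for k in ("NH", "CA", "CO")]
    core_sc = table.sc_pair_core()
    for a in range(ncat):
        for b in range(a, ncat):
            if a < 3 and b < 3:
                t = _core_type(reg, 0.5 * (bb_d[a] + bb_d[b]))
            elif a < 3 <= b:
                t = _core_type(reg,
                               0.5 * (bb_d[a] + table.sc_diameters[b - 3]))
            else:
                t = _well_type(reg, core_sc[a - 3, b - 3],
                               table.sc_well_range[a - 3, b - 3],
                               table.sc_well_depth[a - 3, b - 3])
            base[a, b] = base[b, a] = t

    ptype = base[cat[:, None], cat[None, :]].copy()
    np.fill_diagonal(ptype, 0)

    same_chain = chain[:, None] == chain[None, :]
    dres = np.abs(res[:, None] - res[None, :])

    # hydrogen-bond pairs: NH with CO, different residues, and either on
    # different chains or separated by at least the local-exclusion window
    hb_core = table.hb_core()
    hb_t = reg.of((hb_core, table.hb_range), (INF, -table.eps_hb, 0.0),
                  True, False)
    is_nh = kind == KIND_NH
    is_co = kind == KIND_CO
    hb_mask = (is_nh[:, None] & is_co[None, :]) | \
              (is_co[:, None] & is_nh[None, :])
    hb_ok = hb_mask & (~same_chain |
                       (dres >= table.hb_min_same_chain_sep))
    ptype[hb_ok] = hb_t

    # local sterics: same-chain neighbours that are not bonded interact
    # through reduced cores (keeps turns from collapsing without freezing them)
    lf = table.local_backbone_factor
    local = same_chain & (dres <= 1)
    near_hb = hb_mask & same_chain & (dres >= 2) & \
        (dres < table.hb_min_same_chain_sep)
    for i, j in np.argwhere(np.triu(local | near_hb, 1)):
        if kind[i] == KIND_SC and kind[j] == KIND_SC:
            t = _core_type(reg, lf * core_sc[aa[i], aa[j]])
        elif kind[i] == KIND_SC or kind[j] == KIND_SC:
            s, b = (i, j) if kind[i] == KIND_SC else (j, i)
            # squeeze: SC against the neighbouring residue's backbone
            d = table.squeeze_distance(
                "ACDEFGHIKLMNPQRSTVWY"[aa[s]],
                ("NH", "CA", "CO")[kind[b]])
            t = _core_type(reg, d)
        else:
            t = _core_type(reg, lf * 0.5 * (bb_d[kind[i]] + bb_d[kind[j]]))
        ptype[i, j] = ptype[j, i] = t

    # enhanced salt bridge: scale the well of the configured SC residue pair
    ra, rb = table.salt_bridge_pair
    sc_a = np.nonzero((kind == KIND_SC) & (res == ra))[0]
    sc_b = np.nonzero((kind == KIND_SC) & (res == rb))[0]
    for i in sc_a:
        for j in sc_b:
            if i == j:
                continue
            t = _well_type(reg, core_sc[aa[i], aa[j]],
                           table.sc_well_range[aa[i], aa[j]],
                           table.salt_bridge_factor *
                           table.sc_well_depth[aa[i], aa[j]])
            ptype[i, j] = ptype[j, i] = t

    # bonds override everything
    delta = table.bond_tolerance
    for (i, j), l in zip(topology.bonds, topology.bond_lengths):
        t = reg.of((l * (1 - delta), l * (1 + delta)),
                   (INF, 0.0, INF), False, True)
        ptype[i, j] = ptype[j, i] = t

    nd, radii, level, t_hb, t_bond = reg.tables()

    # CA neighbour lookup for strand-direction vectors
    ca_self = np.zeros(n, dtype=np.int32)
    ca_prev = np.zeros(n, dtype=np.int32)
    ca_next = np.zeros(n, dtype=np.int32)
    bi = topology.bead_index
    lo = topology.first_residue
    hi = lo + topology.n_residues - 1
    for b in range(n):
        c, r = int(chain[b]), int(res[b])
        ca_self[b] = bi[(c, r, KIND_CA)]
        ca_prev[b] = bi[(c, max(r - 1, lo), KIND_CA)]
        ca_next[b] = bi[(c, min(r + 1, hi), KIND_CA)]

    return CompiledSystem(
        topology=topology, table=table, ptype=ptype,
        type_nd=nd, type_radii=radii, type_level=level,
        type_is_hb=t_hb, type_is_bond=t_bond,
        ca_prev=ca_prev, ca_next=ca_next, ca_self=ca_self,
    )


# ---------------------------------------------------------------------------
# potential queries


def pair_step_potential(system: CompiledSystem, i: int, j: int,
                        separation: float) -> tuple[float, np.ndarray]:
    """Energy level at *separation* and the discontinuity radii beyond it.

    Returns ``(level, radii)`` where *level* is the piecewise-constant energy
    (ε_HB units; ``inf`` inside a forbidden region) and *radii* the strictly
    increasing discontinuity radii outward of *separation*.
    """
    if separation <= 0:
        raise ValueError("separation must be positive")
    t = system.ptype[i, j]
    nd = int(system.type_nd[t])
    radii = system.type_radii[t, :nd]
    shell = int(np.searchsorted(radii, separation))
    return float(system.type_level[t, shell]), radii[shell:].copy()


def effective_well_depth(system: CompiledSystem, i: int, j: int) -> float:
    """Depth (ε_HB) of the attractive well between beads *i*, *j*, 0 if none.

    Already includes the κ enhancement for the configured salt-bridge pair.
    """
    t = system.ptype[i, j]
    nd = int(system.type_nd[t])
    levels = system.type_level[t, : nd + 1]
    finite = levels[np.isfinite(levels)]
    if finite.size == 0 or finite.min() >= 0:
        return 0.0
    return float(-finite.min())


def _delta(a: np.ndarray, b: np.ndarray,
           box_length: float | None) -> np.ndarray:
    d = a - b
    if box_length is not None:
        d = d - box_length * np.round(d / box_length)
    return d


def strand_vector(system: CompiledSystem, pos: np.ndarray, bead: int,
                  box_length: float | None = None) -> np.ndarray:
    """Local strand direction CA(i-1) -> CA(i+1) at a backbone bead."""
    v = _delta(pos[system.ca_next[bead]], pos[system.ca_prev[bead]],
               box_length)
    norm = np.linalg.norm(v)
    if norm == 0:
        raise InconsistentStateError("degenerate strand vector")
    return v / norm


def hb_eligible(system: CompiledSystem, pos: np.ndarray,
                nh: int, co: int,
                hb_partner: np.ndarray | None = None,
                box_length: float | None = None) -> bool:
    """Full hydrogen-bond formation rule for an NH/CO bead pair.

    True iff (1) the pair is an HB-typed pair (which encodes the same-chain
    sequence exclusion), (2) NH-CO separation is within range, (3) neither
    bead is already committed, (4) the auxiliary CA-neighbour distances fall
    in the configured window, and (5) when the parallel preference is on, the
    two local strand directions are within the orientation threshold.
    """
    topo = system.topology
    if topo.kind[nh] != KIND_NH or topo.kind[co] != KIND_CO:
        raise ValueError("hb_eligible expects an NH bead and a CO bead")
    t = system.ptype[nh, co]
    if not system.type_is_hb[t]:
        return False
    table = system.table
    d = float(np.linalg.norm(_delta(pos[nh], pos[co], box_length)))
    if not (system.type_radii[t, 0] < d <= table.hb_range):
        return False
    if hb_partner is not None and (hb_partner[nh] >= 0 or
                                   hb_partner[co] >= 0):
        return False
    aux1 = float(np.linalg.norm(
        _delta(pos[nh], pos[system.ca_self[co]], box_length)))
    aux2 = float(np.linalg.norm(
        _delta(pos[co], pos[system.ca_self[nh]], box_length)))
    if not (table.hb_aux_min <= aux1 <= table.hb_aux_max and
            table.hb_aux_min <= aux2 <= table.hb_aux_max):
        return False
    if table.parallel_preference:
        v1 = strand_vector(system, pos, nh, box_length)
        v2 = strand_vector(system, pos, co, box_length)
        if float(v1 @ v2) < np.cos(np.deg2rad(table.parallel_max_angle_deg)):
            return False
    return True


def match_hydrogen_bonds(system: CompiledSystem, pos: np.ndarray,
                         box_length: float | None = None
                         ) -> list[tuple[int, int]]:
    """Geometric HB assignment for a static structure.

    Enumerates eligible NH/CO pairs within range and commits them greedily by
    increasing separation under single occupancy per NH and per CO.
    """
    topo = system.topology
    nh_idx = np.nonzero(topo.kind == KIND_NH)[0]
    co_idx = np.nonzero(topo.kind == KIND_CO)[0]
    cand = []
    for i in nh_idx:
        dv = pos[co_idx] - pos[i]
        if box_length is not None:
            dv = dv - box_length * np.round(dv / box_length)
        d = np.linalg.norm(dv, axis=1)
        for j, dij in zip(co_idx[d <= system.table.hb_range],
                          d[d <= system.table.hb_range]):
            if system.type_is_hb[system.ptype[i, j]] and \
                    hb_eligible(system, pos, int(i), int(j),
                                box_length=box_length):
                cand.append((float(dij), int(i), int(j)))
    cand.sort()
    partner = np.full(topo.n_beads, -1, dtype=np.int64)
    out = []
    for _, i, j in cand:
        if partner[i] < 0 and partner[j] < 0:
            partner[i], partner[j] = j, i
            out.append((i, j))
    return out


# ---------------------------------------------------------------------------
# energies and audits


def _as_positions(system: CompiledSystem, x) -> np.ndarray:
    if isinstance(x, Structure):
        return x.to_flat(system.topology)
    return np.asarray(x, dtype=float)


def total_energy(system: CompiledSystem, state,
                 hb_pairs: list[tuple[int, int]] | None = None,
                 box_length: float | None = None,
                 core_tol: float = 1e-9) -> float:
    """Total interaction energy in ε_HB units by direct pair enumeration.

    Sums the piecewise-constant level of every non-HB pair at its current
    separation and adds ``-ε_HB`` per hydrogen bond (matched geometrically
    unless *hb_pairs* is given, e.g. from an engine registry).  Raises
    :class:`InconsistentStateError` on a hard-core overlap.
    """
    pos = _as_positions(system, state)
    n = pos.shape[0]
    energy = 0.0
    radii = system.type_radii
    level = system.type_level
    nd = system.type_nd
    for i in range(n - 1):
        d = pos[i + 1:] - pos[i]
        if box_length is not None:
            d -= box_length * np.round(d / box_length)
        r = np.linalg.norm(d, axis=1)
        trow = system.ptype[i, i + 1:]
        active = np.nonzero((trow != 0) &
                            (r < radii[trow].max(axis=1) + core_tol))[0]
        for k in active:
            t = trow[k]
            shell = int(np.searchsorted(radii[t, : nd[t]], r[k] + core_tol))
            lv = level[t, shell]
            if system.type_is_hb[t]:
                continue  # counted through the HB registry below
            if not np.isfinite(lv):
                if system.type_is_bond[t]:
                    continue  # bond-wall excursions audited separately
                raise InconsistentStateError(
                    f"hard-core overlap between beads {i} and {i + 1 + k} "
                    f"(r = {r[k]:.4f} Å)")
            energy += lv
    if hb_pairs is None:
        hb_pairs = match_hydrogen_bonds(system, pos)
    energy -= system.table.eps_hb * len(hb_pairs)
    return float(energy)


def core_matrix(system: CompiledSystem) -> np.ndarray:
    """(N, N) minimum allowed non-bonded separations (0 for bonds/none).

    Hydrogen-bond pairs contribute their NH-CO core.  Useful for vectorized
    overlap screening when generating conformations.
    """
    radii = system.type_radii[:, 0].copy()
    radii[system.type_is_bond] = 0.0
    radii[0] = 0.0
    return radii[system.ptype]


def audit_constraints(system: CompiledSystem, state,
                      box_length: float | None = None,
                      tol: float = 1e-9) -> list[str]:
    """Hard-constraint violations (core overlaps, bond-wall excursions)."""
    pos = _as_positions(system, state)
    issues = []
    radii = system.type_radii
    nd = system.type_nd
    n = pos.shape[0]
    for i in range(n - 1):
        d = pos[i + 1:] - pos[i]
        if box_length is not None:
            d -= box_length * np.round(d / box_length)
        r = np.linalg.norm(d, axis=1)
        trow = system.ptype[i, i + 1:]
        for k in np.nonzero(trow != 0)[0]:
            t = trow[k]
            j = i + 1 + k
            if system.type_is_bond[t]:
                lo, hi = radii[t, 0], radii[t, 1]
                if not (lo - tol <= r[k] <= hi + tol):
                    issues.append(
                        f"bond {i}-{j}: r={r[k]:.5f} outside "
                        f"[{lo:.5f}, {hi:.5f}]")
            else:
                core = radii[t, 0] if nd[t] else 0.0
                if system.type_is_hb[t]:
                    continue  # HB core checked only for committed pairs
                if r[k] < core - tol:
                    issues.append(
                        f"core overlap {i}-{j}: r={r[k]:.5f} < {core:.5f}")
    return issues
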