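"""Synthetic conformers: idealized fibril templates, coils and dilute boxes.

These generators stand in for simulated structures when exercising the
analysis layer.  The fibrillar templates are built from a planar Cα path
(straight β-strands joined by semicircular turns, with a small out-of-plane
pleat), stacked in register along z with a constant inter-chain rise, NH/CO
beads offset so that the in-register hydrogen-bond ladder forms between
neighbouring chains, and side-chain centroids alternating sides of the
sheet.  The U-shape places its turn at residues 24-27 so that D23 and K28
(and F19 and I32) sit mirror-paired across the two strands — the contact
motif of the U-shape amyloid fold; S-variants are three-strand serpentines
with distinct turn placements; D-variants are schematic alternative strand
topologies used to exercise multi-class classification.

Template geometry numbers (4.8 Å rise, 3.8 Å Cα spacing, arc-derived sheet
widths) are package conventions, documented in the methods note and chosen
once so the U template's contacts fall inside the default wells.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._amino import AB17_42, AB17_42_FIRST_RESIDUE, AA_INDEX
from ._chain_geometry import build_chain, coil_dihedrals
from .forcefield import CompiledSystem, audit_constraints, compile_system
from .params import InteractionTable, default_table
from .structure import Structure
from .topology import build_peptide

FIBRIL_SHAPES = ("U", "S1", "S2", "S3", "D1", "D2")
ALL_SHAPES = FIBRIL_SHAPES + ("BH", "coil", "extended")

CA_SPACING = 3.8          # Å along a strand
STACK_RISE = 4.85         # Å between stacked chains
PLEAT = 0.35              # Å out-of-plane zigzag
# turn placement per shape: list of (first turn residue, turn length)
TURNS = {
    "U": [(24, 4)],
    "S1": [(24, 4), (34, 4)],
    "S2": [(22, 4), (31, 4)],
    "S3": [(26, 4), (35, 4)],
    "D1": [(21, 4)],
    "D2": [(28, 4)],
    "extended": [],
}


@dataclasses.dataclass
class ConformerSpec:
    """Recipe for a generated multi-chain conformer."""

    shape: str
    n_chains: int = 1
    rise: float = STACK_RISE
    jitter: float = 0.0
    seed: int = 0
    sequence: str = AB17_42
    first_residue: int = AB17_42_FIRST_RESIDUE

    def __post_init__(self) -> None:
        if self.shape not in ALL_SHAPES:
            raise ValueError(f"unknown shape {self.shape!r}")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")
        for start, length in TURNS.get(self.shape, []):
            if not (self.first_residue < start and
                    start + length - 1 <
                    self.first_residue + len(self.sequence)):
                raise ValueError("turn outside the sequence range")


# ---------------------------------------------------------------------------
# template construction


def _serpentine_calpha(n_res: int, turns: list[tuple[int, int]],
                       first_residue: int) -> tuple[np.ndarray, np.ndarray,
                                                    np.ndarray, np.ndarray]:
    """Planar Cα path: (ca, tangent, lateral, sc_dir) arrays of shape (R, 3).

    Strands run along ±y in lanes of increasing x; each turn is a
    semicircular arc whose width follows from keeping the Cα spacing on the
    arc, so consecutive residues stay ~3.8 Å apart everywhere.  The lateral
    direction (used to offset NH/CO off the Cα trace) points across the
    sheet on strands and *outward* on turn arcs, so consecutive turn beads
    do not converge; side chains alternate along the global sheet normal on
    strands and point outward on turns.
    """
    ca = np.zeros((n_res, 3))
    tan = np.zeros((n_res, 3))
    lat = np.zeros((n_res, 3))
    sc_dir = np.zeros((n_res, 3))
    alt = np.where(np.arange(n_res) % 2 == 0, 1.0, -1.0)
    turn_set = {}
    for start, length in turns:
        for s in range(length):
            turn_set[start - first_residue + s] = (s + 1, length)
    x = 0.0
    y = 0.0
    direction = 1.0
    k = 0
    while k < n_res:
        if k in turn_set:
            s, length = turn_set[k]
            gaps = length + 1
            width = 2.0 * gaps * CA_SPACING / np.pi
            # arc from (x, y) [previous strand end] over the travel direction
            cx = x + width / 2.0
            ang = s * np.pi / gaps
            outward = np.array([-np.cos(ang),
                                np.sin(ang) * direction, 0.0])
            ca[k, :2] = (cx + (width / 2.0) * outward[0],
                         y + (width / 2.0) * outward[1])
            tan[k] = np.array([np.sin(ang),
                               np.cos(ang) * direction, 0.0])
            lat[k] = outward
            sc_dir[k] = outward
            if s == length:          # next residue starts the new strand
                x += width
                direction = -direction
            k += 1
            continue
        ca[k, 0] = x
        ca[k, 1] = y
        tan[k] = np.array([0.0, direction, 0.0])
        lat[k] = np.array([direction, 0.0, 0.0])   # tan x z
        sc_dir[k] = np.array([alt[k], 0.0, 0.0])
        # peek: does a turn start at k+1?
        if (k + 1) in turn_set:
            pass                      # y stays: arc anchors at strand end
        else:
            y += direction * CA_SPACING
        k += 1
    ca[:, 2] = PLEAT * alt
    return ca, tan, lat, sc_dir


def _template_chain(shape: str, sequence: str, first_residue: int,
                    table: InteractionTable) -> np.ndarray:
    """Single-chain (R, 4, 3) bead template for a fibrillar shape or BH."""
    n_res = len(sequence)
    if shape == "BH":
        # one empty slot in the ring keeps the chain-junction beads of
        # consecutive turns outside their hard cores
        slots = n_res + 1
        radius = slots * CA_SPACING / (2.0 * np.pi)
        theta = 2.0 * np.pi * np.arange(n_res) / slots
        ca = np.stack([radius * np.cos(theta), radius * np.sin(theta),
                       STACK_RISE * np.arange(n_res) / n_res], axis=1)
        tan = np.stack([-np.sin(theta), np.cos(theta),
                        np.zeros(n_res)], axis=1)
        lat = np.stack([np.cos(theta), np.sin(theta),
                        np.zeros(n_res)], axis=1)  # radial, outward
        side = np.where(np.arange(n_res) % 2 == 0, 1.0, -1.0)
        sc_dir = lat * side[:, None]
    else:
        ca, tan, lat, sc_dir = _serpentine_calpha(n_res, TURNS[shape],
                                                  first_residue)
    xyz = np.full((n_res, 4, 3), np.nan)
    up = np.array([0.0, 0.0, 1.0])
    for k, letter in enumerate(sequence):
        xyz[k, 1] = ca[k]
        xyz[k, 0] = ca[k] - 0.5 * tan[k] + 1.33 * lat[k] - 0.33 * up
        xyz[k, 2] = ca[k] + 0.5 * tan[k] + 1.40 * lat[k] + 0.33 * up
        if letter != "G":
            b = table.ca_sc[AA_INDEX[letter]]
            xyz[k, 3] = ca[k] + b * sc_dir[k]
    return xyz


def _stack(template: np.ndarray, n_chains: int, rise: float) -> np.ndarray:
    coords = np.empty((n_chains, *template.shape))
    for c in range(n_chains):
        coords[c] = template + np.array([0.0, 0.0, rise * c])
    return coords


def _check_overlaps(struct: Structure, table: InteractionTable) -> None:
    topo = build_peptide(struct.sequence, struct.n_chains, table,
                         first_residue=struct.first_residue)
    system = compile_system(topo, table)
    issues = [m for m in audit_constraints(system, struct)
              if m.startswith("core overlap")]
    if issues:
        raise RuntimeError("template generates hard-core overlaps: "
                           + issues[0])


def make_fibril(spec: ConformerSpec,
                table: InteractionTable | None = None,
                validate: bool = False) -> Structure:
    """In-register stacked fibril fixture for a fibrillar shape."""
    if spec.shape not in FIBRIL_SHAPES + ("extended",):
        raise ValueError(f"{spec.shape!r} is not a fibrillar shape")
    table = table or default_table()
    template = _template_chain(spec.shape, spec.sequence,
                               spec.first_residue, table)
    struct = Structure(spec.sequence, spec.first_residue,
                       _stack(template, spec.n_chains, spec.rise))
    if spec.jitter > 0:
        struct = perturb(struct, spec.jitter, spec.seed)
    if validate:
        _check_overlaps(struct, table)
    return struct


def make_beta_helix(n_chains: int,
                    table: InteractionTable | None = None,
                    jitter: float = 0.0, seed: int = 0,
                    validate: bool = False) -> Structure:
    """Helically wound inter-chain β-sheet (the off-pathway BH trimer motif).

    Each chain forms one full turn of a wide solenoid; chains continue each
    other along the helix, so hydrogen bonding is dominated by inter-chain
    ladder contacts.  Inter-chain by definition: requires >= 2 chains.
    """
    if n_chains < 2:
        raise ValueError("a β-helix aggregate needs at least 2 chains")
    table = table or default_table()
    template = _template_chain("BH", AB17_42, AB17_42_FIRST_RESIDUE, table)
    struct = Structure(AB17_42, AB17_42_FIRST_RESIDUE,
                       _stack(template, n_chains, STACK_RISE))
    if jitter > 0:
        struct = perturb(struct, jitter, seed)
    if validate:
        _check_overlaps(struct, table)
    return struct


def make_coil_chains(n_chains: int, seed: int = 0,
                     table: InteractionTable | None = None,
                     separation: float = 60.0) -> Structure:
    """Random-coil chains placed far apart (no inter-chain contacts)."""
    table = table or default_table()
    rng = np.random.default_rng(seed)
    cores = _single_chain_cores(AB17_42, table)
    coords = np.empty((n_chains, len(AB17_42), 4, 3))
    for c in range(n_chains):
        chain = _random_coil_chain(AB17_42, rng, table, cores)
        coords[c] = chain + np.array([separation * c, 0.0, 0.0])
    return Structure(AB17_42, AB17_42_FIRST_RESIDUE, coords)


def perturb(structure: Structure, amplitude: float,
            seed: int = 0) -> Structure:
    """Gaussian jitter: iid displacement with per-component σ = amplitude."""
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if amplitude == 0:
        return Structure(structure.sequence, structure.first_residue,
                         structure.coords.copy())
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, amplitude, structure.coords.shape)
    xyz = structure.coords + noise
    xyz[~np.isfinite(structure.coords)] = np.nan
    return Structure(structure.sequence, structure.first_residue, xyz)


# ---------------------------------------------------------------------------
# random dilute initial configurations


def _single_chain_cores(sequence: str,
                        table: InteractionTable) -> np.ndarray:
    """Minimum allowed separations between one chain's beads."""
    from .forcefield import core_matrix
    topo = build_peptide(sequence, 1, table)
    return core_matrix(compile_system(topo, table))


def _random_coil_chain(sequence: str, rng: np.random.Generator,
                       table: InteractionTable,
                       cores: np.ndarray | None = None,
                       max_tries: int = 500) -> np.ndarray:
    """Self-avoiding random coil satisfying every bonded constraint.

    Dihedrals are sampled from the coil basins and the whole chain is
    rejected if any non-bonded pair dips below its hard core (or squeeze)
    distance, so the result is a valid dynamical state.
    """
    n = len(sequence)
    if cores is None:
        cores = _single_chain_cores(sequence, table)
    for _ in range(max_tries):
        phi, psi = coil_dihedrals(n, rng)
        xyz = build_chain(sequence, phi, psi, table)
        flat = xyz.reshape(-1, 3)
        # dropping NaN rows leaves beads in topology order (glycine: no SC)
        p = flat[np.isfinite(flat[:, 0])]
        d = np.linalg.norm(p[:, None] - p[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if (d >= cores - 1e-9).all():
            return xyz
    raise RuntimeError("failed to generate a self-avoiding coil")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_random_config(n_chains: int, concentration: float, seed: int,
                       system: CompiledSystem,
                       temperature: float = 0.2,
                       clearance: float = 2.0,
                       max_tries: int = 400):
    """Dilute random start: coils at random positions/orientations.

    Chains are rejection-sampled so that every inter-chain bead pair stays
    beyond the largest interaction range plus *clearance* Å, giving a
    well-defined zero of interaction energy; velocities are
    Maxwell–Boltzmann at *temperature* (the schedule's first temperature in
    a full run).  Deterministic for a fixed seed.
    """
    from .engine import SystemState, maxwell_velocities
    from .protocol import box_length as _box

    topo = system.topology
    if topo.n_chains != n_chains:
        raise ValueError("system was compiled for a different chain count")
    table = system.table
    L = _box(n_chains, concentration)
    rng = np.random.default_rng(seed)
    min_gap = system.max_range() + clearance
    cores = _single_chain_cores(topo.sequence, table)
    placed: list[np.ndarray] = []
    for c in range(n_chains):
        ok = False
        for _ in range(max_tries):
            chain = _random_coil_chain(topo.sequence, rng, table, cores)
            flat = chain.reshape(-1, 3)
            flat = flat[np.isfinite(flat[:, 0])]
            rot = _random_rotation(rng)
            xyz = (flat - flat.mean(0)) @ rot.T
            origin = rng.uniform(0.0, L, 3)
            xyz = xyz + origin
            clash = False
            for other in placed:
                d = xyz[:, None, :] - other[None, :, :]
                d -= L * np.round(d / L)
                if (np.linalg.norm(d, axis=-1) < min_gap).any():
                    clash = True
                    break
            if not clash:
                placed.append(xyz)
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place chain {c} without overlap; "
                "density too high for a dilute start")
    pos = np.concatenate(placed, axis=0)
    if pos.shape[0] != topo.n_beads:
        raise RuntimeError("bead count mismatch during placement")
    vel = maxwell_velocities(topo.n_beads, temperature, rng)
    return SystemState(pos, vel, L)


# ---------------------------------------------------------------------------
# reference profiles


def reference_library(table: InteractionTable | None = None,
                      start: int | None = None, end: int | None = None,
                      min_separation: int = 5) -> dict:
    """One distance profile per polymorph class from the shipped templates.

    The similarity measure is intra-peptide and chain-averaged, so a single
    template chain per class defines its reference profile.
    """
    from .metrics import distance_profile

    table = table or default_table()
    start = AB17_42_FIRST_RESIDUE if start is None else start
    end = AB17_42_FIRST_RESIDUE + len(AB17_42) - 1 if end is None else end
    refs = {}
    for shape in FIBRIL_SHAPES:
        s = make_fibril(ConformerSpec(shape=shape, n_chains=1), table)
        refs[shape] = distance_profile(s.calpha(), start, end,
                                       min_separation)
    bh = make_beta_helix(2, table)
    refs["BH"] = distance_profile(bh.calpha(), start, end, min_separation)
    return refs
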