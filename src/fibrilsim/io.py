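"""File formats: coarse-grained PDB frames and reference Cα extraction.

Backbone beads map to atom names N/CA/C; the side-chain centroid is written
as pseudo-atom CB so standard tools display it attached to the residue.
Reference structures (experimental fibril models, multi-model NMR entries)
are read through biotite; model 1 is used when several are present, and any
chain missing a residue of the requested range is dropped with a warning.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from .structure import CalphaSet, Structure
from .topology import KIND_CA, KIND_CO, KIND_NH, KIND_SC

_ATOM_NAMES = {KIND_NH: "N", KIND_CA: "CA", KIND_CO: "C", KIND_SC: "CB"}
_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclasses.dataclass
class CGFrame:
    """One exported frame plus its metadata."""

    structure: Structure
    time: float = 0.0
    collisions: int = 0
    energy: float | None = None
    kinetic_t: float | None = None


def read_reference_calpha(path: str | Path, residue_range: tuple[int, int],
                          chain_offset: int = 0) -> CalphaSet:
    """Cα coordinates for every chain covering *residue_range* (inclusive).

    *chain_offset* is added to the file's residue numbers before the range
    is applied, to map references using another numbering convention onto
    the Aβ42 convention used throughout.  Chains missing any residue in
    range are excluded with a warning; an empty selection raises.
    """
    start, end = residue_range
    if end < start:
        raise ValueError("invalid residue range")
    pdb = bpdb.PDBFile.read(str(path))
    atoms = pdb.get_structure(model=1)
    ca = atoms[(atoms.atom_name == "CA") & ~atoms.hetero]
    wanted = np.arange(start, end + 1)
    chains = []
    kept_ids = []
    for cid in np.unique(ca.chain_id):
        sel = ca[ca.chain_id == cid]
        resnum = sel.res_id + chain_offset
        lookup = {int(r): k for k, r in enumerate(resnum)}
        missing = [int(r) for r in wanted if r not in lookup]
        if missing:
            warnings.warn(
                f"chain {cid} missing residue(s) {missing[:5]} in range "
                f"{start}-{end}; chain excluded", stacklevel=2)
            continue
        chains.append(sel.coord[[lookup[int(r)] for r in wanted]])
        kept_ids.append(str(cid))
    if not chains:
        raise ValueError(
            f"no chain covers residues {start}-{end} in {path}")
    return CalphaSet(wanted, np.stack(chains), kept_ids)


def write_cg_pdb(frame: CGFrame | Structure, path: str | Path) -> None:
    """Write a coarse-grained frame as a standard PDB file."""
    struct = frame.structure if isinstance(frame, CGFrame) else frame
    records = []
    for c in range(struct.n_chains):
        for k, letter in enumerate(struct.sequence):
            for kind in (KIND_NH, KIND_CA, KIND_CO, KIND_SC):
                xyz = struct.coords[c, k, kind]
                if not np.isfinite(xyz).all():
                    continue
                records.append((c, struct.first_residue + k, letter, kind,
                                xyz))
    n = len(records)
    atoms = bst.AtomArray(n)
    atoms.coord = np.array([r[4] for r in records], dtype=np.float32)
    atoms.chain_id = np.array(
        [chr(ord("A") + (r[0] % 26)) for r in records])
    atoms.res_id = np.array([r[1] for r in records])
    atoms.res_name = np.array([_ONE_TO_THREE[r[2]] for r in records])
    atoms.atom_name = np.array([_ATOM_NAMES[r[3]] for r in records])
    atoms.element = np.array(
        ["N" if r[3] == KIND_NH else "C" for r in records])
    atoms.hetero = np.zeros(n, dtype=bool)
    pdb = bpdb.PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


def write_trajectory_npz(path: str | Path, log, topology_info: dict,
                         **extra) -> None:
    """Self-describing trajectory container (compressed NumPy archive)."""
    np.savez_compressed(
        str(path),
        times=log.times, positions=log.positions, potential=log.potential,
        kinetic=log.kinetic, collisions=log.collisions,
        hb_counts=log.hb_counts,
        event_kinds=np.array(sorted(log.event_counts)),
        event_counts=np.array(
            [log.event_counts[k] for k in sorted(log.event_counts)]),
        **{f"meta_{k}": np.asarray(v) for k, v in topology_info.items()},
        **extra,
    )
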