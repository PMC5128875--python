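"""In-memory containers for coarse-grained structures.

A :class:`Structure` stores all beads of a multi-chain system on a regular
(chain, residue, bead-kind) grid; absent beads (glycine SC) are NaN.  A
:class:`CalphaSet` is the reduced Cα-only view that the similarity measure
and the PDB reader both produce, so simulated and experimental structures are
interchangeable downstream.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .topology import KIND_CA, KIND_NAMES, PeptideTopology


@dataclasses.dataclass
class CalphaSet:
    """Cα coordinates keyed by (chain, residue number)."""

    residue_numbers: np.ndarray          # (R,) increasing
    coords: np.ndarray                   # (C, R, 3) Å
    chain_ids: list                      # length C, display labels

    def __post_init__(self) -> None:
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (chains, residues, 3)")
        if self.coords.shape[1] != self.residue_numbers.shape[0]:
            raise ValueError("residue axis does not match residue_numbers")

    @property
    def n_chains(self) -> int:
        return self.coords.shape[0]

    def restrict(self, start: int, end: int) -> "CalphaSet":
        """Inclusive residue-number slice; raises if the range is not covered."""
        mask = (self.residue_numbers >= start) & (self.residue_numbers <= end)
        covered = set(self.residue_numbers[mask])
        wanted = set(range(start, end + 1))
        if wanted - covered:
            missing = sorted(wanted - covered)
            raise ValueError(f"structure missing residues {missing} "
                             f"in range {start}-{end}")
        return CalphaSet(self.residue_numbers[mask], self.coords[:, mask],
                         list(self.chain_ids))


@dataclasses.dataclass
class Structure:
    """All beads of ``n_chains`` copies of one sequence."""

    sequence: str
    first_residue: int
    coords: np.ndarray                   # (C, R, 4, 3) Å; NaN where no bead

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        c, r, k, d = self.coords.shape
        if (r, k, d) != (len(self.sequence), 4, 3):
            raise ValueError("coords shape inconsistent with sequence")

    @property
    def n_chains(self) -> int:
        return self.coords.shape[0]

    @property
    def n_residues(self) -> int:
        return self.coords.shape[1]

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.arange(self.first_residue,
                         self.first_residue + self.n_residues)

    def calpha(self) -> CalphaSet:
        return CalphaSet(self.residue_numbers, self.coords[:, :, KIND_CA],
                         [chr(ord("A") + (c % 26)) for c in
                          range(self.n_chains)])

    def bead(self, chain: int, resnum: int, kind: int) -> np.ndarray:
        return self.coords[chain, resnum - self.first_residue, kind]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | float = 0.0) -> "Structure":
        """Rigidly transformed copy (rotation about the origin, then shift)."""
        xyz = self.coords.copy()
        if rotation is not None:
            xyz = xyz @ np.asarray(rotation).T
        xyz = xyz + np.asarray(translation, dtype=float)
        return Structure(self.sequence, self.first_residue, xyz)

    # -- flat-array interop with PeptideTopology -------------------------
    def to_flat(self, topology: PeptideTopology) -> np.ndarray:
        """Positions ordered as *topology* beads; raises on mismatch."""
        if (topology.sequence != self.sequence
                or topology.n_chains != self.n_chains
                or topology.first_residue != self.first_residue):
            raise ValueError("structure does not match topology")
        pos = np.empty((topology.n_beads, 3))
        r0 = self.first_residue
        for b in range(topology.n_beads):
            pos[b] = self.coords[topology.chain[b],
                                 topology.resnum[b] - r0,
                                 topology.kind[b]]
        if not np.isfinite(pos).all():
            raise ValueError("missing bead coordinate for a topology bead")
        return pos

    @classmethod
    def from_flat(cls, topology: PeptideTopology,
                  pos: np.ndarray) -> "Structure":
        xyz = np.full((topology.n_chains, topology.n_residues, 4, 3), np.nan)
        r0 = topology.first_residue
        for b in range(topology.n_beads):
            xyz[topology.chain[b], topology.resnum[b] - r0,
                topology.kind[b]] = pos[b]
        return cls(topology.sequence, topology.first_residue, xyz)

    def concat(self, other: "Structure",
               offset: np.ndarray | float = 0.0) -> "Structure":
        """Stack another structure's chains (same sequence) after this one."""
        if (other.sequence != self.sequence
                or other.first_residue != self.first_residue):
            raise ValueError("can only concatenate matching sequences")
        shifted = other.transformed(translation=offset)
        return Structure(self.sequence, self.first_residue,
                         np.concatenate([self.coords, shifted.coords]))


def kind_name(kind: int) -> str:
    return KIND_NAMES[kind]
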