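"""Peptide topology: beads, bonds and chirality for the four-bead model.

Each residue carries three backbone united atoms (NH, CA, CO) and one
side-chain centroid (SC); glycine has no SC bead.  Bonds — covalent and
pseudo — are hard walls at l·(1±δ), which is what fixes backbone angles, the
trans peptide plane and, through the NH/CO/CA-to-SC distance triple, the
L-isomer handedness of every side chain.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._amino import AA_INDEX, validate_sequence
from .params import InteractionTable

KIND_NH, KIND_CA, KIND_CO, KIND_SC = 0, 1, 2, 3
KIND_NAMES = ("NH", "CA", "CO", "SC")


@dataclasses.dataclass
class PeptideTopology:
    """Bead-level description of ``n_chains`` identical peptide chains."""

    sequence: str
    n_chains: int
    first_residue: int                      # residue number of sequence[0]
    kind: np.ndarray                        # (N,) int8, KIND_* codes
    aa: np.ndarray                          # (N,) int8, index into AA_CODES
    chain: np.ndarray                       # (N,) int32
    resnum: np.ndarray                      # (N,) int32, author numbering
    bonds: np.ndarray                       # (B, 2) int32 bead indices
    bond_lengths: np.ndarray                # (B,) Å
    bond_tolerance: float
    bead_index: dict                        # (chain, resnum, kind) -> bead

    @property
    def n_beads(self) -> int:
        return self.kind.shape[0]

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def residue_numbers(self) -> np.ndarray:
        return np.arange(self.first_residue,
                         self.first_residue + len(self.sequence))

    def beads_of_chain(self, c: int) -> np.ndarray:
        return np.nonzero(self.chain == c)[0]

    def ca_index(self, c: int, resnum: int) -> int:
        return self.bead_index[(c, resnum, KIND_CA)]

    def ca_indices(self, c: int) -> np.ndarray:
        return np.array([self.ca_index(c, r) for r in self.residue_numbers])

    def chirality_quadruples(self) -> list[tuple[int, int, int, int]]:
        """(CA, NH, CO, SC) per non-glycine residue; the sign of
        det[NH-CA, CO-CA, SC-CA] is the residue's handedness."""
        quads = []
        for c in range(self.n_chains):
            for r, aa in zip(self.residue_numbers, self.sequence):
                if aa == "G":
                    continue
                quads.append((
                    self.bead_index[(c, r, KIND_CA)],
                    self.bead_index[(c, r, KIND_NH)],
                    self.bead_index[(c, r, KIND_CO)],
                    self.bead_index[(c, r, KIND_SC)],
                ))
        return quads

    def bonded_pairs(self) -> set[tuple[int, int]]:
        return {(min(i, j), max(i, j)) for i, j in self.bonds}


def build_peptide(
    sequence: str,
    n_chains: int,
    table: InteractionTable | None = None,
    first_residue: int = 17,
) -> PeptideTopology:
    """Construct the bead/bond topology for *n_chains* copies of *sequence*.

    Raises ``ValueError`` for an empty or non-standard sequence and for
    ``n_chains < 1``.
    """
    seq = validate_sequence(sequence)
    if n_chains < 1:
        raise ValueError("n_chains must be >= 1")
    if table is None:
        from .params import default_table
        table = default_table()

    kind, aa, chain, resnum = [], [], [], []
    bead_index: dict = {}
    bonds: list[tuple[int, int, float]] = []
    bl = table.bond_lengths

    for c in range(n_chains):
        for k, letter in enumerate(seq):
            r = first_residue + k
            ai = AA_INDEX[letter]
            kinds = (KIND_NH, KIND_CA, KIND_CO) if letter == "G" else \
                    (KIND_NH, KIND_CA, KIND_CO, KIND_SC)
            for kd in kinds:
                bead_index[(c, r, kd)] = len(kind)
                kind.append(kd)
                aa.append(ai)
                chain.append(c)
                resnum.append(r)
            nh = bead_index[(c, r, KIND_NH)]
            ca = bead_index[(c, r, KIND_CA)]
            co = bead_index[(c, r, KIND_CO)]
            bonds.append((nh, ca, bl["nh_ca"]))
            bonds.append((ca, co, bl["ca_co"]))
            bonds.append((nh, co, bl["nh_co"]))
            if letter != "G":
                sc = bead_index[(c, r, KIND_SC)]
                bonds.append((ca, sc, table.ca_sc[ai]))
                bonds.append((nh, sc, table.nh_sc[ai]))
                bonds.append((co, sc, table.co_sc[ai]))
            if k > 0:
                pr = r - 1
                pco = bead_index[(c, pr, KIND_CO)]
                pca = bead_index[(c, pr, KIND_CA)]
                bonds.append((pco, nh, bl["co_nh_next"]))
                bonds.append((pca, nh, bl["ca_nh_next"]))
                bonds.append((pco, ca, bl["co_ca_next"]))
                bonds.append((pca, ca, bl["ca_ca_next"]))

    pairs = np.array([(i, j) for i, j, _ in bonds], dtype=np.int32)
    lengths = np.array([l for _, _, l in bonds], dtype=float)
    if (lengths <= 0).any():
        raise ValueError("all ideal bond lengths must be positive")
    return PeptideTopology(
        sequence=seq,
        n_chains=n_chains,
        first_residue=first_residue,
        kind=np.array(kind, dtype=np.int8),
        aa=np.array(aa, dtype=np.int8),
        chain=np.array(chain, dtype=np.int32),
        resnum=np.array(resnum, dtype=np.int32),
        bonds=pairs,
        bond_lengths=lengths,
        bond_tolerance=table.bond_tolerance,
        bead_index=bead_index,
    )
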