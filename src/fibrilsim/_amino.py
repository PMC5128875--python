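"""Amino-acid bookkeeping shared across the package.

One-letter codes, side-chain volumes and interaction classes used to build
the default parameter tables.  The numeric values here are stand-in defaults
following the conventions of four-bead-per-residue square-well protein models
(three backbone united atoms NH, CA, CO plus one side-chain centroid); every
number is overridable through the config files.
"""

from __future__ import annotations

import numpy as np

AA_CODES = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_CODES)}
N_AA = len(AA_CODES)

#: Aβ17-42 one-letter sequence (residues numbered 17..42).
AB17_42 = "LVFFAEDVGSNKGAIIGLMVGGVVIA"
AB17_42_FIRST_RESIDUE = 17

# Approximate side-chain volumes in Å^3 (residue volume minus the glycine
# backbone); used only to derive default side-chain sphere diameters.
SIDECHAIN_VOLUME = {
    "A": 26.0, "R": 113.0, "N": 58.0, "D": 51.0, "C": 44.0,
    "Q": 80.0, "E": 73.0, "G": 0.0, "H": 92.0, "I": 93.0,
    "K": 96.0, "L": 93.0, "M": 98.0, "F": 115.0, "P": 66.0,
    "S": 31.0, "T": 51.0, "W": 146.0, "Y": 123.0, "V": 71.0,
}

HYDROPHOBIC = set("AVLIMFWYCP")
POSITIVE = set("KRH")
NEGATIVE = set("DE")
POLAR = set("STNQG")

# Sphere packing factor applied to the volume-equivalent diameter; keeps the
# large aromatic side chains from dominating the steric footprint.
_PACKING = 0.80


def sidechain_diameter(aa: str) -> float:
    """Default side-chain hard-sphere diameter in Å for one-letter code *aa*."""
    v = SIDECHAIN_VOLUME[aa]
    if v <= 0.0:  # glycine: no side-chain bead; nominal value for table shape
        return 3.0
    return _PACKING * (6.0 * v / np.pi) ** (1.0 / 3.0)


def ca_sc_bond(aa: str) -> float:
    """Default CA-to-side-chain-centroid pseudo-bond length in Å."""
    if aa == "G":
        return 0.0
    return 1.0 + 0.5 * sidechain_diameter(aa)


def pair_well_depth(a: str, b: str) -> float:
    """Default square-well depth (ε_HB units) for side chains *a*, *b*.

    Positive return value = attractive depth; negative = repulsive shoulder.
    Class-based rules: hydrophobic pairing dominates, opposite charges attract
    strongly (salt bridge, before any D23-K28 enhancement), like charges repel.
    """
    if a == "G" or b == "G":
        return 0.0
    in_h = (a in HYDROPHOBIC, b in HYDROPHOBIC)
    in_p = (a in POSITIVE, b in POSITIVE)
    in_n = (a in NEGATIVE, b in NEGATIVE)
    if all(in_h):
        return 0.20
    if (in_p[0] and in_n[1]) or (in_n[0] and in_p[1]):
        return 0.30
    if all(in_p) or all(in_n):
        return -0.15
    if any(in_h):
        return 0.05
    return 0.10


def validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper()
    if not seq:
        raise ValueError("empty peptide sequence")
    bad = sorted(set(seq) - set(AA_CODES))
    if bad:
        raise ValueError(f"unknown residue code(s): {','.join(bad)}")
    return seq
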