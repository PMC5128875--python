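"""Internal-coordinate chain construction.

Builds single-chain bead coordinates from backbone dihedrals (φ, ψ) with the
canonical bond lengths/angles of the parameter tables, using the standard
natural-extension (NeRF) placement.  Because bond lengths, the trans peptide
plane and the three SC anchor distances are taken from the same table that
defines the bond constraints, any chain produced here satisfies every bonded
constraint exactly and carries L-handed side chains by construction.
"""

from __future__ import annotations

import numpy as np

from ._amino import AA_INDEX
from .params import (
    ANGLE_CA_CO_NH,
    ANGLE_CO_NH_CA,
    ANGLE_NH_CA_CO,
    BOND_CA_CO,
    BOND_CO_NH,
    BOND_NH_CA,
    InteractionTable,
)

EXTENDED_PHI_PSI = (-135.0, 135.0)
HELIX_PHI_PSI = (-57.0, -47.0)

# (phi mean, phi sd, psi mean, psi sd, weight) basins for random coils
_COIL_BASINS = np.array([
    [-135.0, 25.0, 135.0, 25.0, 0.45],
    [-75.0, 15.0, 150.0, 15.0, 0.25],
    [-60.0, 15.0, -45.0, 15.0, 0.30],
])


def _place(a: np.ndarray, b: np.ndarray, c: np.ndarray,
           bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position of atom D bonded to C with angle B-C-D and dihedral A-B-C-D."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array([
        -np.cos(ang),
        np.sin(ang) * np.cos(dih),
        np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def sidechain_position(nh: np.ndarray, ca: np.ndarray, co: np.ndarray,
                       bond: float) -> np.ndarray:
    """L-isomer SC centroid from the residue's backbone frame."""
    u1 = nh - ca
    u1 /= np.linalg.norm(u1)
    u2 = co - ca
    u2 /= np.linalg.norm(u2)
    perp = np.cross(u1, u2)
    perp /= np.linalg.norm(perp)
    direction = -0.536 * u1 - 0.536 * u2 + 0.652 * perp
    direction /= np.linalg.norm(direction)
    return ca + bond * direction


def build_chain(sequence: str, phi: np.ndarray, psi: np.ndarray,
                table: InteractionTable) -> np.ndarray:
    """(R, 4, 3) bead coordinates for one chain with given dihedrals.

    ``phi[0]`` and ``psi[-1]`` are unused (no flanking peptide bond).
    """
    n_res = len(sequence)
    xyz = np.full((n_res, 4, 3), np.nan)
    ang = np.deg2rad(ANGLE_NH_CA_CO)
    nh = np.zeros(3)
    ca = np.array([BOND_NH_CA, 0.0, 0.0])
    co = ca + BOND_CA_CO * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for k, letter in enumerate(sequence):
        if k > 0:
            nh_next = _place(nh, ca, co, BOND_CO_NH, ANGLE_CA_CO_NH,
                             psi[k - 1])
            ca_next = _place(ca, co, nh_next, BOND_NH_CA, ANGLE_CO_NH_CA,
                             180.0)
            co_next = _place(co, nh_next, ca_next, BOND_CA_CO,
                             ANGLE_NH_CA_CO, phi[k])
            nh, ca, co = nh_next, ca_next, co_next
        xyz[k, 0], xyz[k, 1], xyz[k, 2] = nh, ca, co
        if letter != "G":
            xyz[k, 3] = sidechain_position(nh, ca, co,
                                           table.ca_sc[AA_INDEX[letter]])
    return xyz


def uniform_dihedrals(sequence: str,
                      phi_psi: tuple[float, float]) -> tuple[np.ndarray,
                                                             np.ndarray]:
    n = len(sequence)
    return (np.full(n, phi_psi[0]), np.full(n, phi_psi[1]))


def coil_dihedrals(n_res: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sample (φ, ψ) per residue from a three-basin coil distribution."""
    basins = rng.choice(len(_COIL_BASINS), size=n_res,
                        p=_COIL_BASINS[:, 4] / _COIL_BASINS[:, 4].sum())
    b = _COIL_BASINS[basins]
    phi = rng.normal(b[:, 0], b[:, 1])
    psi = rng.normal(b[:, 2], b[:, 3])
    return phi, psi
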