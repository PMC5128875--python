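"""Shared fixtures: compiled systems, engines and a bare two-bead system."""

from __future__ import annotations

import numpy as np
import pytest

import fibrilsim as fs
from fibrilsim.forcefield import CompiledSystem
from fibrilsim.topology import PeptideTopology

INF = np.inf


@pytest.fixture(scope="session")
def table():
    return fs.default_table()


@pytest.fixture(scope="session")
def topo1(table):
    return fs.build_peptide(fs.AB17_42, 1, table)


@pytest.fixture(scope="session")
def system1(table, topo1):
    return fs.compile_system(topo1, table)


@pytest.fixture(scope="session")
def topo3(table):
    return fs.build_peptide(fs.AB17_42, 3, table)


@pytest.fixture(scope="session")
def system3(table, topo3):
    return fs.compile_system(topo3, table)


@pytest.fixture(scope="session")
def topo8(table):
    return fs.build_peptide(fs.AB17_42, 8, table)


@pytest.fixture(scope="session")
def system8(table, topo8):
    return fs.compile_system(topo8, table)


@pytest.fixture(scope="session")
def reference_profiles(table):
    return fs.reference_library(table)


def make_pair_system(table, core: float = 4.0, outer: float = 6.0,
                     depth: float = 1.0) -> CompiledSystem:
    """A bare two-bead square-well system (no bonds, no hydrogen bonds)."""
    topo = PeptideTopology(
        sequence="A", n_chains=2, first_residue=1,
        kind=np.array([3, 3], dtype=np.int8),
        aa=np.array([0, 0], dtype=np.int8),
        chain=np.array([0, 1], dtype=np.int32),
        resnum=np.array([1, 1], dtype=np.int32),
        bonds=np.empty((0, 2), dtype=np.int32),
        bond_lengths=np.empty(0),
        bond_tolerance=table.bond_tolerance,
        bead_index={(0, 1, 3): 0, (1, 1, 3): 1},
    )
    type_nd = np.array([0, 2], dtype=np.int8)
    type_radii = np.array([[0.0, 0.0, 0.0], [core, outer, 0.0]])
    type_level = np.array([[0.0, 0.0, 0.0, 0.0],
                           [INF, -depth, 0.0, 0.0]])
    return CompiledSystem(
        topology=topo, table=table,
        ptype=np.array([[0, 1], [1, 0]], dtype=np.int16),
        type_nd=type_nd, type_radii=type_radii, type_level=type_level,
        type_is_hb=np.array([False, False]),
        type_is_bond=np.array([False, False]),
        ca_prev=np.array([0, 1], dtype=np.int32),
        ca_next=np.array([0, 1], dtype=np.int32),
        ca_self=np.array([0, 1], dtype=np.int32),
    )


def total_mechanical_energy(engine, state) -> float:
    """Exact event-loop potential (when available) plus recomputed KE.

    States produced by ``advance`` end exactly on a discontinuity, where a
    geometric energy recomputation is ambiguous by one well depth; the
    loop's own exact bookkeeping avoids that edge.
    """
    pe = state.potential if state.potential is not None \
        else engine.potential_energy(state)
    return pe + 0.5 * float((state.velocities ** 2).sum())
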