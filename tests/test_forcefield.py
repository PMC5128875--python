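"""Topology construction and the discontinuous pair potentials."""

import numpy as np
import pytest

import fibrilsim as fs
from fibrilsim.conformers import ConformerSpec, make_fibril
from fibrilsim.forcefield import (
    compile_system,
    effective_well_depth,
    hb_eligible,
    match_hydrogen_bonds,
    pair_step_potential,
    total_energy,
)
from fibrilsim.topology import KIND_CO, KIND_NH, KIND_SC, build_peptide
from fibrilsim._amino import AA_INDEX


class TestBuildPeptide:
    def test_ab17_42_has_26_residues_and_99_beads(self, topo1):
        assert topo1.n_residues == 26
        # 26 residues x 4 beads minus the 5 glycines without a side chain
        assert topo1.n_beads == 26 * 4 - fs.AB17_42.count("G")
        assert fs.AB17_42.count("G") == 5

    def test_multi_chain_replication(self, table):
        topo = build_peptide(fs.AB17_42, 3, table)
        assert topo.n_beads == 3 * 99
        assert set(topo.chain) == {0, 1, 2}

    def test_glycine_has_no_side_chain_bead(self, topo1):
        gly_res = [17 + k for k, a in enumerate(fs.AB17_42) if a == "G"]
        assert gly_res == [25, 29, 33, 37, 38]
        for r in gly_res:
            assert (0, r, KIND_SC) not in topo1.bead_index

    def test_chirality_quadruples_cover_non_glycines(self, topo1):
        assert len(topo1.chirality_quadruples()) == 26 - 5

    @pytest.mark.parametrize("seq,nc,err", [
        ("", 1, "empty"), ("LVXF", 1, "unknown residue"),
        (fs.AB17_42, 0, "n_chains"),
    ])
    def test_invalid_inputs_rejected(self, seq, nc, err):
        with pytest.raises(ValueError, match=err):
            build_peptide(seq, nc)


class TestPairStepPotential:
    def test_sc_pair_inside_well_sees_minus_depth(self, system1, table):
        # first two side chains on the chain: L17 and V18 (adjacent pair is
        # locally screened, so use L17 / F19 instead)
        i = system1.topology.bead_index[(0, 17, KIND_SC)]
        j = system1.topology.bead_index[(0, 19, KIND_SC)]
        a, b = AA_INDEX["L"], AA_INDEX["F"]
        mid = 0.5 * (table.sc_pair_core()[a, b] + table.sc_well_range[a, b])
        level, radii = pair_step_potential(system1, i, j, mid)
        assert level == pytest.approx(-table.sc_well_depth[a, b])
        assert radii.size == 1

    def test_beyond_all_ranges_is_zero_with_no_discontinuities(self, system1):
        i = system1.topology.bead_index[(0, 17, KIND_SC)]
        j = system1.topology.bead_index[(0, 30, KIND_SC)]
        level, radii = pair_step_potential(system1, i, j, 50.0)
        assert level == 0.0
        assert radii.size == 0

    def test_below_squeeze_distance_is_forbidden(self, system1, table):
        # SC of V18 against the backbone NH of its neighbour L17
        i = system1.topology.bead_index[(0, 18, KIND_SC)]
        j = system1.topology.bead_index[(0, 17, KIND_NH)]
        d = table.squeeze_distance("V", "NH")
        level, _ = pair_step_potential(system1, i, j, 0.5 * d)
        assert np.isinf(level)

    def test_discontinuity_radii_strictly_increase(self, system1):
        radii = system1.type_radii
        nd = system1.type_nd
        for t in range(1, radii.shape[0]):
            r = radii[t, : nd[t]]
            assert (np.diff(r) > 0).all() or nd[t] <= 1


class TestEffectiveWellDepth:
    @pytest.mark.parametrize("kappa", [1.0, 2.0])
    def test_salt_bridge_pair_scales_with_kappa(self, table, kappa):
        import dataclasses
        t = dataclasses.replace(table, salt_bridge_factor=kappa)
        topo = build_peptide(fs.AB17_42, 2, t)
        system = compile_system(topo, t)
        i = topo.bead_index[(0, 23, KIND_SC)]   # D23
        j = topo.bead_index[(1, 28, KIND_SC)]   # K28, other chain
        base = t.sc_well_depth[AA_INDEX["D"], AA_INDEX["K"]]
        assert effective_well_depth(system, i, j) == pytest.approx(
            kappa * base)

    def test_non_salt_bridge_pair_unchanged(self, system1, table):
        i = system1.topology.bead_index[(0, 17, KIND_SC)]  # L17
        j = system1.topology.bead_index[(0, 30, KIND_SC)]  # I30
        base = table.sc_well_depth[AA_INDEX["L"], AA_INDEX["I"]]
        assert effective_well_depth(system1, i, j) == pytest.approx(base)


class TestHydrogenBondRule:
    def _sheet(self, table):
        return make_fibril(ConformerSpec("extended", 2), table)

    def test_cross_chain_parallel_pair_eligible(self, table):
        topo = build_peptide(fs.AB17_42, 2, table)
        system = compile_system(topo, table)
        pos = self._sheet(table).to_flat(topo)
        nh = topo.bead_index[(1, 30, KIND_NH)]
        co = topo.bead_index[(0, 30, KIND_CO)]
        assert hb_eligible(system, pos, nh, co)

    def test_antiparallel_orientation_rejected(self, table):
        topo = build_peptide(fs.AB17_42, 2, table)
        system = compile_system(topo, table)
        struct = self._sheet(table)
        xyz = struct.coords.copy()
        # rotate chain 1 by 180 deg about z through its centroid: strands
        # now run antiparallel but NH/CO bead distances stay comparable
        centre = np.nanmean(xyz[1, :, 1], axis=0)
        rot = np.diag([-1.0, -1.0, 1.0])
        flat = xyz[1].reshape(-1, 3)
        xyz[1] = ((flat - centre) @ rot.T + centre).reshape(xyz[1].shape)
        from fibrilsim.structure import Structure
        pos = Structure(struct.sequence, struct.first_residue,
                        xyz).to_flat(topo)
        nh_beads = [topo.bead_index[(1, r, KIND_NH)] for r in range(18, 42)]
        co_beads = [topo.bead_index[(0, r, KIND_CO)] for r in range(18, 42)]
        hits = [(i, j) for i in nh_beads for j in co_beads
                if np.linalg.norm(pos[i] - pos[j]) <= table.hb_range
                and hb_eligible(system, pos, i, j)]
        assert hits == []

    def test_same_chain_close_sequence_pair_excluded(self, system1):
        topo = system1.topology
        nh = topo.bead_index[(0, 20, KIND_NH)]
        co = topo.bead_index[(0, 22, KIND_CO)]
        assert not system1.type_is_hb[system1.ptype[nh, co]]

    def test_wrong_bead_kinds_raise(self, system1):
        topo = system1.topology
        ca = topo.bead_index[(0, 20, 1)]
        co = topo.bead_index[(0, 30, KIND_CO)]
        pos = np.zeros((topo.n_beads, 3))
        with pytest.raises(ValueError, match="NH bead"):
            hb_eligible(system1, pos, ca, co)

    def test_single_occupancy_blocks_second_bond(self, table):
        topo = build_peptide(fs.AB17_42, 2, table)
        system = compile_system(topo, table)
        pos = self._sheet(table).to_flat(topo)
        nh = topo.bead_index[(1, 30, KIND_NH)]
        co = topo.bead_index[(0, 30, KIND_CO)]
        partner = np.full(topo.n_beads, -1)
        partner[nh] = co
        partner[co] = nh
        assert not hb_eligible(system, pos, nh, co, hb_partner=partner)


class TestTotalEnergy:
    def test_dilute_state_has_zero_energy(self, system1):
        pos = np.zeros((system1.n_beads, 3))
        # place each bead on a sparse grid, far beyond every range
        for b in range(system1.n_beads):
            pos[b] = (100.0 * b, 0.0, 0.0)
        assert total_energy(system1, pos) == 0.0

    def test_single_hydrogen_bond_counts_minus_one(self, system1):
        pos = np.zeros((system1.n_beads, 3))
        for b in range(system1.n_beads):
            pos[b] = (100.0 * b, 0.0, 0.0)
        topo = system1.topology
        nh = topo.bead_index[(0, 20, KIND_NH)]
        co = topo.bead_index[(0, 30, KIND_CO)]
        assert total_energy(system1, pos, hb_pairs=[(nh, co)]) == -1.0

    def test_u_fixture_matches_brute_force_enumeration(self, table, topo8,
                                                       system8):
        """Energy equals an independent O(n^2) pair-by-pair oracle."""
        struct = make_fibril(ConformerSpec("U", 8), table)
        pos = struct.to_flat(topo8)
        hb = match_hydrogen_bonds(system8, pos)
        expected = -len(hb) * table.eps_hb
        for i in range(topo8.n_beads - 1):
            for j in range(i + 1, topo8.n_beads):
                t = system8.ptype[i, j]
                if t == 0 or system8.type_is_hb[t] \
                        or system8.type_is_bond[t]:
                    continue
                r = float(np.linalg.norm(pos[i] - pos[j]))
                level, _ = pair_step_potential(system8, i, j, r)
                assert np.isfinite(level)
                expected += level
        assert total_energy(system8, pos) == pytest.approx(expected,
                                                           abs=1e-9)
        assert expected < 0

    def test_energy_invariant_under_rigid_motion(self, table, topo8,
                                                 system8):
        struct = make_fibril(ConformerSpec("U", 8), table)
        e0 = total_energy(system8, struct.to_flat(topo8))
        ang = 0.8
        rot = np.array([[np.cos(ang), -np.sin(ang), 0],
                        [np.sin(ang), np.cos(ang), 0], [0, 0, 1.0]])
        moved = struct.transformed(rotation=rot,
                                   translation=np.array([11.0, -3.0, 7.0]))
        e1 = total_energy(system8, moved.to_flat(topo8))
        assert abs(e1 - e0) < 1e-9

    def test_kappa_one_and_bias_off_reduce_to_unbiased_table(self, table,
                                                             topo8):
        struct = make_fibril(ConformerSpec("U", 8), table)
        biased_off = compile_system(topo8, table.unbiased())
        import dataclasses
        plain = compile_system(
            topo8, dataclasses.replace(table, salt_bridge_factor=1.0,
                                       parallel_preference=False))
        pos = struct.to_flat(topo8)
        assert total_energy(biased_off, pos) == total_energy(plain, pos)

    def test_hard_core_overlap_raises(self, system1):
        pos = np.zeros((system1.n_beads, 3))
        for b in range(system1.n_beads):
            pos[b] = (100.0 * b, 0.0, 0.0)
        pos[98] = pos[0] + np.array([0.5, 0.0, 0.0])
        with pytest.raises(Exception, match="overlap"):
            total_energy(system1, pos)
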