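"""Distance profiles, Pearson similarity, classification and trajectory tools."""

import numpy as np
import pytest

import fibrilsim as fs
from fibrilsim.conformers import (
    ConformerSpec,
    make_beta_helix,
    make_coil_chains,
    make_fibril,
)
from fibrilsim.metrics import (
    DistanceProfile,
    classify_structure,
    cluster_chains,
    distance_profile,
    frame_average,
    in_register_score,
    pair_index_set,
    pearson_similarity,
    population_heatmap,
    secondary_structure_fractions,
    tail_frames,
)
from fibrilsim.structure import CalphaSet, Structure


class TestPairIndexSet:
    @pytest.mark.parametrize("start,end,msep,count", [
        (17, 40, 5, 190),     # C(24,2) minus near-diagonal pairs
        (17, 42, 5, 231),     # C(26,2) minus near-diagonal pairs
        (1, 5, 5, 0),         # max separation only 4
    ])
    def test_counts_match_enumeration(self, start, end, msep, count):
        pairs = pair_index_set(start, end, msep)
        assert pairs.shape[0] == count
        brute = [(i, j) for i in range(start, end + 1)
                 for j in range(start, end + 1)
                 if j - i >= msep]
        assert len(brute) == count
        if count:
            assert (pairs[:, 1] - pairs[:, 0] >= msep).all()


def _straight_chain_calpha(n_chains=1, spacing=3.8, start=17, n_res=26):
    res = np.arange(start, start + n_res)
    coords = np.zeros((n_chains, n_res, 3))
    for c in range(n_chains):
        coords[c, :, 0] = spacing * np.arange(n_res)
        coords[c, :, 2] = 10.0 * c
    return CalphaSet(res, coords, [str(c) for c in range(n_chains)])


class TestDistanceProfile:
    def test_collinear_chain_distances_scale_with_separation(self):
        prof = distance_profile(_straight_chain_calpha(), 17, 42, 5)
        expect = 3.8 * (prof.pairs[:, 1] - prof.pairs[:, 0])
        assert prof.values == pytest.approx(expect)

    def test_translated_copies_average_to_single_chain_profile(self):
        one = distance_profile(_straight_chain_calpha(1), 17, 42)
        two = distance_profile(_straight_chain_calpha(2), 17, 42)
        assert two.values == pytest.approx(one.values)

    def test_matches_brute_force_double_loop(self, table, topo8):
        struct = make_fibril(ConformerSpec("S2", 8, jitter=1.0, seed=3),
                             table)
        prof = distance_profile(struct, 17, 42, 5)
        cal = struct.calpha()
        for k in range(0, prof.pairs.shape[0], 17):
            i, j = prof.pairs[k]
            vals = [np.linalg.norm(cal.coords[c, i - 17] -
                                   cal.coords[c, j - 17])
                    for c in range(8)]
            assert prof.values[k] == pytest.approx(np.mean(vals), abs=1e-12)

    def test_missing_residue_named_in_error(self):
        cal = _straight_chain_calpha()
        with pytest.raises(ValueError, match=r"missing residues \[43\]"):
            distance_profile(cal, 17, 43)


class TestPearsonSimilarity:
    def test_self_similarity_is_one(self, reference_profiles):
        u = reference_profiles["U"]
        assert pearson_similarity(u, u).r == pytest.approx(1.0)

    def test_reflection_gives_minus_one(self, reference_profiles):
        u = reference_profiles["U"]
        flipped = DistanceProfile(u.start, u.end, u.min_separation,
                                  u.pairs, 2 * u.values.mean() - u.values)
        assert pearson_similarity(u, flipped).r == pytest.approx(-1.0)

    def test_three_point_hand_example(self):
        pairs = np.array([[1, 6], [1, 7], [1, 8]])
        a = DistanceProfile(1, 8, 5, pairs, np.array([1.0, 2.0, 4.0]))
        b = DistanceProfile(1, 8, 5, pairs, np.array([1.0, 3.0, 3.0]))
        # cov = 8/3, var_a = 14/3, var_b = 8/3 -> r = 8/sqrt(14*8) ~ 0.756
        assert pearson_similarity(a, b).r == pytest.approx(0.7559, abs=2e-4)

    def test_symmetry_exact(self, reference_profiles):
        a, b = reference_profiles["U"], reference_profiles["S1"]
        assert pearson_similarity(a, b).r == pearson_similarity(b, a).r

    def test_rigid_motion_invariance_to_1e12(self, table, topo8):
        struct = make_fibril(ConformerSpec("U", 8, jitter=0.7, seed=1),
                             table)
        ref = distance_profile(struct, 17, 42)
        ang = 1.1
        rot = np.array([[1, 0, 0],
                        [0, np.cos(ang), -np.sin(ang)],
                        [0, np.sin(ang), np.cos(ang)]])
        moved = struct.transformed(rotation=rot, translation=-55.0)
        r = pearson_similarity(ref, distance_profile(moved, 17, 42)).r
        assert abs(r - 1.0) < 1e-12

    def test_zero_variance_raises_not_zero(self):
        pairs = np.array([[1, 6], [1, 7], [1, 8]])
        a = DistanceProfile(1, 8, 5, pairs, np.array([2.0, 2.0, 2.0]))
        b = DistanceProfile(1, 8, 5, pairs, np.array([1.0, 3.0, 3.0]))
        with pytest.raises(ValueError, match="zero variance"):
            pearson_similarity(a, b)

    def test_mismatched_pair_lists_rejected(self, reference_profiles):
        u = reference_profiles["U"]
        short = DistanceProfile(17, 40, 5, pair_index_set(17, 40, 5),
                                np.ones(190))
        with pytest.raises(ValueError, match="pair lists"):
            pearson_similarity(u, short)

    def test_noise_degrades_similarity_monotonically(self, table):
        """Mean r against the clean profile decreases with jitter."""
        clean = make_fibril(ConformerSpec("U", 4), table)
        ref = distance_profile(clean, 17, 42)
        means = []
        for amp in (0.5, 1.0, 2.0, 4.0):
            rs = []
            for seed in range(100):
                noisy = make_fibril(
                    ConformerSpec("U", 4, jitter=amp, seed=seed), table)
                rs.append(pearson_similarity(
                    ref, distance_profile(noisy, 17, 42)).r)
            means.append(np.mean(rs))
        assert all(a > b for a, b in zip(means, means[1:]))


class TestClusterChains:
    def test_no_contacts_gives_singletons(self, table):
        s = make_coil_chains(4, seed=0, table=table, separation=80.0)
        comps = cluster_chains(s, cutoff=7.5)
        assert sorted(len(c) for c in comps) == [1, 1, 1, 1]

    def test_transitive_chain_contact(self, table):
        u = make_fibril(ConformerSpec("U", 3), table)      # A-B-C stacked
        lone = make_fibril(ConformerSpec("U", 1), table)
        s = u.concat(lone, offset=np.array([90.0, 0.0, 0.0]))
        comps = cluster_chains(s, cutoff=7.5)
        assert [len(c) for c in comps] == [3, 1]
        assert comps[0] == [0, 1, 2]

    def test_matches_reference_graph_search(self, table, system8):
        struct = make_fibril(ConformerSpec("U", 8, jitter=6.0, seed=2),
                             table)
        comps = cluster_chains(struct, system8)
        # oracle: independent adjacency + BFS over the same contact rule
        cutoff = system8.max_range()
        nc = struct.n_chains
        adj = np.zeros((nc, nc), dtype=bool)
        for a in range(nc):
            for b in range(a + 1, nc):
                pa = struct.coords[a].reshape(-1, 3)
                pb = struct.coords[b].reshape(-1, 3)
                pa = pa[np.isfinite(pa[:, 0])]
                pb = pb[np.isfinite(pb[:, 0])]
                d = np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)
                adj[a, b] = adj[b, a] = (d < cutoff).sum() >= 3
        import collections
        seen, comps2 = set(), []
        for s0 in range(nc):
            if s0 in seen:
                continue
            q = collections.deque([s0])
            seen.add(s0)
            comp = []
            while q:
                u = q.popleft()
                comp.append(u)
                for v in np.nonzero(adj[u])[0]:
                    if v not in seen:
                        seen.add(int(v))
                        q.append(int(v))
            comps2.append(sorted(comp))
        comps2.sort(key=len, reverse=True)
        assert comps == comps2


class TestInRegister:
    def test_perfect_fixture_scores_one(self, table, system8):
        u = make_fibril(ConformerSpec("U", 8), table)
        assert in_register_score(u, system8) == 1.0

    def test_register_shift_scores_zero(self, table, topo3, system3):
        u = make_fibril(ConformerSpec("U", 3), table)
        xyz = u.coords.copy()
        for c in range(3):
            xyz[c, :, :, 1] += 3.8 * c   # slide each chain one step along y
        shifted = Structure(u.sequence, u.first_residue, xyz)
        assert in_register_score(shifted, system3) == 0.0

    def test_no_interchain_bonds_is_flagged_undefined(self, table, system3):
        s = make_coil_chains(3, seed=1, table=table, separation=90.0)
        assert in_register_score(s, system3) is None


class TestSecondaryStructure:
    def test_parallel_sheet_is_mostly_strand(self, table):
        topo = fs.build_peptide(fs.AB17_42, 2, table)
        system = fs.compile_system(topo, table)
        sheet = make_fibril(ConformerSpec("extended", 2), table)
        frac = secondary_structure_fractions(sheet, system)
        assert frac["strand"] >= 0.9
        assert sum(frac.values()) == pytest.approx(1.0)

    def test_helical_chain_is_mostly_helix(self, table, system1):
        from fibrilsim._chain_geometry import build_chain, HELIX_PHI_PSI
        xyz = build_chain(fs.AB17_42, np.full(26, HELIX_PHI_PSI[0]),
                          np.full(26, HELIX_PHI_PSI[1]), table)
        helix = Structure(fs.AB17_42, 17, xyz[None])
        frac = secondary_structure_fractions(helix, system1)
        assert frac["helix"] >= 0.9

    def test_isolated_extended_chain_has_no_strand_without_bonds(
            self, table, system1):
        one = make_fibril(ConformerSpec("extended", 1), table)
        frac = secondary_structure_fractions(one, system1)
        assert frac["strand"] == 0.0
        assert frac["coil"] == pytest.approx(1.0 - frac["helix"])


class TestClassification:
    def test_u_fixture_recovered_in_register(self, table, system8,
                                             reference_profiles):
        u = make_fibril(ConformerSpec("U", 8), table)
        label = classify_structure(u, reference_profiles, system8)
        assert label.label == "U"
        assert label.in_register is True
        assert label.scores["U"] > 0.95

    def test_separated_coils_are_monomer_small_oligomer(
            self, table, system3, reference_profiles):
        s = make_coil_chains(3, seed=4, table=table, separation=90.0)
        label = classify_structure(s, reference_profiles, system3)
        assert label.label == "monomer_small_oligomer"

    def test_u_plus_bh_contact_aggregate_is_hybrid(self, table,
                                                   reference_profiles):
        u4 = make_fibril(ConformerSpec("U", 4), table)
        bh3 = make_beta_helix(3, table)
        comp = u4.concat(bh3, offset=np.array([22.0, 10.0, 2.0]))
        topo = fs.build_peptide(fs.AB17_42, 7, table)
        system = fs.compile_system(topo, table)
        label = classify_structure(comp, reference_profiles, system)
        assert label.label == "hybrid"
        assert label.cluster_sizes[0] == 7

    def test_empty_reference_library_rejected(self, table, system3):
        u = make_fibril(ConformerSpec("U", 3), table)
        with pytest.raises(ValueError, match="reference library"):
            classify_structure(u, {}, system3)


class TestPopulationHeatmap:
    def test_identical_frames_occupy_single_bin_with_density_one(
            self, table, reference_profiles):
        u = make_fibril(ConformerSpec("U", 4), table)
        traj = [[(u, -50.0)] * 10]
        h, _, _ = population_heatmap(traj, reference_profiles["U"],
                                     tail_fraction=0.3)
        assert h.sum() == pytest.approx(1.0)
        assert (h > 0).sum() == 1
        assert h.max() == pytest.approx(1.0)

    def test_tail_selection_takes_last_three_of_ten(self):
        assert tail_frames(10, 0.30).tolist() == [7, 8, 9]

    def test_two_population_mixture_recovers_weights(self, table,
                                                     reference_profiles):
        u = make_fibril(ConformerSpec("U", 4), table)
        s1 = make_fibril(ConformerSpec("S1", 4), table)
        frames = [(u, -200.0)] * 7 + [(s1, -100.0)] * 3
        h, r_edges, e_edges = population_heatmap(
            [frames], reference_profiles["U"], tail_fraction=1.0)
        assert h.sum() == pytest.approx(1.0)
        # mass near r=1 (U matches its reference) should be 0.7
        hi = h[r_edges[:-1] >= 0.9, :].sum()
        assert hi == pytest.approx(0.7)

    def test_empty_selection_raises(self, reference_profiles):
        with pytest.raises(ValueError):
            population_heatmap([[]], reference_profiles["U"])


class TestFrameAverage:
    def test_identical_frames_average_to_themselves(self, table):
        u = make_fibril(ConformerSpec("U", 3), table)
        out = frame_average([u, u, u])
        mask = np.isfinite(u.coords)
        assert out.coords[mask] == pytest.approx(u.coords[mask])

    def test_rigid_rotations_removed_by_superposition(self, table):
        u = make_fibril(ConformerSpec("U", 3), table)
        frames = [u]
        rng = np.random.default_rng(2)
        for _ in range(4):
            q = rng.normal(size=4)
            q /= np.linalg.norm(q)
            w, x, y, z = q
            rot = np.array([
                [1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                 2 * (x * z + w * y)],
                [2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                 2 * (y * z - w * x)],
                [2 * (x * z - w * y), 2 * (y * z + w * x),
                 1 - 2 * (x * x + y * y)]])
            frames.append(u.transformed(rotation=rot,
                                        translation=rng.normal(0, 20, 3)))
        out = frame_average(frames)
        mask = np.isfinite(u.coords)
        assert np.abs(out.coords[mask] - u.coords[mask]).max() < 1e-6

    def test_noise_residual_shrinks_with_frame_count(self, table):
        from fibrilsim.conformers import perturb
        u = make_fibril(ConformerSpec("U", 3), table)
        mask = np.isfinite(u.coords[..., 0])

        def residual(n_frames, seed0):
            frames = [perturb(u, 0.5, seed=seed0 + k)
                      for k in range(n_frames)]
            out = frame_average(frames)
            return np.sqrt(np.nanmean(
                ((out.coords - u.coords)[mask] ** 2)))

        r2 = np.mean([residual(2, 100 * s) for s in range(6)])
        r8 = np.mean([residual(8, 100 * s) for s in range(6)])
        assert r8 < r2 / 1.5   # ~ 1/sqrt(n) shrinkage

    def test_mismatched_topologies_rejected(self, table):
        u3 = make_fibril(ConformerSpec("U", 3), table)
        u4 = make_fibril(ConformerSpec("U", 4), table)
        with pytest.raises(ValueError, match="mismatched"):
            frame_average([u3, u4])
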