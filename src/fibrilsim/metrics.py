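"""Structure analysis: distance profiles, similarity, classification.

The similarity statistic works on the *intra-peptide* state: for every pair
of Cα atoms on the same chain separated by at least ``min_separation``
residues along the sequence, the pair distance is averaged over all chains
of the structure; two such profiles (simulated vs reference) are compared
through the Pearson correlation coefficient r.  Because only internal
distances enter, the measure is invariant to rigid motion of either
structure and insensitive to how chains are stacked — it asks whether the
peptide fold (U, serpentine S, β-helix loop, ...) matches, not whether the
aggregates superimpose.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .forcefield import CompiledSystem, match_hydrogen_bonds
from .structure import CalphaSet, Structure
from .topology import KIND_CA, KIND_CO, KIND_NH

FIBRIL_THRESHOLD = 0.8      # "red region" similarity boundary
IN_REGISTER_THRESHOLD = 0.9
SMALL_OLIGOMER_CUTOFF = 3   # largest cluster below this => monomer/small olig.
MIN_SUBAGGREGATE = 3        # chains needed for a sub-aggregate class vote


@dataclasses.dataclass
class DistanceProfile:
    """Chain-averaged intra-peptide Cα distance dataset."""

    start: int
    end: int
    min_separation: int
    pairs: np.ndarray          # (P, 2) residue numbers i < j
    values: np.ndarray         # (P,) Å

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.pairs.shape[0] != self.values.shape[0]:
            raise ValueError("pair list and values disagree in length")

    def compatible(self, other: "DistanceProfile") -> bool:
        return (self.pairs.shape == other.pairs.shape and
                bool((self.pairs == other.pairs).all()))


@dataclasses.dataclass
class SimilarityScore:
    r: float
    reference_id: str
    start: int
    end: int


@dataclasses.dataclass
class StructureLabel:
    """Polymorph assignment for one aggregate or whole system."""

    label: str                       # U/S1/S2/S3/D1/D2/BH/hybrid/disordered/
    #                                  monomer_small_oligomer
    in_register: bool | None
    scores: dict[str, float]         # best r per reference class
    energy: float | None = None
    cluster_sizes: tuple[int, ...] = ()


def pair_index_set(start: int, end: int,
                   min_separation: int = 5) -> np.ndarray:
    """Ordered (i, j) residue pairs with i < j and j - i >= min_separation.

    The default of 5 encodes "separated by more than 4 residues along the
    sequence".
    """
    if end < start:
        raise ValueError("end must be >= start")
    pairs = [(i, j)
             for i in range(start, end + 1)
             for j in range(i + min_separation, end + 1)]
    return np.array(pairs, dtype=int).reshape(-1, 2)


def distance_profile(calpha: CalphaSet | Structure, start: int, end: int,
                     min_separation: int = 5) -> DistanceProfile:
    """Chain-averaged intra-peptide Cα distances over [start, end]."""
    if isinstance(calpha, Structure):
        calpha = calpha.calpha()
    sub = calpha.restrict(start, end)
    pairs = pair_index_set(start, end, min_separation)
    ii = pairs[:, 0] - start
    jj = pairs[:, 1] - start
    d = np.linalg.norm(sub.coords[:, ii] - sub.coords[:, jj], axis=2)
    return DistanceProfile(start, end, min_separation, pairs, d.mean(axis=0))


def pearson_similarity(a: DistanceProfile, b: DistanceProfile,
                       reference_id: str = "") -> SimilarityScore:
    """Pearson r between two matching profiles: cov(a,b)/(sd(a)·sd(b))."""
    if not a.compatible(b):
        raise ValueError("profiles have different pair lists")
    if a.values.size < 3:
        raise ValueError("need at least 3 pairs for a similarity score")
    x = a.values - a.values.mean()
    y = b.values - b.values.mean()
    vx = float(x @ x)
    vy = float(y @ y)
    if vx == 0.0 or vy == 0.0:
        raise ValueError("zero variance: similarity undefined")
    r = float(x @ y / np.sqrt(vx * vy))
    return SimilarityScore(r, reference_id, a.start, a.end)


# ---------------------------------------------------------------------------
# aggregation graph


def cluster_chains(structure: Structure, system: CompiledSystem | None = None,
                   cutoff: float | None = None,
                   min_contacts: int = 3) -> list[list[int]]:
    """Connected components of the chain-contact graph, sizes descending.

    Two chains are in contact when at least *min_contacts* inter-chain bead
    pairs fall within interaction range (a fixed *cutoff* in Å, or each
    pair's own well range when a compiled *system* is given).
    """
    nc = structure.n_chains
    flat = [structure.coords[c].reshape(-1, 3) for c in range(nc)]
    finite = [np.isfinite(f[:, 0]) for f in flat]
    adj = [[] for _ in range(nc)]
    if cutoff is None:
        cutoff = system.max_range() if system is not None else 7.5
    for a in range(nc):
        pa = flat[a][finite[a]]
        for b in range(a + 1, nc):
            pb = flat[b][finite[b]]
            d = np.linalg.norm(pa[:, None] - pb[None, :], axis=-1)
            if int((d < cutoff).sum()) >= min_contacts:
                adj[a].append(b)
                adj[b].append(a)
    seen = [False] * nc
    comps = []
    for a in range(nc):
        if seen[a]:
            continue
        stack, comp = [a], []
        seen[a] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
        comps.append(sorted(comp))
    comps.sort(key=len, reverse=True)
    return comps


# ---------------------------------------------------------------------------
# hydrogen-bond register


def _backbone_hb_pairs(structure: Structure, system: CompiledSystem
                       ) -> list[tuple[int, int, int, int]]:
    """Inter/intra-chain HBs as (chain_nh, res_nh, chain_co, res_co)."""
    pos = structure.to_flat(system.topology)
    topo = system.topology
    out = []
    for i, j in match_hydrogen_bonds(system, pos):
        nh, co = (i, j) if topo.kind[i] == KIND_NH else (j, i)
        out.append((int(topo.chain[nh]), int(topo.resnum[nh]),
                    int(topo.chain[co]), int(topo.resnum[co])))
    return out


def in_register_score(structure: Structure,
                      system: CompiledSystem) -> float | None:
    """Fraction of inter-chain backbone HBs joining identical residues.

    Returns ``None`` (undefined, flagged) when the structure has no
    inter-chain hydrogen bonds at all.
    """
    inter = [(rn, rc) for cn, rn, cc, rc in
             _backbone_hb_pairs(structure, system) if cn != cc]
    if not inter:
        return None
    hits = sum(1 for rn, rc in inter if rn == rc)
    return hits / len(inter)


# ---------------------------------------------------------------------------
# secondary structure


def _virtual_dihedrals(ca: np.ndarray) -> np.ndarray:
    """Cα virtual dihedral per residue (i-1, i, i+1, i+2); NaN at termini."""
    n = ca.shape[0]
    out = np.full(n, np.nan)
    for i in range(1, n - 2):
        b1 = ca[i] - ca[i - 1]
        b2 = ca[i + 1] - ca[i]
        b3 = ca[i + 2] - ca[i + 1]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        x = float(n1 @ n2)
        y = float(m1 @ n2)
        out[i] = np.degrees(np.arctan2(y, x))
    return out


def secondary_structure_fractions(structure: Structure,
                                  system: CompiledSystem) -> dict[str, float]:
    """Fractions of residues in α-helix, β-strand and coil/turn.

    Assignment convention for the bead model: a residue is *strand* when its
    Cα virtual dihedral is extended (|θ| > 120°) and its NH or CO engages a
    backbone hydrogen bond; *helix* when the dihedral sits in the
    right-handed helical band (-100°..-30° under this dihedral sign
    convention).  Otherwise coil/turn.  Terminal residues inherit the
    nearest interior dihedral; chains shorter than the four-Cα window are
    entirely coil.  Fractions sum to 1.
    """
    hbs = _backbone_hb_pairs(structure, system)
    bonded: set[tuple[int, int]] = set()
    for cn, rn, cc, rc in hbs:
        bonded.add((cn, rn))
        bonded.add((cc, rc))
    counts = {"helix": 0, "strand": 0, "coil": 0}
    ca = structure.coords[:, :, KIND_CA]
    first = structure.first_residue
    for c in range(structure.n_chains):
        theta = _virtual_dihedrals(ca[c])
        good = np.nonzero(~np.isnan(theta))[0]
        if good.size:
            theta[: good[0]] = theta[good[0]]
            theta[good[-1]:] = theta[good[-1]]
        for k in range(structure.n_residues):
            th = theta[k]
            if np.isnan(th):
                counts["coil"] += 1
            elif -100.0 < th < -30.0:
                counts["helix"] += 1
            elif abs(th) > 120.0 and (c, first + k) in bonded:
                counts["strand"] += 1
            else:
                counts["coil"] += 1
    total = structure.n_chains * structure.n_residues
    return {k: v / total for k, v in counts.items()}


# ---------------------------------------------------------------------------
# classification


def _best_scores(profile: DistanceProfile,
                 reference_library: dict) -> dict[str, float]:
    out = {}
    for name, ref in reference_library.items():
        out[name] = pearson_similarity(profile, ref, name).r
    return out


def classify_structure(structure: Structure,
                       reference_library: dict,
                       system: CompiledSystem,
                       energy: float | None = None,
                       fibril_threshold: float = FIBRIL_THRESHOLD,
                       in_register_threshold: float = IN_REGISTER_THRESHOLD,
                       small_cutoff: int = SMALL_OLIGOMER_CUTOFF,
                       ) -> StructureLabel:
    """Assign a polymorph class to the largest aggregate of a structure.

    Rules: below the size cutoff the system is "monomer_small_oligomer"; a
    cluster whose chains split across two or more reference classes (each
    claiming >= 3 chains) is "hybrid"; otherwise the best-matching reference
    above the fibril threshold names the class, and anything else is
    "disordered".  The in-register flag comes from the inter-chain HB
    register of the whole structure.
    """
    if not reference_library:
        raise ValueError("reference library is empty")
    any_ref = next(iter(reference_library.values()))
    start, end, msep = any_ref.start, any_ref.end, any_ref.min_separation

    clusters = cluster_chains(structure, system)
    sizes = tuple(len(c) for c in clusters)
    try:
        reg = in_register_score(structure, system)
    except ValueError:
        reg = None          # Cα-only input: no NH/CO beads to pair
    in_reg = None if reg is None else bool(reg >= in_register_threshold)

    if not clusters or sizes[0] < small_cutoff:
        return StructureLabel("monomer_small_oligomer", in_reg, {}, energy,
                              sizes)

    main = clusters[0]
    # per-chain votes over the cluster
    votes: dict[str, int] = {}
    for c in main:
        sub = CalphaSet(structure.residue_numbers,
                        structure.coords[c:c + 1, :, KIND_CA], [str(c)])
        prof = distance_profile(sub, start, end, msep)
        scores = _best_scores(prof, reference_library)
        best = max(scores, key=scores.get)
        if scores[best] >= fibril_threshold:
            votes[best] = votes.get(best, 0) + 1
    strong = [k for k, v in votes.items() if v >= MIN_SUBAGGREGATE]
    if len(strong) >= 2:
        mean_prof = distance_profile(
            CalphaSet(structure.residue_numbers,
                      structure.coords[main, :, KIND_CA],
                      [str(c) for c in main]), start, end, msep)
        return StructureLabel("hybrid", in_reg,
                              _best_scores(mean_prof, reference_library),
                              energy, sizes)

    mean_prof = distance_profile(
        CalphaSet(structure.residue_numbers,
                  structure.coords[main, :, KIND_CA],
                  [str(c) for c in main]), start, end, msep)
    scores = _best_scores(mean_prof, reference_library)
    best = max(scores, key=scores.get)
    if scores[best] >= fibril_threshold:
        return StructureLabel(best, in_reg, scores, energy, sizes)
    return StructureLabel("disordered", in_reg, scores, energy, sizes)


# ---------------------------------------------------------------------------
# trajectory-level tools


def population_heatmap(trajectories: list[list[tuple[Structure, float]]],
                       reference: DistanceProfile,
                       tail_fraction: float = 0.30,
                       bins: tuple[int, int] = (40, 40),
                       r_range: tuple[float, float] = (-1.0, 1.0),
                       energy_range: tuple[float, float] | None = None,
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalized (r, energy) population density over late-trajectory frames.

    Each trajectory is a frame list of ``(structure, energy)``; the final
    ``tail_fraction`` of each (by frame index, at least one frame) enters
    the histogram.  Returns ``(density, r_edges, e_edges)`` with
    ``density.sum() == 1``.
    """
    if not 0.0 < tail_fraction <= 1.0:
        raise ValueError("tail_fraction must be in (0, 1]")
    rs, es = [], []
    for frames in trajectories:
        if not frames:
            continue
        k0 = len(frames) - max(1, int(round(tail_fraction * len(frames))))
        for struct, energy in frames[k0:]:
            prof = distance_profile(struct, reference.start, reference.end,
                                    reference.min_separation)
            rs.append(pearson_similarity(prof, reference).r)
            es.append(energy)
    if not rs:
        raise ValueError("no frames selected for the heat map")
    if energy_range is None:
        lo, hi = min(es), max(es)
        pad = 0.5 * max(1e-9, hi - lo) * 0.05 + 1e-6
        energy_range = (lo - pad, hi + pad)
    h, r_edges, e_edges = np.histogram2d(
        rs, es, bins=bins, range=[r_range, energy_range])
    h = h / h.sum()
    return h, r_edges, e_edges


def tail_frames(n_frames: int, tail_fraction: float = 0.30) -> np.ndarray:
    """Indices of the final *tail_fraction* of an n-frame trajectory."""
    if n_frames < 1:
        raise ValueError("empty trajectory")
    k = max(1, int(round(tail_fraction * n_frames)))
    return np.arange(n_frames - k, n_frames)


def _kabsch(p: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation, translation minimizing RMSD mapping q onto p."""
    pc = p.mean(0)
    qc = q.mean(0)
    h = (q - qc).T @ (p - pc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, pc - rot @ qc


def frame_average(frames: list[Structure]) -> Structure:
    """Mean structure after rigid superposition of every frame onto the first.

    The field's convention for presenting simulated fibril snapshots is the
    average over a handful of consecutive frames; superposition removes
    rigid-body drift so the mean reflects internal structure only.
    """
    if not frames:
        raise ValueError("need at least one frame")
    ref = frames[0]
    for f in frames[1:]:
        if (f.sequence != ref.sequence or
                f.coords.shape != ref.coords.shape):
            raise ValueError("frames have mismatched topologies")
    mask = np.isfinite(ref.coords[..., 0])
    p = ref.coords[mask]
    acc = p.copy()
    for f in frames[1:]:
        q = f.coords[mask]
        rot, trans = _kabsch(p, q)
        acc += q @ rot.T + trans
    acc /= len(frames)
    xyz = np.full_like(ref.coords, np.nan)
    xyz[mask] = acc
    return Structure(ref.sequence, ref.first_residue, xyz)
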