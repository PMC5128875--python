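# Methods

## Model

`fibrilsim` implements a four-bead-per-residue discontinuous force field for
peptide aggregation. Each residue carries three backbone united atoms — NH,
Cα (CA) and CO — and one side-chain centroid (SC); glycine has no SC bead.
All interactions are piecewise constant in the pair distance:

* **Bonds and pseudo-bonds** are hard walls at `l·(1 ± δ)`. Covalent bonds
  (NH–CA, CA–CO, CO–NH′) fix the backbone connectivity; pseudo-bonds
  (NH–CO, CA–NH′, CO–CA′, CA–CA′ and the three SC anchors NH–SC, CA–SC,
  CO–SC) fix the backbone angles, the trans peptide plane and the
  side-chain position, leaving φ and ψ as the soft degrees of freedom.
* **Hard cores** act between all non-bonded beads. A side chain against the
  backbone of its sequence neighbours sees a reduced core (the *squeeze*
  distance, `squeeze_factor ×` the mean diameter); near-neighbour backbone
  pairs that are not bonded see a locally reduced core
  (`local_backbone_factor`). Both factors were chosen so that the standard
  extended / polyproline-II / right-handed-helical dihedral basins are
  sterically allowed (the scan is reproducible from
  `_chain_geometry.coil_dihedrals` and the default table): squeeze 0.70 and
  local factor 0.65 leave ≥ 0.1 Å clearance at the 3-σ edges of the basins.
* **Side-chain square wells**: a 20×20 matrix of (depth, range). Shipped
  depths follow residue-class rules (hydrophobic–hydrophobic 0.20 ε_HB,
  opposite charges 0.30, like charges repulsive −0.15, polar pairs 0.10);
  ranges are 1.55 × the pair core. These are stand-in defaults in the
  conventions of published four-bead square-well force fields, not fitted
  values; everything is configurable through `wells.yaml`.
* **Hydrogen bonds** are square wells of depth ε_HB ≡ 1 (the energy unit)
  between NH and CO beads, gated at formation by (i) single occupancy per
  NH and per CO, (ii) a same-chain sequence exclusion (|Δres| ≥ 4), (iii)
  auxiliary distance windows between each partner and the other partner's
  Cα (3.0–6.8 Å, keeping the bond roughly linear), and (iv) when the
  *parallel preference* bias is on, an orientation gate requiring the two
  local strand directions (CA(i−1)→CA(i+1)) to be within 90° of parallel.
  An escape attempt with insufficient radial kinetic energy reflects
  ("bounce") and the bond survives.
* **Enhanced salt bridge**: the SC–SC well between residues D23 and K28 (on
  any chain pair) is deepened by a factor κ (default 2). κ = 1 and the
  parallel flag off reproduce the unbiased model bit-for-bit.

Reduced units: ε_HB = k_B = m_bead = 1, lengths in Å; T* = k_B T/ε_HB and
the time unit is τ = Å·(m/ε_HB)^1/2.

### L-isomer preservation and the bond tolerance

Handedness of every side chain is encoded purely geometrically: the three
SC anchor distances admit two mirror solutions, and flipping between them
requires the NH/CA/CO/SC tetrahedron to pass through a flat (coplanar)
configuration. Whether that flat configuration is reachable *inside* the
bond tolerance bands is a property of δ: a trilateration analysis (minimum
in-band SC height above the backbone plane) shows that at δ = 2.5% the
height reaches zero for every residue type — so chirality could flip
without any wall crossing — while at the shipped default δ = 1.5% the
minimum in-band height stays above 1.0 Å for all twenty residues, making a
flip geometrically impossible along any valid trajectory. The engine test
suite verifies sign preservation directly on thermostatted runs.

## Event-driven dynamics

Between events beads move ballistically. The engine predicts the smallest
positive root of |Δr + Δv·t| = R under the minimum-image convention for
each pair discontinuity and resolves events with exact impulses: hard
reflections for cores and bond walls; for finite steps ΔU the radial
relative velocity u is mapped to sign(u)·√(u² − 2ΔU/μ) when the radial
kinetic energy suffices (μ = reduced mass), otherwise the pair bounces.
Momentum is conserved identically and total energy to floating-point
round-off (the conservation audit bounds |ΔE| by 10⁻⁸ ε_HB over 10⁶
events).

Scheduling uses a binary-heap calendar with lazy invalidation: each bead
keeps its earliest predicted event; per-bead event counters mark stale
entries, and a stale pop re-schedules any bead whose counter still matches
(the other bead was already rescheduled at its own event). Candidate pairs
come from a Verlet neighbour list built over per-type interaction ranges
plus a skin (default 1.5 Å) and rebuilt whenever `v_max · (t − t_built)`
reaches half the skin — a conservative horizon that makes missed events
impossible. Correctness, not speed, is the contract: the list reproduces
all-pairs predictions exactly on small systems.

The thermostat is Andersen-style: at exponentially distributed ghost times
a uniformly chosen bead's velocity is resampled from the Maxwell–Boltzmann
distribution at the current target temperature. The target follows the
temperature schedule by collision count, which implements the
alternating-temperature protocol (switch every `half_cycle` collisions; 5
billion at full scale, desk-scale values in tests). Everything is
deterministic under a fixed seed.

Ghost-kick rates are context-dependent by design: calibration runs use
1–2 kicks per bead per τ (fast velocity equilibration), while the dilute
aggregation demonstration uses 0.02 per bead per τ so that chain transport
at 1 mM stays near-ballistic — a strongly coupled Andersen thermostat would
suppress centre-of-mass diffusion and make encounters in a ~171 Å box
unrealistically slow.

## Analysis layer

The similarity statistic is computed on the *intra-peptide* state: all
Cα–Cα distances within a chain for residue pairs separated by at least 5
positions (`j − i ≥ 5`, i.e. "more than 4"), averaged over all chains, form
a profile; two profiles over the same residue range are compared with the
Pearson correlation coefficient r. The residue range is 17–42 for Aβ42-type
references and 17–40 for Aβ40-type ones (190 and 231 pairs respectively).
Classification assigns the best-matching reference class when max r ≥ 0.8
(the heat-map "red region" boundary), with BH matched by its own reference;
aggregates whose chains split across ≥ 2 classes with ≥ 3 chains each are
*hybrid*; systems whose largest contact cluster has < 3 chains are
*monomer/small oligomer*; everything else is *disordered*. The in-register
score is the fraction of inter-chain backbone hydrogen bonds joining equal
residue indices (threshold 0.9 for the in-register flag). Chain clustering
is by connected components over a bead-contact graph (≥ 3 inter-chain bead
pairs within interaction range).

Secondary structure uses a documented bead-model convention (no atomistic
assignment exists for this representation): a residue is *strand* when its
Cα virtual dihedral is extended (|θ| > 120°) and it takes part in a
backbone hydrogen bond, *helix* when the dihedral falls in the right-handed
helical band (−100°…−30° under the builder's sign convention), otherwise
coil/turn; termini inherit the nearest interior dihedral. Its acceptance is
internal consistency on ideal fixtures, not agreement with experimental
percentages.

Population heat maps select the final 30% of frames of each trajectory,
score each frame against a reference profile, and bin (r, total energy)
into a density normalized to 1. Frame averaging superposes each frame onto
the first (Kabsch) before taking per-bead means, the convention used for
presenting simulated fibril snapshots.

## Synthetic conformers

Fibril templates are built from a planar Cα path — straight β-strands at
3.8 Å spacing joined by semicircular turns whose width follows from keeping
the spacing on the arc — stacked in register with a 4.85 Å rise, a 0.35 Å
pleat, NH/CO beads offset so the inter-chain i-to-i hydrogen-bond ladder
forms, and side chains alternating across the sheet. The U-shape places its
turn at residues 24–27, which mirror-pairs D23 with K28 and F19 with I32
across the strands: the salt bridge falls inside its (enhanced) well and
the hydrophobic contact inside its well on every chain — the defining
contact motif of the U-fold. S-variants are three-strand serpentines with
distinct turn placements (S1: 24/34, S2: 22/31, S3: 26/35); D1/D2 are
schematic alternative topologies (turns at 21 and 28) that exist to
exercise multi-class classification, not as structural claims. The β-helix
(BH) winds each chain into one turn of a wide solenoid (one empty lattice
slot per turn keeps chain junctions clash-free), so hydrogen bonding is
dominated by inter-chain ladder contacts. A committed regression test pins
the pairwise r between all class templates below the 0.8 threshold.

Random coils are built in internal coordinates (NeRF) with φ/ψ drawn from a
three-basin coil distribution and rejection-sampled against all hard cores,
so every generated chain is a valid dynamical state. Dilute boxes place
coils at random positions/orientations with all inter-chain bead pairs
beyond the largest interaction range; velocities are Maxwell–Boltzmann at
the schedule's first temperature. The box edge is L = (NC/(c·N_A))^1/3
(237 Å for 8 chains at 1 mM).

### What the generator does and does not emulate

The templates are idealized: perfectly in-register, jitter-controlled, and
built from the package's own geometry conventions rather than experimental
coordinates (user-supplied PDB references are read through the normal
reader). Passing the classification and similarity suites therefore shows
the *statistic and decision rules* behave correctly on structures with the
stated geometric properties; it does not validate the force field against
experimental fibril structures, and the D-variants in particular make no
claim of geometric fidelity.

## Problem sizes

Tests and the acceptance script run desk-scale versions of the full-scale
protocol: single chains or 2–3 chains, 10⁵–10⁷ events per run, and a
three-chain aggregation demonstration at 1 mM integrated to t* = 1.2×10⁴ τ
per run (a few × 10⁷ events), three seeds averaged, with a hot control at
T* = 0.5. The demonstration's conditions follow its transport physics: at
1 mM the encounter of three chains is diffusion-limited with a ~2×10⁴ τ
scale, and a strongly coupled Andersen thermostat suppresses centre-of-mass
motion (measured chain displacements drop from ~100 Å to ~25 Å per 2000 τ
when the kick rate rises from 0.005 to 0.02 per bead per τ), so the demo
uses the weak coupling; the quench T* = 0.14 binds chains on contact while
leaving enough NH/CO donors uncommitted for inter-chain hydrogen bonds.
These sizes were chosen so the whole suite completes on one core in
minutes while the demonstrated effects (conservation, canonical statistics,
plateaus, aggregation onset) are statistically resolved; full-scale runs
(10⁹–10¹¹ collisions, 8–12 chains) use the same code paths with larger
budgets.

## Known limitations

* Default geometry/well numbers are conventions, not the (unpublished)
  revised parameter set of the model family; quantitative populations of
  polymorphs are outside the desk-scale scope.
* The hydrogen-bond auxiliary criteria are distance windows at formation
  only; no angular well-locking of neighbours is applied after formation.
* The engine is serial; no domain decomposition or pressure coupling.
* The aggregation demonstration is qualitative: at 1 mM the encounter time
  of three chains is diffusion-limited and stochastic, so observables are
  averaged over seeds and compared against a hot control rather than
  against quantitative rates.
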