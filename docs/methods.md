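# Methods

This note documents the models, estimators, numerical choices and known
limitations of `icebound`. Everything stated here is computed by the test
suite or by `scripts/acceptance.py`; no empirical claims beyond those
computations are made.

## Scope and assumptions

The package analyses *crystallographically resolved* hydration water on
antifreeze-protein ice-binding sites (IBS). Waters are represented by
their oxygen positions only: deposited structures do not resolve water
hydrogens, so no statistic here depends on water orientation or on
hydrogen-bond directionality within the water network. Residue numbering
is 1-based author numbering as deposited; coordinates are Cartesian
ångströms throughout.

The default IBS definition is the residue-position set of the fungal
DUF3494 isoform family this package was built around (positions 19–25,
38–45, 123–129, 147–153, 174–180, 192–198, 210–216); it is a parameter
(`AnalysisConfig.ibs_ranges`), not a constant of the method.

## Structure I/O and symmetry expansion (`structio`)

Reading/writing goes through gemmi. Alternate conformers are collapsed
to one site per atom, keeping the highest occupancy (ties favour the
blank/'A' altloc) — a deposition-convention choice; the analysis is
insensitive to it because water oxygens rarely carry altlocs. Water
residue names HOH/WAT/H2O are recognised.

Symmetry expansion maps every water through all space-group operators
(taken from gemmi's tables via the header symbol) combined with integer
lattice translations over ±1 cell, keeping images within a radius of a
centre selection and dropping duplicates within 0.1 Å. Pure lattice
translations of the identity are included: a water in the neighbouring
cell is as real a neighbour as a rotated copy. Consequence: in P1 the
expansion is empty only when the radius is smaller than the nearest
neighbour-cell distance. Tests verify the expansion against an
exhaustive operator × 27-cell brute-force oracle.

The "waters on the IBS" selection is any-atom distance ≤ 4.0 Å to any
atom of the IBS residues. The 4.0 Å default is a package choice
(configurable): it is the upper edge of the first hydration-shell
distance range for protein surface atoms.

## Ice Ih lattice and plane patches (`ice_lattice`)

The ice Ih oxygen sublattice is generated as the 4-oxygen wurtzite basis
(fractional (1/3,2/3,0), (2/3,1/3,1/2), (1/3,2/3,3/8), (2/3,1/3,7/8))
tiled on a hexagonal cell. Defaults a = 4.52 Å, c = 7.36 Å correspond to
ice Ih near 0 °C. Note the axial ratio 7.36/4.52 = 1.628 is slightly
below the ideal √(8/3) ≈ 1.633, so the along-c bond (3c/8 = 2.760 Å) and
the three oblique bonds (√(a²/3 + c²/64) = 2.767 Å) differ by 7 mÅ; the
nearest-neighbour O–O distance, which is what the interior-uniformity
invariant and the reported `ice_min_oo_distance` use, is their minimum.

Plane patches are two-sided slabs (default half-thickness 1.0 Å, enough
for one puckered bilayer) around: the basal {0001} plane through the
centre of the first bilayer, and the prism planes {10-10}/{11-20}
through an origin-adjacent oxygen. Characteristic spacings are the
distinct norms of integer combinations (|m|,|n| ≤ 2) of the in-plane
primitive lattice vectors, up to 16 Å — the repeat intervals that rows
of ice waters exhibit, against which measured bound-water intervals are
compared. For the default constants the primary prism plane yields
4.52 Å (one a repeat) and 14.72 Å (two c repeats); literature
comparisons sometimes quote these as ≈ 4.6 / 14.7 Å, consistent with
slightly different assumed lattice constants. No hydrogen placement,
proton disorder, surface relaxation or quasi-liquid layer is modelled.

## Water networks and motifs (`water_network`)

Edges connect waters within a closed-interval cutoff (default 3.7 Å, the
conventional outer limit for water–water hydrogen bonds in crystal
structures). Angles are measured at the middle water of every connected
triple. "Branches" are nodes of degree ≥ 3.

*Linear trough*: candidates are waters within 3.5 Å of any side-chain
atom of the anchor residues (the six inward-facing hydrophobics of the
IBS β-sheet by default). The largest subset (≥ 3) whose perpendicular
residuals from a total-least-squares line all fall within a tolerance
(default 1.0 Å) is returned, ordered by projection. The search is
exhaustive up to 12 candidates and pair-seeded (each candidate pair
defines a trial line, inliers collected, TLS-refit) above; tests pin the
heuristic to the exhaustive oracle on small instances. Ties break by
minimal total residual, then lexicographic water ids.

*Hydration ring*: on the candidate graph (waters within a contact cutoff
of the side-chain carbons, edges at 3.5 Å) the largest simple cycle of
length ≥ 4 is found by exact enumeration up to 15 candidates (cycle-basis
greedy fallback above, which the bundled analyses never reach); with no
cycle, the longest open chain is returned flagged `ring_closure=False`.

## Superposition and docking (`superpose`)

Kabsch is the closed-form SVD solution restricted to proper rotations;
reflections are always rejected because the chirality of a water motif
is physically meaningful. Degenerate (collinear) inputs raise.

Docking a bound-water set onto an ice patch must also *find the
correspondence*. Nearest-neighbour ICP traps easily at ice-lattice
densities (swapped assignments), so the assignment step is solved
exactly as an optimal injective bipartite matching on the squared
distance matrix. Starts: 24 deterministic seeds (water-plane normal
aligned to ±patch normal × 12 in-plane angles) plus seeded-random
orientations to `n_starts` (default 64); convergence when the RMSD
change < 1e-6 Å, cap 100 iterations; best converged solution returned;
fully deterministic given the seed. Because the correspondence is
searched rather than fixed by hand, the optimum can only be at or below
the RMSD of any particular hand-chosen pairing.

Cα RMSD pairs atoms by residue number (≥ 3 common residues required) and
reports the Kabsch RMSD — the standard backbone-agreement measure
between isoform structures.

## Thermal unfolding (`thermal_unfolding`)

Two-state normalisation f(T) = (θ_T − θ_low)/(θ_high − θ_low) with
references at 20/60 °C (70 °C variant for thermostable isoforms — a
parameter, not a branch). Smoothing is an unweighted mean over a
symmetric ±0.4 °C window, truncated symmetrically at the trace ends so
the endpoint values are unbiased (this also keeps a linear ramp exactly
linear). The window is interpreted as half-width ±0.4 °C; it is
configurable where a total-width reading is preferred. After smoothing,
normalisation uses the smoothed references, guaranteeing f(t_low) = 0
and f(t_high) = 1; the curve is linearly resampled to a 1.0 °C grid.
T_m is the linear interpolation of the *first upward* crossing of 0.5 —
the first-crossing rule is the two-state reading of noisy traces.
No van't Hoff ΔH fit is attempted: the target proteins denature
irreversibly, so only the midpoint is meaningful.

## Hydrogen-bond forward lifetimes (`hbond_residence`)

The bond criterion is donor–acceptor distance ≤ 3.5 Å plus, when
hydrogens are present, hydrogen–donor–acceptor angle within 30° of
linear; distance-only otherwise. These are the conventional geometric
definitions for trajectory hydrogen-bond analysis.

The forward lifetime is the *continuous* (uninterrupted-run) definition:
a maximal bonded run of k frames contributes k·Δt, runs truncated by
either trajectory end are excluded by default (the break is never
observed; including them is a flag), and a single unbonded frame ends a
run (no grace period by default; a configurable `grace_frames` bridges
short interruptions for users who prefer an intermittent reading).
Region aggregation pools completed runs of all bonds whose residue
position falls in the region; the whole-surface value is therefore
always between the regional values when both are populated.

The MD engine itself is out of scope: input is a small multi-frame
coordinate array or a precomputed per-frame event table (CSV with a
`# dt_ps=` header). Absolute residence times from the literature depend
on force field and trajectory length and are not reproduced here; the
estimator is validated by parameter recovery on telegraph-process
occupancies with known geometric run-length distribution (2% agreement
at ≥ 10⁵ completed runs) and by clean separation of planted two-region
contrasts (80 vs 68 ps).

## Synthetic data (`synthetic_data`)

Every generator plants a recorded ground truth and is deterministic per
seed (one seed fans out to independent substreams). Noise is isotropic
Gaussian in Cartesian coordinates, matching B-factor-style positional
uncertainty. Defaults are the study conditions of the motif geometry the
package targets: zigzag spacing 2.86 Å / angle 116°, trough interval
4.6 Å, ring edge 2.74 Å with mean 3.4 Å aromatic contact, 54 IBS waters,
746 (wild-type-like) or 554 (mutant-like) waters total, motif coordinate
noise 0.02 Å (the coordinate precision scale of a ~1.5 Å-resolution
structure), melting midpoint 47.5 °C with 2 °C logistic width, hydrogen-
bond lifetimes 80/68 ps at Δt = 1 ps.

`gen_reference_structure` assembles a full synthetic stand-in crystal:
a 223-residue single-chain poly-Ala scaffold (with VAL/LEU trough
anchors and a PHE ring residue at the family's positions) in the
57.12 × 62.99 × 101.21 Å P2₁2₁2₁ cell, motifs planted on a z ≈ 50 Å
plane, extra IBS waters in 3.8 Å-spaced rows (outside the 3.7 Å network
cutoff), and bulk waters in a separate slab. Because the operator
(½+x, ½−y, −z) maps that slab onto itself, the layout confines IBS
waters to y ∈ [4, 13] (images then land in y ∈ [18.5, 27.5], ≥ 4.5 Å
from every IBS atom) and bulk waters to z ∈ [64.5, 89] (all image bands
clear the IBS atoms in z); the generator verifies both properties by
brute force before returning. What the stand-in does *not* emulate: a
real protein fold, realistic B-factors/occupancies, correlated
positional error, partial hydration shells, or crystal-contact water
sharing. Passing tests on it therefore demonstrate correctness of the
*measurement* pipeline, not the biological values of any particular
deposited structure.

## Pipeline and CLI

`run_analysis` composes: read → symmetry expansion around the IBS
(radius 8 Å default; optional) → IBS water selection → network +
largest-component statistics (the largest connected component is
reported as the loop-region network) → trough → ring → docking of the
first 11 loop waters onto basal/prism1/prism2 patches. Stage failures
are recorded per stage and independent stages continue. Reports are
JSON with sorted keys and an embedded config echo, seed and version, so
a rerun with the same seed is byte-identical. Structure comparison
counts waters as shared when an injective nearest matching after Cα
superposition pairs them within 1.0 Å (the "corresponding positions"
notion made quantitative). The CLI (`icebound analyze/compare/simulate/
dock/melt/residence`) is a thin layer over these functions.

## Problem sizes used in the checks

Acceptance-level runs use: stand-in structures with 746/554 waters; ice
lattices of extent 4 (256 oxygens); 20 docking replicates at 0.45 Å
planted displacement (the deviation scale of bound-water motifs from
ideal ice); 100 replicates for motif parameter recovery at σ = 0.05 Å;
50 noisy melting curves at 2% amplitude noise; ≥ 10⁵ completed
hydrogen-bond runs. These sizes give standard errors comfortably inside
every stated tolerance while keeping the whole suite and the acceptance
script in the seconds range on one CPU.

## Known limitations

- Deposited-structure values (water counts, unit cells, motif statistics
  of specific PDB entries) are recovered here from synthetic stand-ins
  with planted truth; running the pipeline on the real depositions
  requires only the coordinate files and the same `analyze` command.
- The hydration-ring search maximises cycle length, not any energetic
  score; with fewer than 4 candidate waters no ring is reported.
- The docking searches rigid transforms only; no flexible fitting, no
  protein–ice energetics.
- The forward-lifetime estimator uses the continuous-run definition;
  intermittent (correlation-function) lifetimes are longer by
  construction and are not computed.
- `expand_symmetry` searches ±1 cell of lattice translations; pathological
  cells thinner than the search radius would need a larger `shells`.
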