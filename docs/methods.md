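# Methods

## Search algorithm

The minima search treats the protein as a rigid external field and the
ligand as fully flexible. One *test optimization* is: draw a random pose,
filter clashes, minimize locally, offer the result to the minima set.

Pose generation follows a fixed order: (i) the ligand's geometric center
(plain mean over all atoms, hydrogens included) is moved to a point drawn
uniformly from the search sphere (direction uniform on the unit sphere,
radius ∝ U^{1/3}); (ii) the ligand is rotated as a whole about a random
axis through its center, axis uniform on the sphere and angle uniform in
[−π, π] — this axis-angle recipe is kept literally even though it is not
the Haar measure on SO(3), because sampling density only affects
efficiency, not which minima exist; (iii) each rotatable torsion is
turned by an independent angle uniform in [−π, π]. Torsion turns move the
smaller side of the bond, and the pose is not re-centered afterwards.
Bond lengths and angles are exactly preserved by construction.

A pose is rejected if any receptor–ligand or ligand–ligand atom pair is
separated by ≤ 0.5 Å (boundary rejects). Ligand pairs at graph distance
1 or 2 (bonded, angle) are exempt — their separations are fixed by the
topology, and without the exemption no pose could ever pass.

Local optimization is SciPy's L-BFGS-B over all 3n ligand Cartesian
coordinates, declared converged when the maximal gradient component is
≤ 10⁻⁵ kcal/mol/Å; an explicit post-check enforces this, restarting up to
twice if the line search stalls early, and an iteration cap of 10 000
turns pathological starts into counted failures rather than hangs. A
converged minimum is rejected if its center left the search sphere, if it
duplicates a stored member (heavy-atom RMSD ≤ 0.1 Å, identity mapping, no
superposition — poses share the fixed receptor frame, so they are
comparable in place), or if the set is full and it does not beat the
current worst member. Ties in energy rank by insertion order.

Per-trial randomness comes from a counter-based stream keyed by
(seed, trial index), so results are reproducible and independent of how
trials are partitioned among workers; the `worker_count` parameter is a
parallelization contract (independent workers, one merging master), and
any partition yields the same minima multiset as the serial run.

Diagnostics record every trial's fate (clash-rejected, optimizer failure,
out-of-sphere, duplicate, capacity-rejected, inserted) plus the trial
indices at which the set changed. A quiet tail in that update curve —
saturation — is the operational sign that the searched region has been
exhausted.

## Energy models

The package's own field is a deliberately simple, smooth, fully analytic
toy: harmonic bonds and angles (E = k(r−r₀)², k(θ−θ₀)²; reference values
taken from the ligand's input geometry, defaults k_bond = 300
kcal/mol/Å², k_angle = 50 kcal/mol/rad²), a cosine series on each
rotatable torsion (default a single 3-fold term, 1 kcal/mol), and
nonbonded Lennard-Jones plus Coulomb (332.064·q₁q₂/εr) with
Lorentz–Berthelot combination. Intramolecular nonbonded pairs start at
graph distance 3 (1-2 and 1-3 excluded, 1-4 at full weight — the simplest
defensible convention, configurable in spirit by swapping the model). No
cutoff by default; an optional hard distance cutoff exists. Gradients are
analytic and tested against central differences at 10⁻⁴ relative
tolerance; the dihedral term uses the standard four-point gradient with
the two inner-atom contributions assembled from the end-atom vectors.

Production target functions enter through the model contract: any object
with a pure `evaluate(receptor, ligand, conformation) → (energy,
gradient)` in kcal/mol and Å. `rescore_set` re-evaluates stored geometries
untouched under a second model and re-sorts (the pattern behind
"search in vacuum, rank in solvent"); `reoptimize_set` re-minimizes each
member under the new model and re-applies deduplication, since distinct
wells of one model can share a basin of another. Implicit-solvent and
quantum-chemical engines are out of scope by design; they are exactly
what the contract abstracts.

## Synthetic systems

Testing a minima search requires systems whose minima are *known*. Two
pockets are built from fixed Lennard-Jones sites:

* **double-well** — two sites on the x axis at ±3.2 Å whose pair
  parameters against the single-atom carbon probe are σ = 2.0 Å and
  ε = 0.40 / 0.25 kcal/mol. Each site alone would hold the probe on a
  degenerate spherical shell at r\* = 2^{1/6}σ ≈ 2.24 Å; the other site's
  attraction tilts each shell toward its partner, collapsing the
  degeneracy to exactly two point minima on the axis, at x ≈ ∓0.95 Å with
  energies −0.41231 and −0.26977 kcal/mol (gap 0.1425 kcal/mol, fixed by
  the ε asymmetry). All other stationary points are saddles: the
  midpoint, rings around each site, and two very flat axial points
  outside the pair at |x| ≈ 5.44 Å whose transverse curvature (~3×10⁻⁵
  kcal/mol/Å²) is smaller than a 10⁻⁵ gradient stop can classify. The
  fixture therefore carries its own search radius, 5.0 Å, placing those
  flats outside the sphere; within the searched region the system
  provably has exactly two minima. The companion *grid-scan oracle*
  enumerates minima independently of the search: a 10⁻³ Å lattice scan
  along the symmetry axis (every point minimum lies on it by symmetry)
  plus a positive-definite check of the full 3-D Hessian at each
  candidate.
* **spherical-cavity** — 30 Fibonacci-sphere sites at exactly the pair
  equilibrium distance from the origin, so the interior minimum is the
  center by symmetry, with isotropic curvature ≈ N·u″(r\*)/3.

Chain ligands are all-carbon zig-zags (bond 1.54 Å, tetrahedral angles);
a chain of n atoms has n−3 rotatable torsions under the detection rule,
so any requested torsion count is available by construction. For an
isolated 1-torsion chain the rigid torsion scan shows three minima (one
trans, two gauche — the 3-fold cosine series shifted by the 1-4
interaction); the full search relaxes all Cartesians and therefore finds
each basin at or below its rigid-scan energy.

What the toys do not emulate: electrostatic heterogeneity, hydrogen
bonding, solvent, ligand strain at biological magnitudes, or the
10⁵–10⁶-trial scale of production searches. Passing tests demonstrate the
machinery — sampling, filtering, optimization, set maintenance, scoring —
is correct, not that any particular force field positions real ligands
well.

## Torsion detection

A rotatable torsion is an acyclic single bond where each end atom has at
least one non-hydrogen neighbour besides its partner. The non-terminal /
hydrogen-rotor exclusion is a deliberate choice: counting methyl and
hydroxyl rotors would inflate torsion counts without changing the heavy-
atom pose space the metrics measure (published per-ligand torsion counts
for benchmark sets are consistent with the exclusion). The rotating set
is the smaller component left by deleting the bond; ties rotate the side
holding the higher-indexed axis atom.

## Metrics conventions

IN counts members *strictly below* the optimized-native energy, so IN = 1
means "no stored minimum beats the native" and exact ties rank the native
first. When every stored member beats the native, IN is reported as ∞:
the set is capacity-truncated, so the true rank is only bounded from
below. INN uses the *non-optimized* crystal pose and a strict < 2 Å
threshold. The pairwise clustering rule "RMSD < 1.4 Å" is not transitive;
single-linkage connected components — its minimal transitive closure —
are the default, with complete linkage available. Clusters are numbered
by ascending lowest member energy, and the native pose joins the
lowest-numbered cluster with a member within the linking distance. The
5 kT window uses kT at 310 K (0.616 kcal/mol) with a ≤ boundary.

## Thermodynamics

Partition-function work is done in log space and SI units (CODATA-2018
constants); interfaces are kcal/mol, Å, amu, K. The translational factor
includes the literal prefactor e and the standard concentration
ρ = 1 mol/L = 6.022×10²⁶ m⁻³; free energies therefore refer to the 1 M
standard state.

Normal modes come from a central-difference Hessian of the analytic
gradient (step 10⁻⁴ Å), symmetrized and mass-weighted. For a
protein–ligand complex all 3n ligand modes are kept — the rigid
receptor's field breaks translational and rotational invariance. For the
free ligand the rigid-body modes are removed as the smallest-magnitude
eigenvalues: 6 (nonlinear), 5 (diatomic/linear), 3 (single atom).
Eigenvalues below −(1 cm⁻¹)² after filtering raise a saddle-point error;
negatives within that tolerance are clamped out with a warning.

The binding decomposition evaluates ΔE, ΔG_ν, ΔG_t, ΔG_r at the global
minima of complex and free ligand and defines ΔG_all as the multiwell-
minus-global-minima residual, making the identity
ΔG_bind = ΔE + ΔG_ν + ΔG_t + ΔG_r + ΔG_all exact by construction. Ligand
strain — the energy of deforming the ligand from its free-state minimum
to the bound conformation — is automatically included because the two
species use separate global minima. Three design points were genuinely
open and are resolved as follows: (1) the protein contributes its own
translational and rotational factors to ΔG_t and ΔG_r (the benchmark's
≈ 10–11 kcal/mol values are consistent with this three-species
convention); a ligand-only switch (`include_protein_tr=False`) keeps the
alternative available. (2) Per-well rotational factors vary only through
the inertia of each pose; the implementation evaluates Zr once per
species at its global-minimum geometry, a second-order effect for
pocket-bound poses. (3) The e prefactor in Zt is implemented literally as
printed in the source formulation.

## Packaged benchmark tables

The 16-complex evaluation tables (binding-energy decompositions; binding
energies under seven target functions plus two docking scores, with
experimental ΔG from kT·ln K_i at 310 K) are shipped as checksummed CSV
transcriptions. `summarize` recomputes the footer statistics — per-column
energy range (max − min) and Pearson correlation against experiment —
rather than storing them. Two transcribed decomposition rows (1DWC, 2P94)
do not satisfy their own additive identity as printed (residuals 1.0 and
10.0 kcal/mol; the companion energy table suggests digit errors in the
source), and `breakdown_consistency` reports them honestly; the other 14
rows close to within the printed rounding. The Pearson correlation of the
transcribed Autodock column with experiment recomputes to 0.32, not the
0.13 its source footer prints; the recomputed value is the one reported.

## Problem sizes

Default test and acceptance runs use the single-atom double-well probe
(500 trials), chains of ≤ 6 atoms, 10⁴-insertion stress tests and the
16-row benchmark tables — sizes chosen so the full suite exercises every
code path in well under a minute while the search still over-samples each
toy basin by two orders of magnitude.

## Known limitations

No receptor flexibility; no symmetry-aware RMSD (poses related by
chemical symmetry count as distinct, matching the stated RMSD
definition); no anharmonic corrections; no solvent; the toy field has no
neighbour lists, so cost is quadratic in atom count; `worker_count` is a
determinism contract, not a speedup, in this implementation.
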