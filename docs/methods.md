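# Methods

This note records the models, conventions and numerical choices behind
`sterolsites`, in the order the pipeline runs them, and what the synthetic
fixtures do and do not establish about real data.

## Contact criterion and fingerprints

A protein residue interacts with a ligand pose when *any* heavy-atom pair
(protein atom, ligand atom) lies within the sum of the two van der Waals
radii.  Defaults: C 1.70 Å, N 1.55 Å, O 1.52 Å (commonly accepted values);
S and P default to 1.80 Å, and unknown elements fall back to 1.70 Å with a
logged warning — the criterion is deliberately insensitive to the exact
radius of rare elements because the fingerprint is a set, not an energy.
The comparison is inclusive (distance = cutoff counts): a boundary
convention has to be fixed for exact testability, and inclusive matches the
reading of "within a distance".  Hydrogens are dropped at parse time and can
never contribute.  A KD-tree prefilter accelerates the scan but is required
(and tested) to agree exactly with the all-pairs computation.  No periodic
boundary handling: docking and grid-sampling output live in one aperiodic
receptor frame.

## Pose clustering

*Docking route.*  Greedy energy-seeded clustering: poses sorted by ascending
docking energy (ties by input index) join the first cluster whose
representative is within the RMSD tolerance (default 2.0 Å), else seed a new
cluster.  RMSD is computed over heavy atoms in the shared frame with no
superposition and no symmetry correction — the docking-cluster convention.
The representative is therefore always the lowest-energy member, and the
procedure is deterministic given the input.  Significance keeps clusters
with at least `ceil(min_fraction · N)` poses (default 2%, so minimum size 6
of 300); the fraction denominator is always the full ensemble as supplied.
A guard of 1e-9 inside the ceiling absorbs binary-representation noise
(0.02 · 300 is 6.000000000000001 in floating point).

*Grid route.*  Poses with LGFE ≥ −3.5 kcal/mol are discarded; the rest are
clustered greedily by centre of mass (unweighted heavy-atom centroid —
masses are not carried by the pose formats) at a 3 Å radius in ascending
LGFE order; the stage-1 representatives are re-clustered at 4 Å and member
sets merged.  Stage 2 operates on representatives, not on all poses.

*Site groups.*  Representative fingerprints are merged by single linkage at
Jaccard ≥ 0.5 ("sharing most of their interacting residues" read as majority
overlap; the threshold is configurable).  Similarity is computed on
chain-stripped residue-number sets by default: published per-site residue
tables list one residue set per group together with a separate
subunit-occupancy count, which requires symmetry-equivalent clusters on
different chains to collapse into one group.  Chain-aware grouping remains
available (`ignore_chains=False`).  Subunit occupancy then counts chains
whose chain-attributed residue sets match the group consensus at Jaccard ≥
0.5; the consensus set contains the residue numbers present in at least half
of the member fingerprints (majority vote — the natural completion of a
"consensus residue-number set", stable against one noisy member).

## Motif scanning

CRAC, CARC and CRAC-like patterns are anchor triples with 1–5 intervening
residues per gap.  Gaps count *sequence positions*, not author numbers:
motifs are sequence patterns, and a triple whose span crosses a numbering
gap is flagged rather than rejected.  The CRAC-like pattern is CRAC with a
central phenylalanine, inferred from published anchor rows with F centres.
Overlapping matches of one kind merge transitively into a region carrying
all alternative triplets; merged regions are pairwise disjoint by
construction.  Strict assignment of a binding fingerprint to a region
requires some alternative's three anchors contacted on one chain; relaxed
requires the central aromatic anchor plus at least one terminal.  Chains are
evaluated independently and OR-ed so intersubunit sites can satisfy a motif
on either partner.  Strict implies relaxed for every input (property-tested).

CCM detection is three-dimensional and requires user-supplied helix
annotations — helix boundaries are never inferred from geometry.  The triad
(W/Y then I/V/L then K/R, in sequence order) must fit within an 8-residue
window on one helix; the partner (F/Y/R) must sit on a *different* helix
with its side-chain centroid within 10 Å of the triad's heavy-atom centroid.
Both parameters are configurable; published descriptions give neither, so
these are this package's defaults, chosen to span one helix turn plus slack
and one inter-helix distance respectively.

## FragMaps, LGFE and annealing MC

Occupancy maps bin typed probe points into 1 Å cubic voxels with a
half-open `[lo, hi)` convention (boundary points go to the higher voxel).
Cubic voxels are the natural completion of published 1 Å slab binning.  The
Boltzmann transform is

    raw_v = −k_B · T · ln(ρ_v / ρ_bulk),  k_B = 0.0019872 kcal·mol⁻¹·K⁻¹, T = 300 K

with ρ_bulk defaulting to the mean voxel density (a user-supplied bulk value
is accepted); empty voxels get raw = +3.0 kcal/mol (ln 0 is undefined; the
cap magnitude follows the grid-free-energy convention and is configurable).
The voxel mean of raw is then subtracted — twice, to push the floating-point
remainder below the 1e-9 invariant — so every map has exactly zero mean.
Overlap coefficients normalise two occupancy maps to probability
distributions and sum the voxel-wise minima; convergence is checked between
the first and second halves of a trajectory and flagged good above 0.6.

LGFE is the sum over classified ligand heavy atoms of the matching map's
value at the atom's voxel.  Nearest-voxel lookup is the default because it
makes LGFE exactly additive over atoms (and hence exactly testable);
trilinear interpolation is available as an option.  Atoms outside the grid
contribute zero and are counted in a warning.  The default class registry
derives 14 map types from the eight standard probes (benzene, propane,
methanol, formamide, dimethyl ether, methylammonium, imidazole, acetate)
plus water: one class per distinguishable probe heavy-atom type and three
generic merged classes.  The sterol classifier sends the hydroxyl oxygen to
the methanol-hydroxyl (donor/acceptor) class, carbons to the apolar class,
and other elements to generic donor/acceptor classes.

Hotspot search tiles the system into 14.14 Å cubes (the last tile per axis
may overhang) and runs, per box, repeated rigid-body Metropolis MC on the
LGFE: a hot phase (default 50 000 steps at 300 K), then a cooling phase
(default 40 000 steps) with the temperature ramped linearly to 0 K, updated
every step.  At zero temperature only strictly LGFE-decreasing moves are
accepted, so each repeat's final LGFE is monotone through the frozen phase.
Moves alternate randomly between uniform translations (≤ 0.5 Å by default)
and rotations about a uniform random axis (≤ 15°); move sizes and the
per-step ramp are this package's choices — published schedules give only
step counts and endpoint temperatures.  Sampling is confined to the box:
translations that would carry the centre of mass outside it are rejected.
This implements "sampling within each box" literally and matters
numerically — without confinement a substantial fraction of walkers drifts
across the flat far-field of the maps and freezes off-grid at 0 K.  Each
repeat draws its generator from `SeedSequence(seed, repeat)`, so runs are
bit-reproducible and independent of repeat order.

## State comparison and stereospecificity

Site groups from two conformational states are matched one-to-one, greedy
best-first, either by fingerprint Jaccard (≥ 0.5; requires shared author
numbering) or by representative-COM distance (≤ 4 Å; requires a common frame
after superposition).  Ties break toward smaller group indices for
determinism.  A cholesterol group is flagged stereospecific when no
epicholesterol group matches its fingerprint at Jaccard ≥ 0.5 (inclusive:
a boundary match means *not* stereospecific).  The flag is monotone in the
threshold, and an empty epicholesterol set yields all-True with a warning.
The underlying comparison is qualitative; the threshold is configurable and
recorded in the run manifest.

## Synthetic fixtures

`make_tetramer` builds four ideal α-helices (1.5 Å rise, 100° twist per
residue, CA 2.3 Å from the helix axis — canonical helix geometry, not fitted
to any particular channel) with *exact* C4 symmetry about z; backbone N, C,
O and a CB pseudo-side-chain are placed from local helix directions.  Motif
letters are planted at author numbers on a poly-alanine background.
`make_pose_ensemble` scatters a rigid dummy sterol (planar fused-ring carbon
scaffold plus one hydroxyl oxygen; no chemical accuracy claimed) with
Gaussian positional noise and uniform random orientations around planted
sites, drawing energies and LGFEs from per-site normals.  Defaults (30 poses
per site, σ = 0.5 Å positional scatter, energies ≈ −10 ± 0.5 kcal/mol,
LGFEs ≈ −6 ± 0.5 kcal/mol) emulate a well-converged docking funnel at one
site.  `make_probe_trajectory` draws per-frame points from Gaussian mixture
components plus a uniform background, clipped to the box, so GFE minima
(component means) and raw depths (−k_B·T·ln(peak/bulk)) are analytically
known.

What passing these fixtures shows: the bookkeeping, clustering logic,
motif logic and grid arithmetic are correct, deterministic, and agree with
independent brute-force oracles.  What it does not show: that real docked
sterol poses cluster cleanly, that real probe sampling converges, or that
the published site percentages on real cryo-EM structures are reproduced —
those depend on external docking/simulation engines and downloaded
structures, which are outside this package's scope.

## Problem sizes and test design

The test suite exercises tetramers of 20–30 residues per chain (≤ 600 heavy
atoms), pose ensembles of ≤ 80 poses, probe trajectories of ≤ 5 000 frames
(~35 000 points), and a reduced annealing schedule (500 hot + 400 cooling
steps, 50 repeats) on 12–18 Å grids with a single-atom probe ligand.  These
sizes keep every invariant sharp — exact partition, zero mean, exact oracle
agreement — while the full-scale defaults (50 000 + 40 000 steps, 1000
repeats) remain the production configuration.  Statistical checks (well
recovery ≥ 90% of repeats, depth within 15%, OC > 0.6) run at fixed seeds.

## Known limitations

- Only PDB/PDBQT coordinate input (no mmCIF); PDBQT is read-only and torsion
  records are ignored.  Altloc handling keeps the highest-occupancy
  conformer; insertion codes are preserved but untested against real
  insertion-coded structures.
- LGFE is used in its native, uncalibrated form; no mapping to experimental
  binding free energies is attempted.
- The 14-class registry reproduces the standard probe set's map count, not
  any specific published class table; class names are this package's.
- No GCMC insertion/deletion, explicit solvent, membrane, or force-field
  energetics: the MC samples a frozen LGFE field with a rigid ligand.
- Segment labels (S1–S6, PH, TRP) in comparison reports require
  user-supplied annotations; none ship with the package.
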