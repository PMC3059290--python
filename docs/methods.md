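# Methods

## Scope and model

`hemescan` treats heme recognition as a purely geometric problem over
a single static conformer per structure.  The working model has three
layers:

1. **Coordination.**  The heme iron accepts axial ligands roughly
   perpendicular to the porphyrin plane.  We call a protein residue an
   axial ligand when one of its nitrogen, sulfur or oxygen heavy atoms
   lies within **3.0 Å** of the iron — the upper range of Fe–N/S/O
   coordination bond lengths.  The closest qualifying atom is recorded
   as the donor; both side-chain and backbone donors are accepted and
   tagged, so downstream analyses can restrict to side chains if
   desired.  Small molecules (imidazole, glutathione, …) that
   coordinate the iron in place of a residue are reported separately
   as non-residue coordinators, never as residue contacts.
2. **van der Waals contact.**  A residue interacts with a heme when
   any heavy-atom pair (residue, heme) is within **4.5 Å** — a
   standard contact radius that covers van der Waals packing and the
   covalent thioether linkages of heme *c* (which we deliberately do
   not treat specially).
3. **Chain classification.**  A chain binds heme if it contributes at
   least one axial ligand or at least **10** interacting residues.
   The ten-residue route exists because some genuine heme proteins
   coordinate the iron through a bound small molecule rather than a
   residue.  By default the residue count pools distinct residues of
   the chain across all hemes in the structure; a `per_heme` flag
   applies the threshold per heme instead, since the counting unit of
   the rule is a judgment call.

All cutoffs are inclusive (`<=`): "within x Å" reads as ≤ x.  The
neighbor search uses a k-d tree over heme heavy atoms; the test suite
pins its equivalence to an all-pairs scan, and rigid-motion invariance
of every verdict is asserted to 1e-6 Å.

## Canonicalization of structures

Structures are read from PDB format via gemmi and reduced to one
conformer: model 1 only; one alternate location per atom (highest
occupancy wins, ties broken by altloc label order); modified standard
residues (MSE, SEC, …) mapped to their parent amino acid for sequence
purposes and flagged.  Resolution, R-value and experiment method come
from REMARK 2 / REMARK 3 / EXPDTA records.  DSSP output is consumed as
files (parsed with Biopython's DSSP-file reader) rather than executed,
which keeps the pipeline free of external binaries; the synthetic-data
module writes classic-format DSSP files for testing.

Sequence-level statistics ideally use full-length native sequences
(crystallized constructs carry tags and disordered gaps).  The
pipeline accepts a user-supplied FASTA of full-length sequences for
the background; when absent it falls back to observed chain sequences
and logs the caveat.

## Preference statistics

Profiles are pooled counts over all chains (not per-chain averages).
Interacting residues are counted as distinct (chain, position) sites
by default — a residue touching two hemes counts once; a flag switches
to per-contact counting.  Enrichment is the ratio of site frequency to
background frequency; zero-background categories are flagged undefined
rather than divided.  Secondary structure maps to three states
(H/G/I helix, E/B strand, rest coil).  Relative accessibility divides
the DSSP exposed area by a packaged, user-overridable table of
Rose-style per-residue maxima, capped at 1.0 (crystal-contact
artifacts can exceed the tabulated maximum); class boundaries at 7 %
and 37 % are inclusive, with a 1e-9 tolerance absorbing float
round-off exactly at the boundary.  Profile comparison is a Pearson
χ² of one profile's counts against expectations scaled from the
other's frequencies; zero-expectation categories are dropped and
logged, df = remaining categories − 1.

## Motifs

Windows span ±4 observed residues around each axial ligand, padded
with `-` at chain termini; indexing follows observed residues, so
disordered stretches do not silently shift a window.  Pattern matching
supports literal residues, the `X` wildcard, and bracketed residue
classes; all overlapping matches are reported.  The CP enrichment test
is a 2×2 comparison of sequences containing ≥ 1 CP versus not (χ² with
continuity correction; Fisher's exact test whenever an expected cell
is below 5); per-occurrence counts are emitted alongside, and a
per-residue rate test is available by flag because the natural
counting unit of "CP dipeptides in a dataset" is ambiguous.

## Curation and superposition

Quality filtering keeps X-ray structures with resolution and R-value
at or below the cutoffs (3.0 Å / 0.30 for the heme set, 2.5 Å / 0.30
for the background set); structures missing either value are excluded
and logged.  Redundancy culling is greedy in priority order (better
resolution, then lower R-value, then lexicographic id): a chain is
kept iff its identity to every kept chain is below the cutoff, which
guarantees the output's pairwise identities are all below the cutoff.
This approximates PISCES; exact membership of any historical culled
set depends on PISCES internals and a specific database snapshot and
is out of scope.

Pairwise identity uses exact global alignment (match 1, mismatch 0,
affine gaps, free terminal gaps) in place of BLAST — at the ≥ 90 %
identity regime where pairing operates, the choice of aligner is
immaterial, and this removes an external binary.  Identity is
identical columns over aligned (both non-gap) columns; coverage is
aligned columns over the shorter sequence length (the longer-sequence
denominator is available by argument).  Apo candidates are rejected
outright if their structure carries any ligand from the heme-like
exclusion table (packaged representative list, user-extensible; HEM
and HEC are always members), and a candidate's pocket is validated
clear when no non-water hetero heavy atom lies within 4.5 Å (the
contact cutoff, reused deliberately) of the mapped pocket residues.

Superposition is sequence-guided: the pairing alignment supplies the
Cα correspondence, and the Kabsch algorithm (SVD with the
determinant-sign correction, so reflections are never returned) gives
the least-squares proper rotation/translation and the RMSD over all
matched Cα pairs, with no outlier trimming.  Collinear point sets and
sets with fewer than three matched pairs raise errors rather than
returning an underdetermined rotation.  The Monte-Carlo check in the
test suite uses the small-noise expectation
E[rmsd] ≈ σ√3·√(1 − 3/n) for isotropic per-coordinate noise σ.

## Pocket shape

Rvs = V/A has units of length; a sphere of radius r scores exactly
r/3.  nRvs divides Rvs by that of the equal-volume sphere,
nRvs = (V/A)·3/(3V/4π)^⅓, so a sphere scores exactly 1 and rougher or
flatter shapes score lower at equal volume.  This sphere
normalization is a reconstruction from the cited idea rather than a
verified transcription of the original formula, so it is cross-checked
only on analytic shapes (sphere = 1, cube = ½·(4π/3)^⅓ ≈ 0.806).

Externally measured volumes/areas (CASTp-style TSV) are the exact
route and are packaged for the curated apo–holo pairs.  The grid
estimator is an approximate substitute: atoms (minus the heme, minus
waters) are voxelized with probe-inflated van der Waals radii
(probe 1.4 Å, default spacing 0.6 Å); bulk solvent is flood-filled
from the box boundary with 6-connectivity; pocket space is the
enclosed empty space plus the open concavities sealed by a
morphological closing of radius 4 Å; the connected components touching
the heme's former footprint form the pocket.  Volume is voxel count ×
spacing³; area comes from a marching-cubes surface over the pocket
mask (face counting would overestimate a sphere's area by ~50 %;
marching cubes lands within ~10 %, which is why grid-estimated nRvs of
a spherical cavity is asserted only to 1 ± 0.1).  Grid estimates and
external measurements are never mixed in one comparison.  Pockets
below 10 voxels raise an error suggesting finer spacing — wide-open
pockets can legitimately collapse to near-zero enclosed volume under
flood-fill semantics, which is also why the open-groove fixture is
only sanity-ordered (open < enclosed), never matched to an analytic
value.  Dispersion between pocket sets is compared inside a
350–2000 Å³ size window with a median-centered Levene
(Brown–Forsythe) test.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of (parameters, seed) and reruns are
byte-identical.  They emulate exactly the features the rules probe:

- an idealized planar porphyrin (Fe, 4 N at 2.05 Å, 20 ring carbons,
  2 propionate arms; 35 heavy atoms) under a seeded random rigid
  rotation, plus a flagged 5-atom "mini heme" for unit tests;
- contact residues whose anchor atom sits at an exact target distance
  from the nearest heme heavy atom (placed by bisection along a
  direction ray; directions that run the backbone toward a propionate
  arm are re-sampled deterministically).  Target distances in test
  suites avoid the 4.5 Å boundary itself, where float round-off makes
  "exactly at the cutoff" ill-defined;
- sequence families hitting pairwise-identity targets to within
  1/length, with the realized identity matrix recomputed by the
  alignment oracle and shipped alongside;
- apo/holo pairs related by a known rigid motion plus Gaussian noise,
  with an oracle RMSD computed by an independent superposition routine
  (scipy's `Rotation.align_vectors`);
- cavity shells placed vdW + probe outside the nominal wall so the
  estimator's inflated occupancy lands on the analytic boundary, with
  analytic volume/area attached;
- classic-format DSSP files with prescribed secondary structure and
  integer-quantized accessibility.

They do **not** emulate realistic side-chain rotamers, covalent heme-c
linkage geometry, crystal packing, waters, or sequence composition of
real heme proteins.  Passing the fixture suites therefore demonstrates
that the rules, statistics and numerics are implemented correctly —
not that any biological claim about real structures is reproduced.
Checks against real structures require fetching PDB entries and are
kept outside the test suite.

## Problem sizes and defaults

Test and acceptance runs use deliberately small problems chosen to
exercise every code path: 500 seeded contact fixtures (0–15 residues
each), 100-replicate Kabsch Monte-Carlo at n = 500 points, 50 random
4-sequence families at length 80 for culling, a radius-5 Å sphere at
0.5 Å grid spacing, 1000 null χ² simulations at n = 10⁴ draws, and 200
CP-power simulations at 500 sequences of length 150 per set with
containment probability 0.2 vs 0.4 (a doubled rate).  Default cutoffs
(3.0 / 4.5 / 10 / 25 % / 90 % / 95 % / 7 % / 37 % / 350–2000 Å³) are
the study conditions and are embedded in every output table header.

## Known limitations

- Exact reproduction of any historical culled dataset is impossible
  without the same database snapshot and culling internals.
- The grid pocket estimator is not an alpha-shape computation; its
  volumes agree with analytic cavities to ~10 % but can differ more on
  irregular pockets, and nRvs > 1 is possible for grid estimates.
- Sequence-guided superposition assumes the pairing alignment is the
  correct residue correspondence; below ~90 % identity a structure
  aligner would be preferable (an externally produced correspondence
  can be supplied through the pairing alignment object).
- The χ² profile comparison treats residues as independent draws;
  spatial correlation within binding sites is ignored.
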