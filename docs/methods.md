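# Methods

This note documents the models, parameter choices, numerical conventions,
and known limitations of the `targetfish` pipeline, in the spirit of the
methods documentation of mature scientific packages.

## Scoring model

The pipeline is a weighted fusion of a ligand-based and a structure-based
signal. The ligand similarity score `T_L` between a query and a reference
co-crystal ligand is the unweighted mean of per-fingerprint Tanimoto
coefficients `T = N_ab / (N_a + N_b − N_ab)`. Averaging over several
fingerprint algorithms smooths the strong fingerprint dependence of any
single Tanimoto cutoff. The binding similarity `T_B` is the same Tanimoto
form applied to per-residue interaction fingerprints of the docked query
pose and of the co-crystallized ligand in the same receptor. The combined
ranking score is `0.7·T_L + 0.3·T_B`, the published weighting of this
workflow family; weights are configurable but must be non-negative and sum
to one, so the combined score always stays in [0, 1] and is monotone in each
component.

Two all-zero bit-vectors compare as 0.0 (with a logged warning), not NaN or
1.0: a featureless molecule or an interaction-free pose must never rank as a
perfect match.

## Fingerprints

| algorithm | length | role |
|---|---|---|
| Morgan, radius 2 | 2048 | similarity search (presets MM, MMD) |
| MACCS keys | 167 (RDKit slot 0 unused) | similarity search |
| Daylight-style path | 2048 | similarity search (MMD only) |
| atom pairs, torsions, 2D pharmacophore (Gobbi) | toolkit defaults | optional/custom presets |
| Avalon | 512 | activity-model descriptor only |

Lengths follow the reference toolkit's community defaults and are recorded
in library metadata; a library whose stored fingerprints disagree with its
metadata fails validation. SMILES are canonicalized at ingestion (explicit
hydrogens are suppressed for canonicalization but retained on the stored 3D
molecule), so fingerprints are independent of input atom ordering and
duplicate detection is by canonical SMILES.

The default shortlist cutoff is `T_L ≥ 0.4`. Raising the cutoff can only
shrink the shortlist (anti-monotonicity is part of the test contract).
Class-specific (CS) mode filters the library to one target class before
scoring; its output is always the class-restricted subset of the all-class
output at equal settings.

## Interaction fingerprint scheme "v1"

Eight bits per receptor residue, in fixed slot order: hydrophobic,
aromatic-face, aromatic-edge, protein-HB-acceptor, protein-HB-donor,
salt-bridge-protein-positive, salt-bridge-protein-negative, metal-contact.
Residue order is the file order of the receptor; fingerprints from
different receptors are never comparable.

Geometric criteria (all distances in Å):

- hydrophobic: ligand C/S within 4.5 of a side-chain carbon;
- H-bond: donor-heavy–acceptor ≤ 3.5 and D–H···A angle ≥ 120° when the
  donor hydrogen is modelled, distance-only otherwise;
- salt bridge: opposite formal charges ≤ 4.0 (protein cations: Lys NZ,
  Arg NE/NH1/NH2; anions: Asp/Glu carboxylates);
- aromatic face: ring-centroid distance ≤ 4.5 and interplanar angle ≤ 30°;
  edge: distance ≤ 6.0 and angle in (30°, 90°];
- metal contact: ligand O/N/S ≤ 2.8 from a metal ion.

These thresholds are conventional structural-interaction-fingerprint
values; they are versioned ("v1") because any change silently changes every
`T_B` in a library. Ligand atoms are typed from the RDKit molecule: donors
are O/N bearing hydrogens, acceptors are O (neutral or anionic) and
hydrogen-free neutral N, charges are formal charges, aromatic rings come
from the aromaticity perception of the toolkit. Water-mediated contacts,
halogen bonds, and per-atom (rather than per-residue) resolution are out of
scope.

## Receptor and ligand preparation

Receptor cleaning removes waters and any residue outside an allow-list of
the 20 canonical amino acids plus common catalytic metals (ZN, MG, MN, CA,
FE) — metals are kept because they are essential in classes such as
carbonic anhydrase. When a structure carries no hydrogens at all, backbone
amide hydrogens are placed geometrically (1.01 Å from N, opposite the
bisector of N→CA and N→C(prev)); side-chain protonation is not attempted,
which is why the H-bond criterion has a distance-only fallback. Output is
cleaned PDB; PDBQT receptors require an externally configured converter.

Ligand preparation writes a deliberately simplified PDBQT dialect:
Gasteiger charges, AutoDock-style types, nonpolar hydrogens merged onto
their carbons (charges folded in), polar hydrogens retained, a single rigid
ROOT block, and rotatable bonds declared via REMARK annotations plus
TORSDOF. This is sufficient for the Vina text contract; it does not emit
the full BRANCH tree of AutoDockTools.

## Docking

The engine interface is the Vina text contract: PDBQT in, multi-model PDBQT
out with `REMARK VINA RESULT` energies. Any conformant binary (Vina, smina,
PSO-based variants) is substitutable. Defaults where the engine is silent:
search box centered on the co-crystal ligand centroid with its bounding box
grown by 8 Å per side, exhaustiveness 8, fixed seed from options. Pose
selection is the exact minimum over the engine's pose list; a pose whose
centroid drifts beyond the box dimensions fails a sanity check.

The mock engine returns the co-crystal pose verbatim when the query *is*
the co-crystal ligand (so self-docking reproduces the reference binding
mode, `T_B = 1`) and otherwise rigidly translates the query conformer to
the box center, with a deterministic pseudo-energy. It exists to make the
full pipeline deterministic and testable; its energies are not physical.

## Activity models

Per target class, a random forest regresses activity (−log M; the
Ki/Kd/IC50 kind is retained but all activities live on the −log M scale)
on 512-bit Avalon fingerprints. Assessment uses repeated nested CV:
defaults are 5 outer folds, 3 inner folds, 10 repeats, and a grid over
{100, 300, 500} trees × max-features {√p, p/3, p}. The inner grid search
sees only the outer training fold — permuting an outer test fold's labels
provably cannot change that fold's hyperparameter choice, and a dedicated
test asserts this. Folds with zero label or prediction variance have
undefined Pearson R; they are excluded from the mean with a warning (their
RMSE still counts). The deployed model is refit on all data with the most
frequently selected hyperparameters. SVR, gradient-boosted trees and k-NN
are available behind the same interface as comparators.

The test suite and the acceptance script run the nested CV at a reduced
scale (repeats 2, grid {100, 300} × {√p, p/3}, n = 300 synthetic rows) —
the package's own choice of a desk-scale protocol; the full defaults are
unchanged for real use. At this scale the noiseless synthetic signal is
recovered with outer-CV R ≈ 0.95 and permuted labels give |R| ≈ 0.03–0.06.

A missing class model degrades a prediction record to a null activity with
a warning rather than aborting target identification.

## Evaluation conventions

A prediction is correct when the returned `target_name` matches any known
target of the query (case-insensitive, whitespace-normalized). Success@N is
the fraction of queries with a true target in the top N ∈ {1, 5, 10}. For
precision at N the denominator is `min(N, records returned)`, which keeps
precision ≤ 1 for short lists; duplicate PDB entries of one target name
within the top N count once toward TP; F1 is the harmonic mean (0 when both
components are 0) and is bounded by 1 by construction. Aggregates are
unweighted means over queries. Decoy reports count decoys whose intended
target appears in the top 1/5/10 and round percentages to the nearest
integer. Pooled tables sum per-class counts and report percentages over the
union of ligands.

## Synthetic fixtures

The fixture generators are first-class, tested code; every generator is a
pure function of (spec, seed).

- `generate_complex` builds an idealized receptor — residues on a line,
  10 Å apart, with a planar local backbone template — and places ligand
  fragments analytically so that scheme v1 recovers *exactly* the declared
  interaction bits (e.g. a carbonyl O at 2.9 Å from a backbone N–H at a
  160° D–H···A angle; a methylammonium N⁺ at 3.76 Å from an Asp
  carboxylate, inside the salt-bridge cutoff but outside the H-bond
  cutoff). Face-stacked aromatic rings necessarily also satisfy the
  hydrophobic criterion, so that construction declares both bits. This
  round trip is the primary correctness harness for the interaction
  detector. The receptors are deliberately non-physical: exact geometric
  control matters here, realism does not.
- `generate_library` draws co-crystal ligands from fixed per-class chemical
  families (sulfonamides, aliphatic amines, pyridine carboxamides, catechol
  ethers) whose similarity structure is verified at generation: one
  near-duplicate pair (Morgan Tanimoto ≥ 0.7 — in fact the octyl/nonyl
  homologs have identical folded fingerprints) and all cross-class pairs
  ≤ 0.3. Ligands are ETKDG-embedded and parked against a small Ala/Gly
  receptor, so reference interaction fingerprints are sparse but non-trivial.
- `generate_activity_dataset` emits Avalon-length simulated bit-vectors
  with a linear ground-truth activity on k informative bits plus Gaussian
  noise; ground-truth weights are returned for recovery tests.
- `generate_decoys` draws from a fixed diverse pool under two constraints:
  Morgan Tanimoto < 0.4 to every co-crystal ligand of the intended target,
  and ≥ 100 Da molecular-weight spread per decoy set.

What passing these tests shows — and does not show: they verify the
arithmetic, determinism, geometry detection, ranking logic and CV
discipline of the implementation exactly; they do not demonstrate
retrieval performance on real protein–ligand data, which depends on a
curated complex library and a physical docking engine that are outside the
desk-scale scope of this package.

## Design choices on genuinely open points

- A single `pharmacophore2d` algorithm (Gobbi 2D pharmacophore) is exposed;
  Avalon is restricted to activity-model descriptors rather than the
  similarity search.
- Ranking keeps one row per PDB complex (no collapsing by target name);
  correctness checks compare target names. Ties break by combined score,
  then `T_L`, then PDB id ascending — an arbitrary but deterministic total
  order, required for testable ranks.
- Every shortlisted entry is docked; no secondary `T_B` cutoff or candidate
  cap is applied.
- Train/validation splitting is stratified per class, with the first
  shuffled entry of every target name pinned to training so each validation
  ligand's target is trainable; a single-complex target therefore always
  trains (logged).
- Library serialization is a human-inspectable directory (JSON manifest,
  packed binary fingerprint sidecar, copied structure files); the metadata
  timestamp defaults to null so double builds are byte-identical.

## Known limitations

- The interaction scheme is per-residue and typed, not per-atom; two poses
  that touch the same residues in the same ways are indistinguishable.
- MACCS length is the toolkit's 167-slot vector, not the nominal 166 keys.
- Hydrogen handling is minimal (backbone amide H only); structures with
  unusual protonation states fall back to distance-only H-bond checks.
- The simplified PDBQT writer omits the BRANCH tree; engines that require
  full torsion trees for flexible docking need externally prepared ligands.
- Kinase-like subclass-specific activity models are not provided; one model
  per class is the granularity of the design.
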