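# Methods

This note records the modelling decisions behind `paragrid`: what each
stage assumes, which parameters matter, what the synthetic generators do
and do not emulate, and where the design was genuinely open.

## Interface definition and structure handling

A receptor residue is labeled binding when the minimum heavy-atom
distance to the antigen is **≤ 4.5 Å**. Both `≤` and `<` appear in
common usage; the difference is measure-zero on real coordinates, and
one convention (`≤`) is applied uniformly to residue labels, surface-
point labels, and the pair-level interface sanity check. Distances are
computed with a k-d tree but are required (and tested) to agree exactly
with a brute-force all-pairs scan.

PDB input goes through gemmi. Alternate locations collapse to the
highest-occupancy conformer (first encountered wins ties). Cleaning
removes waters, monoatomic ions (a fixed name list plus any monoatomic
HETATM residue), and HETATM ligands; modified residues such as MSE stay,
since they are part of the polymer. Residues are keyed by author chain /
number / insertion code throughout — the package never renumbers.

## Dot surface

The solvent-accessible surface is sampled per heavy atom on the sphere
of radius r_vdW + 1.4 Å (water probe; Bondi-style radii table), at a
default density of 0.5 dots/Å² — the density recommended for large
molecules in the DMS dot-surface tradition. Dots inside any neighbouring
expanded sphere are pruned; normals are radial from the parent atom.

Dot placement uses a deterministic Fibonacci lattice, oriented in a
canonical molecule-intrinsic frame (principal axes with sign fixed by an
index-weighted projection), so that the generated surface is exactly
equivariant under rigid motion of the structure. Molecules with
degenerate principal moments (perfectly symmetric point sets) have
ill-defined axes and lose this guarantee; real proteins never do.
External DMS files are read verbatim (their normals are trusted), giving
compatibility with the original tooling; the two sources are not
expected to agree dot-for-dot, only in the invariants the pipeline
relies on.

## Featurization

Channels 1–18 are the classic chemistry set: nine element classes (B, C,
N, O, P, S, Se, halogen, metal — one-hot, all-zero fallback for exotic
elements), hybridization (integer), heavy valence, heterovalence,
partial charge (Gasteiger), and five pharmacophore flags (hydrophobic,
aromatic, acceptor, donor, ring) evaluated through RDKit's feature
definitions on a molecule built from the structure with proximity
bonding. If RDKit cannot sanitize the molecule, connectivity-derived
channels fall back to zero with a logged count — element classes never
depend on it.

Channels 19–22 are AMBER/CHARMM partial charge and radius. The primary
source is a PQR file per force field (pdb2pqr output); without one, a
packaged template table covers protein backbone atoms (plus ALA/GLY side
chains), and uncovered atoms read 0 with a logged count. Structures
whose PQR generation fails upstream are meant to be excluded from
training sets, mirroring the exclusion bookkeeping in the CLI.

Grids are 41³ voxels at 1 Å — wide enough to contain every atom within
20 Å of the surface point. The local frame's third axis is the surface
normal; the in-plane tangent is fixed by projecting the global x-axis
(y-axis when nearly parallel). That in-plane choice is arbitrary by
construction, and the random 90° rotation augmentation is the pipeline's
own mitigation. Atoms map to the voxel containing their frame
coordinates (half-open intervals, centre voxel spanning [−0.5, 0.5) Å);
co-located atoms sum channel-wise, which preserves per-channel totals
under the rotation augmentation and makes conservation testable.
Sampling balance (|positives| = |negatives|, positives ≤ 800) holds in
both the abundant and the capped branch; negatives are drawn uniformly
from all non-positive points, with no minimum-distance buffer.

## Network

The published outline — initial conv block, four residual stages of
dilated bottlenecks ending at 2048 channels, 1×1×1 compression to 256
(+ BN + ReLU), one transformer block, global average pooling, dropout
0.1, sigmoid head — leaves per-stage depths, strides, dilations and head
count open. The default here is a ResNet-50-style reconstruction:
stages of (3, 4, 6, 3) bottlenecks, widths (256, 512, 1024, 2048),
strides (1, 2, 1, 1) after a stride-2 stem + max-pool, dilations
(1, 1, 2, 4), 8 attention heads over the flattened 6³ token grid with
learned positional embeddings. All of it is overridable via
`ModelConfig`.

Layers are NumPy implementations with manual backpropagation
(convolution as one GEMM per kernel offset), verified against central
finite differences in float64. Training follows the stated recipe:
BCE with logits, Adam, lr(e) = 10⁻⁴ / 5^⌊e/5⌋, batch 64, a held-out
validation split with best-loss checkpointing and optional patience.
Dropout and shuffling derive from the training seed, so runs are exactly
reproducible.

`ModelConfig.reduced()` is a first-class width-reduced configuration
(stem 16, widths 32–256, compression 32, 9³ grids) with the identical
topology, used for CPU-scale training experiments; the full-size model
is exercised forward-only. Problem sizes in the tests (2000 planted
grids of 9³×22, ≤ 5 epochs) were chosen so the whole suite runs on one
CPU core in minutes.

## Synthetic data

`make_toy_complex` builds rigid 4-atom poly-glycine-like residues on a
6 Å lattice. Interface residues sit with one atom at an *exact*
specified distance above an antigen anchor atom; all other receptor
atoms are at least the decoy separation away. Expected binding labels
are therefore known by construction, including exactly-at-cutoff cases.
These fixtures exercise every geometric code path (labels, sanity check,
surfaces, sampling, voxelization) but are chemically minimal:
SMARTS-dependent channels are tested separately on an RDKit-embedded
Ala-Ala dipeptide. Nothing in the toy geometry resembles real antibody
folds, so passing tests demonstrate correctness of the pipeline's rules,
not predictive performance on real complexes.

`make_planted_grids` emits balanced labeled grids whose positive class
carries an additive shift of effect × noise on one channel inside the
central 3³ region, over i.i.d. Gaussian noise. A one-feature linear
read-out separates the classes almost perfectly at ≥ 3σ effects, making
it a calibrated target for the training-mechanism test: a network that
implements its forward/backward passes correctly must reach held-out
AUROC ≥ 0.95 within 5 epochs at 5σ. The default 9³ spatial extent keeps
2000 grids within ordinary memory; the signal is spatially central, so
grids of any odd size work identically.

## Evaluation

IMGT positions are an input (a per-chain mapping table validated for
monotonicity and range); the package deliberately ships no sequence
numberer. Region ranges: FR1 1–26, CDR1 27–38, FR2 39–55, CDR2 56–65,
FR3 66–104, CDR3 105–117, FR4 118–128, constant beyond. CDR±2 flanks
are taken along the ordered chain sequence, not by numbering arithmetic,
so insertion gaps cannot skew them. Scopes nest: CDR ⊂ CDR±2 ⊂ Fv ⊂ Fab.

AUROC and AUPR come from scikit-learn (AUPR as average precision, i.e.
step interpolation), and are tested against O(n²) pairwise-concordance
and threshold-sweep oracles including tied scores. Threshold metrics use
strict `>` at the operating point (0.5 default; 0.734 for comparability
with Paragraph-style evaluations). Pooled metrics are micro-averaged
over residues by default, with a macro (per-complex mean) mode; CAUROC
is always the median of per-complex AUROCs, excluding complexes whose
scoped labels are single-class (they still count in pooled metrics).
The positional baseline scores each (chain type, IMGT position) by its
binding frequency in training, 0 for unseen positions.

## Degenerate inputs and numerical choices

Zero-norm normals, even grid sizes, thresholds outside [0, 1],
single-class training sets, antigens without heavy atoms, empty
structures after cleaning, and unmatched DMS records all raise
structured errors. Residues with no surface points score 0.0 and carry a
flag. Occlusion pruning uses a 10⁻⁹ Å slack so dots exactly on a
neighbouring sphere count as accessible; batch-norm uses ε = 10⁻⁵,
momentum 0.1; the BCE is computed on logits in float64 for stability.

## Known limitations

* The per-stage architecture details are a reconstruction; published
  trained weights are not reproduced, and desk-scale experiments show
  mechanism recovery, not benchmark performance.
* The packaged force-field template covers backbone atoms only; full
  side-chain electrostatics require PQR input.
* The dot surface is a per-atom accessible surface, not a reentrant
  (Connolly) surface; analytic areas and meshes are out of scope.
* Only PDB (and PDB-like PQR/DMS) input is supported; assemblies,
  symmetry expansion and mmCIF beyond gemmi's detection are not.
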