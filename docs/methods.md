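# Methods

## The model

`vhfold` predicts the backbone (N, Cα, C, O) and Cβ coordinates of an
antibody heavy-chain variable domain (VH), nanobody (VHH) or TCR Vβ domain
directly from its amino-acid sequence, with no multiple sequence alignment,
template search or fragment assembly.

The trick that makes direct coordinate regression work is *transformational
invariance by construction*: variable domains share a rigid β-sandwich
framework (frame Cα RMSD across structures is well under 1 Å), so every
training structure is superposed onto one designated reference structure
using its frame Cα atoms, and the network learns coordinates in that single
common frame. Prediction is then a pure sequence → coordinate-matrix map.

**Input.** A sequence of at most 140 residues is one-hot encoded into a
140 × 22 matrix: 20 channels for the amino acids (alphabetical one-letter
order), one for unknown (X), one for "insertion", which also fills all
padding rows beyond the sequence length.

**Architecture.** Two 1-D residual convolutional networks: a first ResNet
with kernel size 25 (wide enough to see whole loops and their flanking
frame), a width-1 convolution to 140 channels, a second ResNet of kernel-5
blocks with dilations cycling through (1, 2, 4, 8, 16) to capture
inter-residue dependencies across the domain, a 25% dropout layer, and two
width-1 projections to 70 and then 15 channels. The 15 output channels per
position are the N, Cα, C, O, Cβ coordinate triples. The default
configuration has ≈1.7M trainable parameters.

Details the architecture description leaves open were fixed as follows and
are all recorded in `ModelConfig`:

* residual blocks are pre-activation (BN → ReLU → conv, twice) with identity
  skips; ResNet-1 has 3 blocks at 64 channels, ResNet-2 one block per
  dilation at 140 channels;
* per-channel batch normalization and ReLU activations;
* the final projection is zero-initialized and followed by a fixed scalar
  output gain (default 30). Coordinates in the reference frame span tens of
  Å while Adam moves each weight by at most the learning rate per step; the
  gain is a units choice that lets short optimization runs reach the right
  output magnitude, and zero-initialization makes the model start at the
  coordinate origin rather than at amplified noise;
* no final activation (coordinates are unbounded);
* no chirality correction is applied; `ca_mirror_fraction` reports the
  fraction of negative Cα virtual dihedrals as a mirror-image diagnostic.

`ModelConfig.small()` is the desk-scale variant used throughout the test
suite (24/40 channels, 2 + 5 blocks, ≈155k parameters). It disables dropout:
with a few hundred training examples the regularization buys nothing, and
dropout's activation noise — amplified by the output gain — puts a floor of
several Å² under the validation error.

## Loss

For target y and prediction ŷ (both 140 × 15, padding masked out):

* **MSE term** — mean squared displacement over included atoms, i.e. the
  squared RMSD in the common frame. Averaging is per *atom*, not per
  component; Cβ entries of glycines are excluded via a Cβ mask.
* **Cα continuity term** — Σᵢ (d(Cαᵢ, Cαᵢ₊₁) − 3.8)², the sum over
  consecutive real-residue pairs, pulling predicted chains toward ideal
  peptide Cα spacing. The printed formula is an unnormalized sum, which we
  keep as the default; `TrainConfig.ca_average` switches to a per-pair mean.
  Note the total loss is *not* zero at the ground truth unless the target's
  own spacing is exactly 3.8 Å.

The total loss is the exact sum of the two terms. Padding rows contribute to
neither; the continuity term runs only over mask-adjacent real pairs.

At desk scale the unnormalized sum (~113 pairs) exceeds the averaged MSE by
roughly two orders of magnitude and dominates the optimization long before
the structure is learned, so every *training run in the test suite* sets
`ca_average=True`; the analytic unit tests of the loss use the printed sum
form.

## Training

Adam (conventional moments), learning rate 0.001, batch size 16, up to 130
epochs with a model checkpoint on the validation loss (dropout off for
validation); the initial state is a checkpoint candidate, so retraining can
never return a model worse on validation than its start. Batches are
reshuffled each epoch from the run seed; the last partial batch is kept.
Training aborts with a diagnostic on non-finite loss. 5-fold cross-validation
supports stratified validation-fold composition (e.g. fixed per-class
counts). TCR-style transfer retraining continues from pretrained parameters
with the same loss and learning rate, capped at 50 epochs.

Everything is implemented in numpy (im2col convolutions, analytic backward
passes verified against finite differences, Adam); training is exactly
reproducible given the seeds.

## Evaluation protocol

Regions follow the Chothia scheme: CDR1 = positions 26–32, CDR2 = 52–56,
CDR3 = 95–102 (configurable, `RegionBoundaries`). Without an imported
numbering table, an anchor heuristic locates the CDRs from the two conserved
cysteines, the CDR1-closing tryptophan and the C-terminal W-G-x-G motif.

Loop accuracy is reported as backbone (N, Cα, C, O) RMSD after superposing
the *frame* atoms only, so loop error is not absorbed into the fit; the
whole-domain value uses its own optimal superposition. Kabsch superposition
(SVD with reflection guard) is the single superposition primitive.
Breakdowns by CDR3 length and by maximal sequence identity (MSI) to the
training set are provided; the MSI trend is summarized with a Spearman rank
correlation (the correlation statistic was an open choice; rank correlation
is robust to the heavy right tail of RMSD values). CAPRI-style docking
quality uses ligand RMSD after receptor superposition and interface RMSD
over native residues with backbone atoms within 10 Å of the partner chain
(cutoff configurable); grades are strict: medium if ligand < 5 Å or
interface < 2 Å, acceptable if ligand < 10 Å or interface < 4 Å.

## Repertoire analysis

Because predictions share the reference frame, structural similarity needs
no superposition: the distance between V and W is
1 − (#Cα pairs matched one-to-one within 1 Å) / min(|V|, |W|). Greedy
closest-pair one-to-one matching keeps the count ≤ min(|V|, |W|), hence the
distance in [0, 1]; it is symmetric with zero diagonal but not a metric (no
triangle inequality is claimed). The matrix is clustered with PAM-style
k-medoids (default k = 12, 10 seeded restarts, best total cost kept).
Sequences are embedded by aligning to 126 canonical positions and one-hot
coding over 21 symbols (20 amino acids + gap) — a 2,646-dimensional vector —
then projected to 2-D with t-SNE; agreement between structural clusters and
sequence families is scored with the adjusted Rand index.

The canonical alignment is layout-based: seven fixed-capacity blocks
(frame 1 = 25, CDR1 = 9, frame 2 = 19, CDR2 = 8, frame 3 = 34, CDR3 = 16,
frame 4 = 15; total 126). Frame 1 is right-aligned (N-terminal truncation is
the common case), other frames left-aligned, CDRs fill from both ends toward
the middle the way numbering schemes place loop insertions. Residues beyond
a block's capacity are dropped from the *embedding only* (logged), never
from model input.

## Synthetic benchmark

The generator emulates the features of variable-domain structure data this
package depends on, with no external downloads:

* **Rigid shared frame.** One frame template per run, built by sequential
  natural-extension (NeRF) placement with ideal bond lengths (N–Cα 1.458 Å,
  Cα–C 1.525 Å, C–N 1.329 Å) and blockwise secondary-structure-like
  torsions; every member reuses the template's frame atoms exactly.
* **Loops as a deterministic, smooth function of loop sequence.** Loop Cα
  traces are grown in virtual-Cα geometry — virtual bonds of exactly 3.8 Å
  whose bend/torsion angles come from a per-family lookup table indexed by
  amino-acid class (4 classes; family base angles drawn from stratified,
  well-separated windows; small per-class offsets, sd 6°) — and closed onto
  the downstream frame anchor with FABRIK inverse kinematics, which
  preserves bond lengths by construction. N and C atoms are placed with
  ideal in-residue bond lengths in local frames along the Cα trace; O in the
  peptide plane; Cβ at ideal tetrahedral geometry (absent for glycine). An
  earlier φ/ψ + cyclic-coordinate-descent implementation was abandoned: its
  closure was chaotic in the loop sequence, which broke both the Cα-spacing
  band and the structural coherence of planted families.
* **Families.** Members share a family frame variant (a few fixed
  substitutions of a global consensus) and a family consensus loop set
  (clonal families share loop lengths); members differ by 2 frame mutations
  and 12% loop point mutations. Anchor motifs (Cys21, the CDR1-closing Trp,
  the second Cys, W-G-x-G) are hard-planted and excluded from mutation, and
  C/W are excluded from the random alphabets so the anchors stay unique.
* **Noise.** A chain-smooth Gaussian displacement field (per-residue, linear
  interpolation of ~8 knots, marginal sd ≈ `noise_sd`, default 0.1 Å)
  applied rigidly to each residue's atoms. Independent per-atom noise at
  this sd would routinely push consecutive-Cα spacing outside [3.6, 4.0] Å;
  the smooth field preserves bond geometry while keeping per-atom
  displacement Gaussian at the stated scale.

What the generator does *not* emulate: real Ramachandran statistics, side
chains, packing/steric exclusion, β-sheet hydrogen bonding, loop
conformations that depend on long-range tertiary contacts, and experimental
artifacts (missing density, altlocs, crystal contacts). Tests passing on
this benchmark show the pipeline is correct and that the network can learn a
smooth sequence → conformation map in a shared frame — not that the default
architecture reaches any particular accuracy on experimental structures.

Sequence identity between members is ~95% within a family and ~80–90%
across families, so the benchmark's identity-based splits exercise the same
machinery as real data (default split cutoff 99%).

## Problem sizes used in the test suite

Training-dependent checks run at reduced width (`ModelConfig.small()`, plus
a 32/64-channel variant for the memorization check): 200 train / 40 held-out
examples for 30 epochs for generalization (held-out mean whole-domain
backbone RMSD < 1.5 Å); 8 examples, batch 2, learning rate 0.005, 500 epochs
for memorization (final loss < 1 Å²; the run is step-limited, not
capacity-limited, so fewer epochs plateau higher); 50 + 50 pretraining
examples and 40 + 40 transfer examples with three paired seeds for the
transfer comparison; 80 structures / 4 families for clustering recovery.
Numerical tolerances: Kabsch vs the rotation-grid + polish oracle within
1e-3 Å; rigid-motion invariance of region RMSD within 1e-6 Å; generator
determinism is bitwise.

## Known limitations

* Coordinate regression can emit locally non-protein-like geometry
  (bond-length violations, mirror backbones); only the Cα-spacing loss term
  and the mirror diagnostic address this, matching the method's scope.
  Side-chain completion is an external hook, not included.
* The identity-based split uses global alignment identity; CDR-weighted
  identity would give stricter splits for loop-focused questions.
* The hand-written numpy network trains comfortably at benchmark scale but
  is not meant for PDB-scale training runs.
* Structures with > 140 residues are rejected, matching the fixed input
  geometry.
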