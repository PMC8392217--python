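# Methods

## The model

`cpinet` predicts whether a small molecule interacts with a protein target
from three complementary views, each processed by a convolutional network
suited to its geometry:

1. **Local site descriptor.** The binding-site atoms are rasterized into an
   8-channel occupancy grid, by default 30 Å per edge at 1 Å resolution
   (shape `8 × 30 × 30 × 30`). Each atom contributes the van der Waals
   occupancy

       n(r) = 1 − exp(−(r_vdw / r)^12),

   which is ≈1 inside the vdW sphere and decays steeply outside; `n(0) = 1`
   by continuity. Per voxel and channel, contributions are aggregated with
   `max`, making the grid idempotent under duplicated atoms and independent
   of atom order. The grid passes through three 3-D convolution blocks
   (3×3×3 kernels, LeakyReLU, 2×2×2 max pooling; channels 8→32→64→128) and
   is flattened into the local feature `XL`.

2. **Global sequence descriptor.** The amino-acid sequence is fixed to 1000
   positions (suffix zero-padding, truncation beyond 1000), embedded through
   a learned 21×128 table (padding row initialized to zero), and passed
   through three 1-D convolution blocks (kernel 5, filters 64→96→128,
   LeakyReLU, width-2 max pooling), flattened into `XG`.

3. **Molecular graph descriptor.** The molecule is a heavy-atom graph with
   73-dimensional one-hot node features: atom type (44 symbols, catch-all
   `X`), heavy-atom degree (0–5), total H count (0–10), implicit H count
   (0–10), aromaticity (1). Each of three layers applies the symmetrically
   normalized propagation

       H' = σ( D̃^{−1/2} (A + I) D̃^{−1/2} H W ),

   followed by width-2 max pooling over the feature dimension; a global max
   over atoms yields a size-invariant `XM`.

The fused vector `X = [XL, XG, XM]` (fixed segment order) feeds a two-layer
head (256 hidden units, LeakyReLU, single sigmoid output). Ablations that
drop a pathway must be requested explicitly.

**Loss.** Training minimizes the class-balance-weighted focal loss over a
batch:

    y = 1:  −(N/(P+N)) · (1 − y′)^γ · log y′
    y = 0:  −(P/(P+N)) · y′^γ      · log(1 − y′)

with P/N the positive/negative sample counts of the training set, γ = 2 by
default, and probabilities clamped to [1e−7, 1 − 1e−7]. With γ = 0 and
P = N this reduces exactly to half the binary cross-entropy, a relation the
tests assert. A separate balance factor α is redundant once the P/N
coefficients are used and is not a parameter of the implementation.

## Channel typing

Published grid descriptors of this family delegate pharmacophoric typing to
an external featurizer; `cpinet` instead ships an explicit, overridable rule
table so grids are reproducible from code alone:

| channel             | rule                                                        |
|---------------------|-------------------------------------------------------------|
| hydrophobic         | C or S with no polar (N/O) neighbour                        |
| aromatic            | atom in an aromatic ring                                    |
| H-bond acceptor     | N or O with a lone pair                                     |
| H-bond donor        | N or O bonded to ≥1 hydrogen                                |
| positive ionizable  | formal charge > 0 (PDB: Lys NZ, Arg NE/NH*/CZ, His ring N)  |
| negative ionizable  | formal charge < 0 (PDB: Asp OD*, Glu OE*, C-terminal OXT)   |
| metal               | element in the metal list (Zn, Fe, Mg, Ca, Mn, Na, K, …)    |
| excluded volume     | every heavy atom                                            |

For PDB input the bonded context is resolved through a per-residue
atom-name table over the 20 standard residues (aromatic ring atoms of
Phe/Tyr/Trp/His, backbone N donor / carbonyl O acceptor, side-chain
donors/acceptors, carbons adjacent to N/O excluded from the hydrophobic
channel). Plain site-atom tables may carry their own 8 flag columns, or fall
back to element-only rules. Unrecognized elements receive only the
excluded-volume flag, with a logged warning; a metal atom never carries
hydrophobic or aromatic flags.

Van der Waals radii come from a bundled Bondi-style per-element table
(default 1.7 Å for unlisted elements), overridable by constructing
`SiteAtom` directly.

## Numerical choices

- **Grid evaluation is cutoff-free.** Occupancy is evaluated for every
  (atom, voxel) pair; at site scale (≤ a few hundred atoms) a full grid
  takes milliseconds, and exactness lets the vectorized path agree with the
  naive triple-loop oracle to 1e−10. A distance cutoff would bias far-field
  voxels by up to ~1e−7.
- **Box placement** is axis-aligned in the input frame, centered on the
  bound-ligand centroid when available, else the site-atom centroid. Voxel
  centers sit at half-integer offsets from the box corner (0-based
  indexing).
- **Convolutions are "valid"** (no padding), matching the index ranges of
  the layer equations; inputs shorter than the kernel are rejected.
- **Training** uses Adam (lr 1e−4 default, batch 16) on a small tape-based
  autodiff engine written on numpy (`cpinet.autograd`): im2col convolutions,
  argmax-routed pooling gradients, float64 throughout. Gradients of every op
  are verified against central finite differences in the test suite. One
  integer seed drives initialization, shuffling and the synthetic generator;
  ties in max pooling route the gradient to the first argmax.
- **Metrics.** ROC AUC is the Mann–Whitney statistic (ties one half),
  computed via scikit-learn and cross-checked against brute-force
  concordance counting in the tests. Per-target threshold counts use strict
  `>` at 0.7/0.8/0.9. The F1-maximizing threshold scans 0, every distinct
  score, and 1, breaking ties toward the lower threshold; predictions are
  positive at score ≥ threshold. Single-class targets are excluded from
  per-target AUC with a warning.
- **Cross-validation folds are target-disjoint**, mirroring the
  by-protein train/test split, so no protein leaks across folds.

## Architecture defaults and the small configuration

Each pathway is three blocks deep by default: 3-D channels 8→32→64→128, 1-D
kernel 5 with filters 64→96→128, GCN widths 64→96→128, and a 256-unit head
— a monotone widening pattern. Every width and depth is
configuration-overridable, as are γ, the optimizer settings, and the
ablation switches.

`NetworkConfig.small()` is the desk-scale configuration used by the
synthetic experiments and tests: a single narrow block per pathway
(8 3-D filters on a 2× average-pooled grid, 16-dim embeddings with 8 1-D
filters, one 16-wide GCN layer), global-max readouts, a 16-unit head, and
lr 1e−3. It trains in CPU minutes while exercising every operator of the
full model.

## The synthetic data generator

The generator emulates the *structure* of a virtual-screening benchmark:
per-target binding-site atom clouds (30–80 atoms in a 12 Å sphere, channel
composition drawn from per-channel element pools so the typing rules fire
deterministically), random sequences of length 50–1200 over the 20-letter
alphabet, and per-target active/decoy sets at a controlled ratio drawn from
a bundled library of 244 parseable drug-like SMILES.

Labels follow a planted rule:
`label = (site_predicate AND molecule_predicate) XOR Bernoulli(noise)`,
defaults: site predicate = metal atom present ∧ aromatic fraction ≥ 0.10;
molecule predicate = contains nitrogen ∧ contains an aromatic atom;
noise = 0. Targets alternate site-capable / site-incapable by index
(stratified), so any target-disjoint split contains both kinds: pairs on
site-incapable targets are all negative — including molecules that satisfy
the molecule predicate — which forces the classifier to use the grid
pathway, not just the molecular one. `noise = 0.5` makes labels independent
of all features (the no-signal control). All randomness descends from one
seed via per-target substreams, so target *i* is identical regardless of
how many targets are generated, and the dataset manifest fully determines
byte-identical regeneration.

What passing the synthetic recovery shows — and what it does not: it
demonstrates that featurization, the three pathways, fusion, the loss and
the optimizer can jointly recover a known composite site×molecule signal
from the exact file formats of the real path. It does not demonstrate
screening accuracy on real chemistry: synthetic sites are i.i.d. atom
clouds without covalent geometry or pockets, sequences carry no signal at
all, and decoys are not property-matched.

## Problem sizes used in the checks

The recovery experiment trains the small configuration on 8 targets × 40
pairs (320 pairs) and scores 2 held-out targets (80 pairs) for 30 epochs;
the no-signal control repeats this at noise 0.5. Operator-equivalence
checks run 100 random small instances per operator against brute-force
oracles, and metric checks run 50 random instances against concordance
counting. Benchmark bookkeeping uses the bundled 91-target active-count
table (68 train / 23 test).

## Known limitations

- No GPU path; the numpy engine is adequate for desk-scale experiments,
  not for full benchmark training.
- Channel typing is rule-based; protonation states, tautomers and
  non-standard residues beyond the table fall back to element-only rules.
- Graph "pooling" is feature-space max pooling, chosen because it keeps the
  readout size-invariant; no edge features or 3-D conformers.
- The site box is axis-aligned with no rotation augmentation; grids for
  whole proteins and binding-site *detection* are out of scope.
- The embedding table is trained end-to-end rather than fixed; non-standard
  residue letters map to the padding token.
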