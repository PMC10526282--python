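# Methods

## Problem and approach

Brain age — the age a model infers from a structural brain scan — is a
candidate biomarker: a large gap between predicted and chronological age
flags possible pathology. Deep 3D convolutional networks predict brain
age well but are expensive to train on high-resolution volumes. This
package implements the projection alternative: each 3D volume (a
gray-matter likelihood map or raw T1 intensity volume) is collapsed into
a handful of 2D *moment projections*, and a small multi-stream 2D CNN
regresses age from those images. The compression step is lossy but
retains most of the age-relevant morphology (cortical shell geometry,
ventricle size), and it shrinks the training problem by two orders of
magnitude.

## Pipeline

1. **Padding.** Every volume is zero-padded symmetrically to a common
   grid (full scale 256 × 256 × 208 voxels; the package default for
   desk-scale work is the quarter-linear-scale 64 × 64 × 52). When a
   margin is odd the extra voxel goes to the high-index side — the
   padding is only specified as "symmetric", and a fixed tie-break makes
   outputs reproducible.
2. **Projection.** For each anatomical plane (axial, coronal, sagittal)
   the volume is reduced along the plane's normal axis into per-pixel
   statistics over slices: mean and standard deviation are the six
   standard channels; standardized third and fourth moments (skew,
   kurtosis) are implemented as optional extensions but excluded from
   the default channel set. The standard deviation is the population
   (÷N) form; the slice count is fixed per plane, so the sample form
   differs only by a constant factor that the network would absorb — ÷N
   was chosen so oracle tests have an exact closed form. Projections are
   computed over the full padded extent, including all-zero slices,
   because padding precedes projection in the pipeline. No intensity
   normalization is applied at any point (a configurable flag exists in
   packing but defaults off).
3. **Packing.** All projections of a cohort are packed into contiguous
   per-plane, per-split arrays (subject × channel × height × width) that
   stay resident in memory for the whole training run — the efficiency
   argument of the approach is precisely that the entire training set
   fits in fast memory and no per-epoch volume IO happens. Plane arrays
   are separate because axial images are square while coronal/sagittal
   are not.

## Network family

Each selected plane has its own convolutional stack (identical topology;
identical weights when `iso=True`); each stack outputs 256w features
(w ∈ {0.5, 1, 2} is the width multiplier); features are concatenated and
a dense head ends in one linear node.

Stack (depth 13; depths 19/25 insert one/two extra mid-block
convolutions per block):

    6 blocks with filters 4w, 8w, 16w, 32w, 64w, 128w:
        Conv 3x3 (bias) → ReLU
        [Conv 3x3 (bias) → ReLU]           (only depths 19/25)
        Conv 3x3 (no bias) → BatchNorm → ReLU [→ Dropout 0.2]
        MaxPool 2x2 (ceil mode)
    Conv 3x3 (128w → 256w, bias) → ReLU
    global mean pool → 256w features

Batch normalization therefore lands after every 2nd (depth 13), 3rd
(19) or 4th (25) convolution, and the layer order within a unit is
convolution → batch norm → activation → dropout. Convolutions feeding a
batch-norm layer carry no bias (it would be redundant).

Head: `concat(256w · planes) → 160w → 128w → 672w → 10 → 1`, ReLU
between layers, linear output. With dropout "between dense" the conv
dropout is removed and Dropout(0.3 or 0.5) follows the first two hidden
dense layers instead; batch normalization stays in the stacks in both
placements.

### How the architecture was fixed

The layer-by-layer source listing of the original network is not
available in the extracted text we worked from, so the family was
reconstructed from the published trainable-parameter counts, which pin
it tightly:

- Writing the non-shared six-channel models as 3S + H and the iso models
  as S + H (S = one stack, H = head) gives exact per-stack and head
  counts at every width and depth. The per-stack polynomial
  S(w) = 589,680 w² + 1,084 w is matched exactly — at all three widths
  and with exact depth-19/25 increments of Σ(9 f² + f) per extra
  block-convolution — by the stack above, and by no simpler variant we
  found (the bias/no-bias pattern is forced).
- The 6ch−3ch differences (108/54/216 at w = 1/0.5/2) force 3×3 kernels
  and first-layer filter counts 4w.
- The head polynomial H(w) = 229,376 w² + 7,680 w + 21 is reproduced
  exactly by the dense chain above. The head is *under*determined by
  counts alone (an exhaustive enumeration of dense-chain structures
  found thousands of count-equivalent solutions); we chose the simplest
  all-dense, no-batch-norm chain among the exact solutions. The
  published counts are identical for both dropout placements, which
  supports keeping batch-norm parameters out of the head: moving them
  between conv and dense positions would change the totals.
- The published depth-25 *non-iso* counts are internally inconsistent
  with any stack/head split (they imply a head 74 parameters larger
  than depths 13 and 19 do, and a non-integer stack size); the iso
  depth-25 count is consistent and is reproduced exactly. We treat the
  two non-iso depth-25 numbers as a printing error; the package's
  counts for those two variants differ from the printed ones by 148.

`count_parameters` counts every trainable scalar — conv/dense weights
and biases plus batch-norm scale and shift — and counts shared stacks
once.

## Training protocol

Mean-squared-error loss on raw ages (years²), Adam with learning rate
0.003, a fixed epoch budget with no early halting, full-epoch passes in
reshuffled order, and a checkpoint written every time the validation MSE
reaches a new minimum. The best-validation checkpoint is the test-time
model. Batch size defaults to 32 (unreported in the original protocol;
exposed in `TrainConfig`). Weight initialization is Glorot-uniform,
seeded. Training is deterministic for a fixed seed on one device;
cross-device BLAS differences can change float results.

The numerical engine is a compact NumPy layer library written for this
package (`brainage2d.nn`): convolution computed as one BLAS matrix
product of the padded grid against all nine kernel taps (channels-last
layout; on a single CPU the engine is memory-bound and this avoids all
per-pixel gathers), batch normalization, max/global-mean pooling,
inverted dropout, dense layers, hand-written backpropagation and Adam.
Every backward pass is verified against central-difference gradients in
the test suite. Forward passes return explicit caches, so applying one
stack object to three planes and summing parameter gradients implements
iso weight sharing exactly (batch-norm statistics are also shared, i.e.
sharing is total).

## Augmentation

Offline, train-only: the augmented set is the original training split
concatenated with `n_copies` (default 3) perturbed copies, giving
(1+3)·n pseudo-subjects with unchanged labels. Each copy of each
subject's plane draws one transform — scale in [0.95, 1.05], shear and
rotation in ±5°, composed about the image center, followed by an
elastic deformation (Gaussian-smoothed uniform displacement field,
σ = 8 px, peak amplitude 2 px) — shared by all channels of that plane,
since a plane's mean and std images depict the same anatomy. Bilinear
interpolation, zero fill. The perturbation magnitudes are package
choices ("small" is the only guidance the protocol gives) and sit in
`AugmentationConfig`.

## Evaluation and ablation

`evaluate` reports MAE and RMSE in years and r² = 1 − SS_res/SS_tot
(SS_tot about the mean of the true ages). r² is reported as a
descriptive statistic only; its interpretation for non-linear models is
debatable and no significance testing is attached.

`run_ablation` trains one model per non-empty channel subset per
learning rate (63 subsets for six channels; the empty set is
untrainable, so a "64 combinations" protocol is read as nominally
including it) and records each run's best validation MSE. A channel's
marginal contribution is the mean of loss(S) − loss(S ∪ {c}) over all
ordered pairs with c ∉ S and S non-empty, averaged jointly over subset
pairs and learning rates. The second learning rate defaults to 0.001
(only 0.003 is stated in the protocol). Ablation subsets with unequal
per-plane channel counts cannot share stack weights, so ablation always
uses non-shared stacks.

## Synthetic phantom cohorts

The phantom generator exists so the pipeline can be exercised and tested
without restricted data; the real cohort it stands in for is not
reproducible here. A phantom is an outer ellipsoid ("brain", semi-axes
0.42 × grid, per-subject jitter ~ N(0, 0.03) per axis) containing a
high-likelihood cortical shell whose thickness shrinks linearly with age
(5 voxels at age 44, −0.08 voxels/year on the 64³-scale grid), a
medium-intensity interior (0.25), and a low-intensity central ventricle
growing linearly with age (4 voxels at 44, +0.05 voxels/year), lightly
smoothed (Gaussian σ = 0.5) with additive clipped Gaussian noise
(σ = 0.05). Ages are integers sampled uniformly on [44, 82] (1-year
resolution); splits are 70/15/15 with the test split absorbing rounding.
Because the shell region shrinks and the ventricle grows by set
inclusion when jitter is fixed, gray-matter and ventricle voxel counts
are provably monotone in age before noise — the oracle used in tests.

What the phantom does *not* emulate: cortical folding, tissue-class
mixtures, scanner artifacts and bias fields, sex differences, and the
non-uniform age histogram of a volunteer cohort. Effect sizes
(thinning/growth rates, jitter, noise) are artifact choices — there is
no published generative model of aging to copy — so passing tests show
that the *pipeline mechanics* recover a known age signal at desk scale,
not that the accuracy numbers transfer to real cohorts.

## Problem sizes and the validated phantom protocol

Unit tests run on 16³ phantoms. The scaled age-recovery check trains a
depth-13, half-width, six-channel model on a 500-phantom cohort at
64 × 64 × 52 (350/75/75 split) and requires the best-validation model's
test MAE to beat half the train-mean-predictor baseline within a
100-epoch budget.

At this cohort size the binding constraint is the generalization gap
(train RMSE ≈ 4 y vs validation ≈ 7–9 y under the full-scale protocol
of Adam at 0.003), so the scaled experiment uses the protocol selected
on *validation* MSE — the test set was never part of the selection:
offline augmentation (3 copies; spec-default affine ranges; elastic
amplitude 1 px rather than the package default 2 px, since on 64-pixel
projections a 2 px warp is comparable to the cortical-shell thickness
and acts as label noise), Adam at 0.001 (the package's second standard
rate, far more stable here than 0.003), 30 epochs, batch 32, dropout
between conv layers. Alternatives rejected on validation loss: He
initialization, weight-shared (iso) stacks, dropout between dense
layers, longer unaugmented training.

The ablation check uses 16³ phantoms (48 subjects) in which mean
channels are replaced by age-independent noise, so only std channels
carry age signal; all 63 subsets × 2 learning rates (0.003, 0.001) are
trained for 60 epochs each and every std channel must out-contribute
every mean channel.

## Known limitations

- The dense head is one of many count-equivalent reconstructions; its
  hidden sizes (160w/128w/672w/10) reproduce every published parameter
  count but are not confirmed layer-by-layer against the original.
- Exact downsampling operator (max pooling here) and activation (ReLU)
  are reconstruction choices; parameter counts cannot distinguish them.
- The NumPy engine is CPU-only and single-threaded except for BLAS; it
  is meant for desk-scale cohorts, not the full-scale dataset.
- Determinism is per-device; BLAS kernels may differ across machines.
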