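# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `ichseg`, in the spirit of a methods appendix.  Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Preprocessing

Volumes are resampled to a fixed standard grid with linear interpolation
(nearest-neighbour for masks, so they stay binary) and then clamped to the
HU window (0, 100).  Choices worth recording:

- **Interpolation convention.** `scipy.ndimage.zoom` with `grid_mode=True`
  places output voxel centres at `(i + 0.5)/zoom − 0.5` in input index
  space (the half-pixel-centred convention), so the physical extent
  `shape × spacing` is preserved exactly; the output spacing is defined as
  extent divided by the target grid.  Edge handling is `mode="nearest"`,
  which makes constant volumes exactly constant after resampling.
- **Order of operations.** Resampling precedes clamping, so interpolation
  operates on native HU values; after clamping the two orders differ only
  at tissue–bone and tissue–air edges.  The pipeline (`run_pipeline`)
  fixes this order.
- **Orientation.** NIfTI volumes are reoriented to the closest canonical
  (RAS) orientation on read.  Axis order is (x, y, z), z axial.

## Network

The segmenter is an encoder–decoder with deep supervision.  Encoder level
`l` (of `depth`, default 4) carries `base_channels · 2^l` channels and one
residual *context module* — two 3×3×3 convolutions with dropout (default
rate 0.3) between them and an identity skip — with stride-2 3×3×3
convolutions between levels.  Decoder stages upsample (nearest-neighbour
×2 followed by a 3×3×3 then a 1×1×1 convolution; a zero-stuffing
"transposed" mode is available via `upsample_mode`), concatenate the
matching encoder feature map, and refine with a localization module (3×3×3
then 1×1×1 convolution).  Segmentation layers (3×3×3 convolutions to one
channel) sit at every decoder stage; their logits are upsampled to full
resolution and merged by element-wise summation before a single sigmoid.
With `use_deep_supervision=False` only the finest segmentation layer is
used and the rest of the network is unchanged, which is what makes the
ablation a controlled comparison.

Design points that were genuinely open, and how they were resolved:

- **Merge before or after the nonlinearity.**  Logits are summed and one
  sigmoid is applied.  Summing probabilities would need renormalization
  and loses the interpretation of the merged map as a probability.
- **Which levels carry segmentation layers.**  Every decoder stage
  (levels 0..depth−2); configurable via `deep_supervision_levels`.  Level
  0 must always be present, since it alone has full-resolution features.
- **One output channel.**  The two-class label space of the loss is
  realized as (1−p, p) from a single sigmoid channel; a two-channel
  softmax head would be redundant for a binary task.
- **ReLU after the 1×1×1 convolutions** is on by default
  (`relu_after_1x1`), exposed rather than guessed.

### Normalization and initialization

The network uses **instance normalization** after the convolution of each
upscaling/localization module and in pre-activation position inside
context modules (default `use_instance_norm=True`, switchable).  This is a
deliberate trainability requirement, not an optional refinement: in a
normalization-free stack of residual blocks the activation variance
doubles at every level, the initial logits reach ±20, and with Adam — whose
first bias-corrected step is ±lr for every parameter regardless of
gradient scale — a single epoch at lr 0.005 shifts the logits by tens.
The sigmoid then saturates across the whole volume, its derivative
underflows, and the optimizer freezes in the all-background state (loss
exactly −0.5).  Three mutually reinforcing measures prevent this:

1. instance normalization keeps pre-logit activations at unit scale;
2. the closing convolution of each residual branch and all segmentation
   heads are **zero-initialized** (He-normal elsewhere), so every residual
   block starts as the identity and the initial probability map is exactly
   0.5 everywhere — a neutral starting point for the Dice loss;
3. logits are clamped to ±40 inside the sigmoid so its derivative can
   never underflow to an exact zero (Adam recovers from small gradients,
   but not from zero ones).

Initialization is seeded **per parameter name** (`seed`, CRC32 of the
name), so two builds with the same seed share identical values for every
parameter they have in common — in particular the two deep-supervision
ablation arms differ only in the extra segmentation heads.

## Training

The loss is the negated class-averaged soft Dice over L = {0, 1} with the
background class taken as (1−g, 1−p).  A perfect prediction scores −1; an
all-background prediction on a sparse mask scores ≈ −0.5.  ε = 1e−5 is
added to each per-class denominator so the expression stays defined when a
class is absent from both masks; with both classes present the
perturbation is below 1e−7 on any realistic grid.  The analytic gradient
is verified against central finite differences in the suite.

Optimization follows the reference schedule exactly: Adam with β₁ = 0.9,
β₂ = 0.999, batch size one, initial learning rate 0.005, learning rate
halved after 10 consecutive epochs without validation-loss improvement,
early stop after 50, epoch cap 500 by default.  "Improvement" means
strictly below the best seen so far; the first epoch always improves on
the initial +∞.  The plateau counter resets after each halving, so a long
plateau halves repeatedly (epochs 10, 20, ...).  The schedule is a pure
function of the validation-loss sequence (`replay_schedule`) and is
unit-tested against scripted sequences.  One master seed fans out (via
`SeedSequence.spawn`) to data ordering and dropout.

The hyper-parameter grid search enumerates the Cartesian product of depths
{3,4,5,6}, learning rates {1e−2, 5e−3, 1e−3, 5e−4, 1e−4} and dropout rates
{0.3, 0.4, 0.5} (60 cells), scores each by best validation loss under a
fixed epoch budget, and breaks ties in favour of the first cell in
enumeration order.

The **capacity test** (memorizing a single 64×64×32 phantom to Dice ≥ 0.9)
runs with dropout disabled: dropout is a regularizer whose purpose is to
impede memorization, and with only one training example per epoch it also
makes the train/evaluation gap large; the optimizer settings (Adam
parameters, lr, batch size) are the tuned ones.

## The phantom generator

The generator emulates the *structure* of a clinical head-CT dataset, not
its radiological appearance.  Each case is an ellipsoidal head with a
bright skull shell (1000 HU, clamping to the window ceiling), parenchyma
at 30 ± 5 HU, two para-midline ventricles at 8 ± 4 HU, and a hematoma of
1–2 irregular lobes at 65 ± 10 HU — inside the window, hyperdense against
parenchyma by ~35 HU, as acute blood is.  Lobes are randomly oriented
ellipsoids (radii 8–18 mm) with a smooth multiplicative boundary
perturbation (amplitude 0.3, three random low-frequency cosine modes);
with probability 0.25 a small calcification decoy (95 ± 3 HU, outside the
truth mask) is added, reproducing the classic false-positive trap for
intensity-driven segmenters.  Additive Gaussian noise (2 HU) models
acquisition noise.  The default native grid is 96×96×48 at (2, 2, 3) mm —
a downsampled analogue of a 512×512×~54 scan at (0.45, 0.45, 2.8) mm — so
that resampling into standard space is exercised.  A seed fully determines
every case.

Simulated raters perturb the true mask only within a band (default ±2
voxels) around its boundary, flipping voxels with per-rater probability
(defaults 0.08/0.10/0.12 for the three raters), optionally after a
systematic dilation or erosion (a radius drawn from a per-rater integer
range) that models over-/under-segmentation bias.  Voxel disagreement with
truth is monotone in the flip probability, which is what the agreement
machinery is tested against.

What the phantoms do **not** model: beam hardening, partial-volume
averaging at the skull base, IVH/SAH subtypes, scanner-dependent noise
texture, or anatomy beyond one head shape.  Passing tests on phantoms
therefore demonstrates that the pipeline's machinery (preprocessing,
optimization, inference, statistics) is correct and that the network can
learn hyperdensity-driven segmentation — not that clinical-grade accuracy
would be reached on real scans.

## Inference and quantification

The probability map is binarized at 0.5 with a strict `>` (a voxel exactly
at threshold is background).  Volume = voxel count × voxel volume / 1000
mL, computed in standard space by default; because the standard-space
voxel size differs slightly from native, `run_pipeline` optionally
resamples the mask back to the native grid (nearest-neighbour) and reports
both values rather than silently preferring either.

## Agreement statistics

Cohen's kappa is computed per image over **all** voxels (no cropping to a
hemorrhage neighbourhood); background dominance pushes kappas toward the
observed-agreement ceiling, which is inherent to this protocol and should
be kept in mind when reading absolute values.  Per-image kappas are
grouped (human–human vs method–human, R×N values each) and compared with a
two-sided Mann–Whitney U test (normal approximation with tie correction —
appropriate at the 30-per-group scale).  Degenerate masks: if both raters
are constant with the same label, kappa is 1 for identical masks and an
error otherwise.  The disagreement measure excludes cases where both
volumes are zero (the relative difference is undefined there) with a
warning.  The volume regression is ordinary least squares with two-sided
p-values for both slope and intercept (statsmodels).  Empty-mask overlap
conventions: a zero-denominator metric is 1 when prediction and reference
are both empty, else 0.

## Problem sizes

The default test and acceptance configurations are deliberately small so a
complete run fits in minutes on one CPU: phantom cohorts of 6–10 cases at
native 48×48×24, standard grid 24×24×16, 2 base channels, ≤50 epochs; the
capacity check uses one 64×64×32 phantom with 4 base channels; the
ablation uses 5 seeds × 30 epochs (threshold −0.6, chosen well below the
−0.5 all-background plateau so reaching it indicates genuine foreground
learning).  The architecture is identical at every scale — grid,
channel width and depth are configuration, not code paths — and
`--paper-scale` restores the 128×128×64 grid with 16 base channels.

## Known limitations

- The numpy autodiff engine is single-threaded apart from BLAS and runs
  seconds per epoch at full 128×128×64 scale with 16 base channels;
  training at that scale is possible but slow.  The engine exists to make
  the method self-contained and auditable, not to compete with GPU
  frameworks.
- Kappa's background dominance (above) compresses differences between
  raters.
- Phantom realism limits are listed in the generator section; in
  particular, reported accuracy on phantoms is not a clinical claim.
- Volumes are quantified from voxel counts only; no connected-component
  filtering or minimum-lesion-size rule is applied.
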