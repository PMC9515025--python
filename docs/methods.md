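# Methods

## The problem

Deep-learning segmentation of organs at risk (OAR) in head-and-neck (HAN)
CT is a voxel-wise classification task with an extreme class imbalance:
well over 95 % of voxels are background, and the foreground organs
themselves span about three orders of magnitude in volume (a mandible
versus an optic chiasm). Because 3D networks are trained on randomly
sampled sub-volumes (patches), two training parameters directly shape the
class distribution the loss actually sees: the **patch size** and the
**loss function's treatment of classes missing from a patch**. This
package implements the measurement and loss machinery for both, plus the
evaluation metrics and an overfitting diagnostic.

## The sigma imbalance statistic

For an epoch of sampled patches, each patch's integer class counts are
normalized to ratios (dividing by the patch voxel count) and the ratio
vectors are **averaged across patches** — the average of ratios, not the
ratio of pooled sums, so every patch carries equal weight regardless of
its size. With C classes (background included) the averaged ratios
r = (r_0, …, r_{C-1}) sum to one, so their mean is fixed at 1/C and the
population standard deviation

    sigma = sqrt( (1/C) * sum_c (r_c - 1/C)^2 )

is exactly the root-mean-square distance from the ideal uniform
distribution: sigma = 0 iff every class receives an equal share, and
sigma approaches its upper bound sqrt(C-1)/C < 1 as one class dominates.
Using sigma as a cost function over candidate patch sizes selects the
training window with minimal class imbalance for a given dataset and
sampling strategy.

Conventions, chosen where the definition leaves room and fixed in
`imbalance.py`:

- **Background is included** among the C classes. Only then does a
  background-dominated whole image produce the characteristic sigma near
  sqrt(C-1)/C (for C = 8 and a 0.97 background share, sigma ≈ 0.32), which
  is what makes the statistic sensitive to the dominant class.
- **Population (divisor C) standard deviation**, matching the
  distance-to-uniform interpretation; a sample divisor would merely scale
  all comparisons by a constant.
- Patch-size optimization evaluates every candidate with a **shared base
  seed** so candidates see identical sampling randomness; ties break
  toward the **larger patch volume** (more spatial context at equal
  imbalance).
- Candidate sizes are multiples of 2^depth per axis (a window must
  survive `depth` U-Net-style halvings), doubling from a minimum size up
  to the dataset median shape.

## Patch sampling

Three strategies are implemented, all driven by one explicit
`numpy.random.Generator` (no global state):

- `whole_image`: every "patch" is the full volume — the degenerate
  reference point with maximal imbalance;
- `uniform_random`: the patch corner is uniform over all valid positions;
- `foreground_oversampled`: with probability `oversample_fraction`
  (default 0.33, the common 33 % foreground-oversampling rule) a
  foreground class present in the volume is chosen uniformly, one of its
  voxels chosen uniformly, and the patch centred there, clipped to
  bounds; otherwise the corner is uniform. A background-only volume
  degrades to uniform sampling with a single logged warning.

Patches larger than the volume are **clipped, never padded**: the
imbalance statistic should reflect real image content, not synthetic
padding. An "epoch" defaults to 500 patches (250 iterations at batch
size 2); it is a parameter, since the appropriate count depends on the
training configuration being emulated.

## The loss family

All losses act on a softmax-normalized prediction tensor P[b, c, v] and a
one-hot ground truth G[b, c, v] (B batch items, C classes, V voxels;
(B, C, X, Y, Z) input is flattened). With eps a small stability constant
(default 1e-5):

- **Cross-entropy**: CE = −(1/BV) Σ G log P. The per-voxel normalization
  makes CE magnitude invariant to patch size, which matters when
  comparing patch-size configurations; `per_batch` restores the 1/B
  scaling. Log arguments are clamped at 1e-12.
- **Multi-class Dice**: the mean over all B·C pairs of
  (2 Σ_v P G + eps) / (Σ_v P + Σ_v G + eps), background included. A class
  absent from both tensors contributes eps/eps = 1 — scored as perfectly
  segmented. This artifact is deliberate: it is the flaw that motivates
  the class-adaptive form, and tests pin it down.
- **Batch Dice (nnU-Dice)**: sums pooled jointly over batch and voxel
  axes, background excluded, averaged over the C−1 foreground classes.
  Pooling makes a class "present" if it appears anywhere in the batch,
  reducing (not removing) the missing-class problem.
- **Class-adaptive Dice (ca-Dice)**: per-(b, c) terms
  2 Σ_v P G / (Σ_v P + Σ_v G + eps) — note eps only in the denominator —
  averaged over only the N pairs with Σ_v G > 0. Absent classes are
  excluded from the average rather than rewarded; a wrongly *predicted*
  absent class also contributes nothing here (cross-entropy carries that
  penalty). With N = 0 the score is undefined (`nan` + N = 0, not an
  error) and the combined loss falls back to cross-entropy alone.
- **Combined loss**: ce_weight·CE + dice_weight·(1 − Dice), weights
  default (1, 1). Dice scores convert to losses as 1 − score
  (`negative` gives −score).

Background handling of ca-Dice is not uniquely determined by its
definition; the default excludes it (consistent with the batch Dice) and
`include_background_in_dice` flips that.

Every loss is cross-checked against an independent triple-loop
implementation to 1e-9 on random small tensors.

## Evaluation metrics

- **DSC**: 2|A∩B| / (|A|+|B|) on hard masks; both-empty scores 1.
- **95HD**: the surface of a mask is its voxels with at least one
  face-adjacent (6-connectivity) neighbour outside the mask, the volume
  border counting as outside. Surface voxel centres are mapped to
  physical mm with the (possibly anisotropic) spacing, the two directed
  nearest-neighbour distance sets are **pooled**, and one percentile
  (default 95th, linear interpolation) is taken — symmetric by
  construction.
- **Surface Dice at tolerance tau**: the fraction of the two surfaces
  lying within tau mm of the other surface. The voxel-centre surface
  representation is a simplification of the surfel (face) formulation;
  the brute-force oracles in the tests document its exact semantics. The
  per-organ tau values from published observer studies are not bundled;
  tau defaults to 1 mm and must be supplied for any external comparison.
- **Empty-prediction policy**: a one-sided empty mask scores DSC 0,
  surface Dice 0 and a distance sentinel — `inf` by default ("a missed
  organ blows up the average", matching how published averages behave),
  or `nan` for downstream exclusion.

## Confidence drift

For each organ, the softmax probability of that organ's class is read at
its **ground-truth voxels** (default; configurable to predicted voxels) in
training and test volumes; the drift is mean(train) − mean(test).
Reading at ground-truth voxels keeps the measure independent of the
model's own decisions. A large positive drift for a class marks it as
overfitted — typically the smallest organs. Long-format exports support
violin-style plots.

## The phantom generator

`han_like_preset` builds a 7-organ phantom (128×128×64 voxels at
(1, 1, 2.5) mm; a half-scale variant for tests) whose label statistics
mimic the HAN setting: background share > 0.95 and a ≥ 100-fold voxel
spread between the mandible-like bar and the chiasm-like speck.
Intensities are arbitrary-unit but roughly CT-scaled (background ≈ 0,
soft tissue ≈ 30–40, bone ≈ 700) with Gaussian noise (sd 10) so the demo
trainer has contrast to learn from. Organs are geometric primitives
painted in list order (later wins on overlap); generation is
bit-reproducible under a fixed seed.

What the phantom does **not** emulate: anatomical shape variability,
inter-patient pose and field-of-view differences, CT physics (beam
hardening, partial volume), or inter-observer label noise. Passing tests
therefore demonstrate the correctness and qualitative behaviour of the
machinery — e.g. that sigma decreases with patch size on a
background-dominated dataset — not clinical segmentation performance.

## The demonstration trainer

The trainer exists to show the losses are optimizable and to feed the
confidence analysis with real softmax outputs at desk scale; it is not a
segmentation architecture study. The model is a **multiscale voxel
classifier**: a fixed feature pyramid per voxel (raw intensity plus
`depth` Gaussian-smoothed scales at sigma = 2, 4, …, giving local
context) concatenated with the voxel's normalized global coordinates,
followed by a trainable stack of 1×1×1 convolutions (an MLP applied per
voxel, hidden widths `channels_base`·2^level, ReLU) and a softmax.
Gradients of CE and both Dice variants are derived analytically with
respect to the softmax output and chained through the softmax Jacobian;
optimization is Adam in plain numpy, fully deterministic under a fixed
seed. A full convolutional encoder–decoder would add nothing to what the
demo is meant to show, at much higher cost and error surface.

Training samples one patch per iteration with the configured sampler
(default: 33 % foreground oversampling). The phantom task is separable by
intensity plus location, so 300 iterations on a 48³ case reduce the
combined loss to well under 25 % of its initial value for both ca-Dice+CE
and nnU-Dice+CE.

## Problem sizes and tolerances

The test suite and the acceptance script run on: 3 default-scale phantoms
(≈ 10⁶ voxels each) for sigma pipelines (n = 2000 patches at 8³, 500 at
larger sizes, 5 seeds for the ordering property), masks ≤ 12³ for
brute-force metric oracles (agreement to 1e-9 mm), 50 random tensors
(B ≤ 2, C ≤ 4, V ≤ 27) for loss oracles (1e-9), and 300-iteration
training runs on 48³ cases. These sizes make the whole suite complete in
about a minute on one CPU while leaving every qualitative claim with a
comfortable margin.

## Known limitations

- The sigma pipeline's absolute values depend on the sampling strategy
  and epoch length; published per-dataset values can only be reproduced
  with the corresponding dataset and matching sampling configuration
  (both are exposed as CLI parameters).
- Volumes with non-axis-aligned direction matrices are read but not
  reoriented (a warning is logged).
- The surface representation is voxel-centre-based; tolerance-sensitive
  comparisons against surfel-based surface-Dice implementations can
  differ near one voxel spacing.
- The trainer is a demonstration harness: no augmentation, no deep
  supervision, no sliding-window inference, batch size 1.
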