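# Methods

## Block collapsing and mean percent signal change

A run is a 4D array `(dimX, dimY, dimZ, T)` with a schedule of
non-overlapping blocks over half-open frame intervals `[start, start+n)`;
labels are `FIXATION` or one of the 5 movement classes (LH, RH, LF, RF,
T). The baseline ȳ is the per-voxel mean over **all fixation frames
pooled across the run's fixation blocks** (not per-block baselines; with a
stationary baseline the two coincide, and pooling is the lower-variance
estimate). Each movement block of N frames collapses to

    p = (Σᵢ₌₁..ₙ yᵢ) / (ȳ · N) · 100 .

Two conventions are exposed: the default `ratio` form above (baseline
block → 100) and `centered` (subtract 100, baseline → 0). The default is
the ratio form because all downstream expectations (the 100 + a closed
form, the acceptance arithmetic) are stated in it; the centered form is a
constant shift and cannot change any classifier after voxel
standardization.

**Zero-baseline guard.** Voxels with |ȳ| < 1e-8 — the air background,
where the baseline is exactly zero — get p = 0 and are recorded in a mask
returned alongside p. The threshold is far below any plausible tissue
intensity and only exists to catch exact zeros and denormals.

**Normalization.** Samples are voxel-wise z-scored with the *population*
(divide-by-n) standard deviation; the n vs n−1 choice is immaterial at
realistic sample counts but is fixed for testability. Voxels with std <
1e-8 are set to 0 after centering. Two fitting modes exist:
`all_samples` (statistics over the full sample set, fitted before the
cross-validation split — the historical behavior, which leaks test-voxel
statistics into training inputs) and `train_only` (fitted per fold on the
training 80%, i.e. train + validation subjects, applied unchanged to
test). The default is `all_samples` to reproduce the historical protocol;
the leakage-free variant is one flag away, and a test asserts that under
`train_only` no perturbation of test samples can alter any training-time
array.

## Slicing

Internally the three axes are addressed by array position 0/1/2, never by
anatomical name — the anatomical labels (coronal/sagittal/axial) are
applied inconsistently in the imaging literature, so they appear only in
user-facing text. Channels are last, `(H, W, C)`, project-wide.

* planar stack along axis a: `moveaxis(v, a, -1)`; channel c is the slice
  at coordinate c. Lossless; `reconstruct_from_stack` inverts it.
* tri-planar input: the three stacks `(dimY, dimZ, dimX)`,
  `(dimX, dimZ, dimY)`, `(dimX, dimY, dimZ)`.
* mean-value 2D: mean over axis 2.
* 1D sequence: axis-2 slices concatenated along axis 1, step
  `s = z·dimY + y` carrying the dimX voxels at (y, z) — the stated
  concatenation order pinned to an explicit index formula, length
  `dimY·dimZ`.
* SVM vector: C-order flatten, length `dimX·dimY·dimZ` (902,629 at full
  scale).

## Architectures and parameter accounting

All six models share: two stride-1 valid convolutions with 16 then 32
kernels of size 3 per spatial dim; leaky-ReLU (slope 0.3, a common
framework default — the slope affects no count and barely affects the easy
synthetic task) after each conv; non-overlapping max-pool of 2 with floor
division; batch normalization after each pool; flatten; dropout 0.5; dense
128 + leaky-ReLU + batch-norm; dense 5 + softmax. The multi-branch model
runs one 2D branch per axis and concatenates the three flatten vectors
before the head (merge width 47,712 at full scale); a single batch-norm is
placed after the merge, which is count-equivalent to per-branch
post-flatten normalization.

Two placement facts are fixed by fitting the closed-form arithmetic to the
published per-model totals, since prose alone underdetermines them:

* **valid padding with floor-halving pooling** is the unique standard
  convention reproducing the published flatten widths
  (d → (d−2)/2, floored, twice per dim);
* a **post-flatten/merge batch-norm exists in the 1D/2D/multi-branch
  models but not in the two 3D models**, and every model has one after
  the dense 128; only this placement reproduces all six totals exactly.

Parameter counts include the batch-norm running mean and variance (4
numbers per feature in total), as the published totals require. The
separable 3D variant factorizes *only the second* convolution into a
depthwise 3×3×3 stage (depth multiplier 1, **no bias**) and a pointwise
1×1×1 stage (**with bias**); the bias split is pinned by the exact
12,880-parameter difference from the plain 3D model
(27·16·32+32 − 27·16 − (16·32+32) = 12,880).

Counts are computed twice and asserted equal: a closed-form walk over the
configuration and the sum of array sizes of an instantiated model. The
property is also checked on randomized small configurations.

## The numpy compute core

`triplanar.nn` is a compact channels-last layer library written for this
package: ConvND (1/2/3-D, im2col via stride tricks), DepthwiseConv3D,
MaxPoolND (argmax-routed gradients), BatchNorm (batch statistics in
training, running statistics at evaluation, momentum 0.9, eps 1e-5),
LeakyReLU, inverted Dropout, Dense, Softmax (max-shifted; exact Jacobian
in backward), Sequential/MultiBranch containers and Adam (β₁ 0.9, β₂
0.999, eps 1e-7). Weights are Glorot-uniform in float32 from an explicit
`numpy.random.Generator`. Every backward pass is verified against central
finite differences at float32-scale tolerances.

## Training and evaluation

* Subject-wise k-fold splits: subjects are shuffled once per seed and cut
  into k test groups; 10% (≥1) of the remaining subjects are validation,
  the rest train. All partitions are disjoint by construction and a hard
  assertion rejects any overlap.
* Learning rate `0.0025 · 0.5^⌊epoch/50⌋`, Adam, categorical
  cross-entropy, batch size 32 (unspecified historically; 32 is recorded
  in run metadata and configurable).
* Checkpointing: "best validation result" is read as best validation
  *accuracy*, ties to the earliest epoch; a `monitor="loss"` switch uses
  validation loss instead.
* Early stopping: strict improvement of the running *training-loss*
  minimum, zero tolerance, patience 6 — i.e. stop after 6 consecutive
  epochs without a new minimum. The returned model is the checkpoint, not
  the final state.
* Metrics: accuracy, macro-averaged precision and F1 (classes are
  balanced, so macro ≈ micro; macro is fixed for determinism; classes
  never predicted contribute precision 0), and the 5×5 confusion matrix.
* PCA+SVM baseline: PCA to 500 components (clamped with a warning when
  the sample count is smaller) followed by a linear L2 SVM with C = 1.0
  (scikit-learn `PCA` + `LinearSVC`).
* All randomness (splits, init, dropout, batch order) derives from
  explicit integer seeds; identical seeds give identical training
  trajectories.

## Synthetic data: what it does and does not show

The generator emulates the block structure (3 fixation + 10 movement
blocks, 2 per class, order shuffled per subject), a strictly positive
soft-edged ellipsoidal baseline (1000 at the centre tapering to 300 at the
rim, 0 outside — exercising the zero-baseline guard), spherical
class-specific ROIs (radius 3 voxels by default, centres fixed per class
and chosen so every ROI lies inside the brain), multiplicative activation
of `amplitude_pct`% during that class's blocks, per-frame i.i.d. Gaussian
noise, and a per-subject log-normal gain (log-sd 0.1) that mean-PSC
cancels exactly, mimicking scanner-gain variation.

Default regime: grid 24×28×24, 12 frames per block, amplitude 30%, noise
sd 1. These were chosen once as a clearly separable desk-scale regime —
on a baseline of ~1000 with 12-frame blocks, the noise contributes only
~0.03 PSC units against a 30-unit effect — so that above-chance
classification tests are stable, and they are deliberately *easy*: at the
default the multi-branch model reaches ~100% under subject-wise 5-fold
cross-validation, and with amplitude 0 every architecture sits at the 20%
chance level. The full 91×109×91 grid is used only for building and
counting models, never for training.

Not modelled: hemodynamic response and lag, temporal autocorrelation,
motion, physiological noise, spatial smoothness of noise, anatomical
variability. Consequently, passing results on synthetic data validate the
*implementation* (shapes, arithmetic, splits, training mechanics), not
expected accuracy on real scans.

## Problem sizes and numerical choices

Desk-scale defaults keep everything on one CPU: training tests run the
20-subject regime with `max_epochs` capped (15 for the 5-fold run, 6 for
the chance check) — with the easy regime the model converges in a handful
of epochs, and at zero amplitude generalization cannot rise above chance
regardless of epochs. Models compute in float32; parameter counting is
exact integer arithmetic. Degenerate inputs are rejected early: conv/pool
shape collapse below 1, overlapping or out-of-range blocks, schedules
without fixation when a baseline is required, non-finite volumes,
non-finite training loss.

## Known limitations

* No GPU path; the numpy core is fine at desk scale but not meant for
  ~10⁴ full-resolution volumes.
* Batch-norm running statistics at small batch counts are noisy; with
  very few training steps evaluation-mode outputs can differ noticeably
  from training-mode behavior.
* The 1D-sequence and flatten orderings are fixed conventions; other
  orderings would train equivalently but break the documented index
  formulas.
* `LinearSVC` uses squared-hinge by default, one of several reasonable
  readings of "linear L2 SVM".
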