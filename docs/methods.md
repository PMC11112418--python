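# Methods

## The model

TGANet is an attention-gated convolutional classifier for single-label
tongue-feature tasks. Its backbone is the five convolutional blocks of
VGG16 — 2,2,3,3,3 convolutions of kernel 3 with channels 64,128,256,512,512,
each block closed by 2×2 max-pooling — with all fully connected layers
removed, so the backbone is fully convolutional and accepts any input whose
height and width are divisible by 32. Three feature taps feed the head: the
pooled outputs of block 2 (F₂, 128 channels at 1/4 resolution), block 4
(F₄, 512 channels at 1/16) and block 5 (G, 512 channels at 1/32).

Each of F₂ and F₄ passes through its own attention gate against G:
both tensors are projected to 256 channels by 1×1 convolutions; the
projected G is bilinearly upsampled to the intermediate feature's spatial
size; their sum U passes through ReLU, a 3×3 convolution to one channel,
and a sigmoid, giving an attention map A ∈ (0,1); the gated feature is
F′ = A ⊙ proj(F). The two gated features and G are global-average-pooled,
concatenated into a 1024-vector, and classified by one linear layer with
softmax. The classification head is swapped per task (3 / 2 / 4 classes for
color / body / coating); everything else is shared structure.

Assumptions: one tongue per image, photographed roughly upright; the
background has been removed by masking before classification; labels are
single-task integers. A `width_multiplier` scales every channel count
uniformly (attention channels included) so the same architecture can be
trained at desk scale; pretrained backbone weights can only be loaded at
full width, from a local checkpoint file.

## Segmentation

A standard U-Net produces the tongue mask: encoder levels of two 3×3
convolutions + ReLU and a 2×2 max-pool, channels doubling from
`base_channels` (default 32) over `depth` levels (default 4); the decoder
mirrors the encoder with nearest-neighbour 2× upsampling followed by a 3×3
convolution, concatenation with the matching encoder feature, and two more
convolutions. "Same" padding keeps skip connections aligned without
cropping. The output layer is a 1×1 convolution with sigmoid, trained with
pixel-wise binary cross-entropy on logits (a numerically stable,
single-channel equivalent of a two-class softmax). Predicted probability
maps are thresholded at 0.5 and reduced to their largest connected
component, since exactly one tongue is expected.

## Augmentation and class balancing

The augmentation chain is translation → rotation → additive Gaussian noise,
in that order. Shifts are whole pixels drawn uniformly and independently
per axis from [−10, +10]; angles are drawn uniformly from [−15°, +15°] and
applied about the image centre with bilinear resampling; noise is i.i.d.
per pixel with mean 0 and variance 0.1 **on the [0,1] intensity scale**
(on a 0–255 scale a 0.1 variance would be invisible), with the result
clipped back to [0,1]. Vacated pixels are zero-filled. Class balancing
upsamples every class to the largest class count by augmenting uniformly
resampled originals; originals are never modified. Balancing is applied
inside each training fold only (a flag extends it to validation folds);
augmented copies therefore never appear in the validation fold of their
source image.

## Training protocol

Classification uses softmax cross-entropy minimized by Adam at learning
rate 1e-4, 20 epochs, batch size 20. Validation accuracy is computed after
every epoch and the returned model is the best-epoch checkpoint (ties go to
the earliest epoch). Attention and head parameters are Kaiming-initialized;
the backbone is Kaiming-initialized unless pretrained weights are loaded.
Evaluation is stratified k-fold cross-validation (default k = 5): per
class, shuffled indices are dealt round-robin so fold counts differ by at
most one; fold assignment, balancing, initialization and batch order all
derive deterministically from one seed. Metrics per fold are accuracy,
macro precision/recall/F1 (zero denominators contribute 0) and macro
one-vs-rest AUC computed by the Mann–Whitney rank statistic with ties at
0.5 — algebraically the area under the ROC curve, robust to tied scores.
Fold summaries are arithmetic mean ± sample standard deviation (n−1).

Inputs are bilinearly resized to `input_size` (default 64, must be
divisible by 32) and shifted by −0.5 so the masked background maps to a
constant −0.5. Desk-scale experiment sizes used by the test-suite and the
acceptance script: segmentation 40 training / 20 held-out images at 64×64
with base width 32 and 10 epochs; classification 200 training / 48 held-out
coating images at 64×64 with width multiplier 0.25 under the full 20-epoch
protocol; the cross-validated benchmark 120 images, 3 folds, 6 epochs.

## The numerical core

No deep-learning framework is used; `tganet.nn` implements the required
operators on float32 NCHW arrays with explicit forward/backward passes:
stride-1 same-padded convolution lowered to a matrix product via im2col
(the input gradient is a convolution with the channel-transposed, spatially
flipped kernel — no scatter-add); 2×2 max-pooling with argmax routing;
bilinear resizing expressed as two separable 1-D interpolation matrices so
the backward pass is the exact adjoint; Kaiming-normal initialization; and
bias-corrected Adam. Gradients are verified in the test suite against
scipy correlation, finite differences, and the adjoint identity
⟨Rx, y⟩ = ⟨x, Rᵀy⟩.

## Synthetic data

The generator renders one ellipse-like tongue per image over a distractor
background (default: random lip/skin-coloured blobs plus gradient and
sensor noise). Class signal per task: colour — three fixed body-colour
distributions (pale red / red / dark red) with within-class jitter, chosen
to overlap slightly yet remain linearly separable from mean foreground RGB
(a logistic probe on 50 train / 50 test images exceeds 0.9 accuracy);
body shape — width-to-height ratio (≈1.18 vs ≈0.70) plus sinusoidal
boundary scalloping imitating tooth marks; coating — a thresholded smooth
noise film confined to the upper (root) third of the tongue, whose
whiteness/yellowness and coverage density (dense ≈0.85 for "greasy",
sparse ≈0.30 for "thin") carry the class. The emitted mask is the exact
raster of the analytic boundary, whose parameters are recorded per image so
the raster can be reproduced independently; the coating pixels are recorded
too. Output is bit-deterministic in (seed, class, index).

What it does not emulate: photorealistic texture, specularity, saliva,
camera pose and illumination variation, correlated labels across tasks, or
annotator noise. Passing tests on this generator demonstrate that the
pipeline's machinery — shapes, gradients, folds, metrics, training loop —
behaves correctly and that the models can extract genuinely present signal;
they say nothing about accuracy on clinical photographs.

## Attention visualization and the localization finding

Maps are upsampled bilinearly to the image grid, min-max normalized per
image (a constant map becomes 0.5 everywhere), coloured through a fixed
256-entry JET lookup table computed from the classic piecewise-linear
formula, and alpha-blended (default 0.5) onto the image.

On the synthetic coating task we quantify localization by comparing the
mean normalized attention over the coating (tongue-root) region against the
mean over the rest of the tongue, per held-out image. The comparison region
is the tongue interior because the background is masked to black and
excluded from the paper-style overlays; black-border cells also attract
spurious attention through zero-padding edge effects, which would otherwise
dominate the comparison. Under the declared experiment seed the B4 map
favours the coating region on 47/48 held-out images. However, a multi-seed
sweep of the identical experiment shows this property is
**initialization-dependent**: B4 attains a majority in 3 of 7 runs
(47, 9, 9, 6, 30, 26, 6 of 48) and the higher-resolution B2 map in 4-5 of
7 (48, 47, 22, 31, 40, 0 of 48), while held-out accuracy is 1.0 in every
run.
Interpretation: once the classifier separates the (easy) synthetic classes
perfectly, the loss applies no further pressure on where attention
settles; consistently root-focused deep attention belongs to the
pretrained-backbone, hard-data regime, not to the architecture as such.
The acceptance script therefore reports the localization fraction
recomputed at whatever seed it is given, and no part of this package
claims the property is robust.

## Numerical and design choices

- Attention map: one channel, broadcast over the 256 projected channels;
  the gated product uses the projected F (required for branch-symmetric
  fusion dimensions). Gating convolution: 3×3, padding 1.
- Fusion: global average pooling before concatenation — the minimal
  reduction producing a fixed-length vector at any input size.
- Binary masks are validated strictly ({0,1}); Dice of two empty masks is
  defined as 1.0.
- Thresholding: 0.5; probabilities exactly at threshold count as
  foreground.
- make_folds warns (not errors) when a class has fewer members than k and
  spreads the class as evenly as possible.
- AUC classes lacking positives or negatives raise in binary problems and
  are skipped with a warning under macro averaging.
- Checkpoints are single `.npz` files holding the flat parameter list plus
  a config record.

## Known limitations

- Training is single-process CPU; runtimes scale with `width_multiplier²`
  and `input_size²`.
- Float32 training is reproducible only under a fixed BLAS threading
  configuration; all declared experiments fix their seeds.
- The attention-localization property is not stable across random
  initializations at desk scale (see above).
- Pretrained VGG16 weights are supported as an explicit local checkpoint
  load only and are unused in all shipped experiments.
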