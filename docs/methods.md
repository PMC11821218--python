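# Methods

This note documents the models and procedures implemented in `dermocad`,
the parameters that matter, the synthetic data the toolkit is validated
on, and the numerical choices made where the design was genuinely open.

## Problem setting

Dermoscopic images of skin lesions are degraded by two dominant nuisance
factors: dark curvilinear hairs occluding lesion pixels, and poor global
contrast. Both hurt downstream lesion segmentation and benign-vs-melanoma
(BEN/MEL) classification. The toolkit implements a full CAD chain —

1. hair removal by grayscale morphology and neighbor repainting,
2. contrast restoration by a multiscale context aggregation network (MCAN),
3. lesion segmentation by an atrous-convolution network (ACNN),
4. classification by a compact CNN (N-DCNN),

plus dataset preparation (correlation dedup, stratified 70/10/20 split,
random oversampling, training-only augmentation) and the full
confusion-matrix metric suite. A two-arm pipeline trains the identical
classifier on raw and on preprocessed images to isolate the contribution
of stages 1–3.

## Hair removal

The image is converted to grayscale with luma weights (0.299, 0.587,
0.114). A grayscale closing (dilation then erosion with the same
structuring element) fills dark structures thinner than the element, so
`Diff = close(I) − I` is nonnegative and large exactly on thin dark
hairs. `Diff > T` with `T = 25` (0–255 scale) yields the hair mask; a
disk-radius-2 dilation bridges fragmented detections.

Choices that were open:

- **SE bank.** The element's shape is a free parameter. We close with
  four line elements of length 15 at 0°/45°/90°/135° and take the
  per-pixel maximum of the closings (DullRazor-style), since a single
  orientation misses perpendicular hairs.
- **Mask refinement.** A raw disk-2 dilation widens a 1–3 px hair mask by
  4 px, which caps the achievable mask Dice against ground truth near
  0.5–0.67 regardless of detection quality. We therefore follow the
  dilation with an erosion by the same disk (the pair is a binary
  closing): gaps are still bridged, but the mask returns to hair width.
  The refined mask is both returned and used for repainting.
- **Repainting.** Each masked pixel receives, per channel, the
  inverse-distance-weighted average of its K = 8 nearest unmasked pixels
  (k-d tree query). This is deterministic, order-independent and honors
  the "intensity of the neighboring pixels" contract; pixels outside the
  mask are returned bit-identical.
- **Boundary handling.** The closing is implemented as a max-filter
  padded with 0 followed by a min-filter padded with 255, which makes the
  dilation/erosion pair a proper adjunction on the finite frame, so
  closing is extensive and idempotent up to the border (replicate padding
  is not, and fails extensivity on random images).
- Only hairs darker than their surroundings are detected (closing is
  one-sided); light hairs are out of scope. Detection runs once, not
  iteratively.

## Contrast restoration (MCAN)

Eight multiscale residual aggregation blocks (MRABs) with dilation rates
2, 4, 6, 8, 16, 32, 64, 128, each: a 3×3 dilated convolution with 32
filters → batch normalization → leaky ReLU (slope 0.3), combined with the
identity branch through two learnable scalars,

    out = μ·x + λ·LReLU(BN(conv_r(x))),

initialized μ = 1, λ = 0, so each block starts as the identity and blends
the context branch in during training (the same zero-init-residual trick
used by ReZero-style networks). A 3×3 stem lifts RGB to 32 channels
(needed so the identity branch of the first MRAB has matching channels)
and a 1×1 regression head maps back to 3 channels. Training minimizes
mean squared error between restored and clean patches; degraded inputs
are produced by a gamma/gain intensity remap (`255·gain·(I/255)^gamma`),
re-sampled fresh every epoch. Images larger than the patch size are
processed as tiled patches and stitched back.

The loss and the initialization are not fixed by the architecture
description; MSE is the only reading consistent with a regression output
layer, and the μ/λ initialization above is our choice.

## Segmentation (ACNN)

Sixteen 3×3 conv layers in five blocks, dilation doubling per block
(1, 2, 4, 8, 16), stride 1 everywhere and no pooling, so the output
resolution equals the input resolution — the point of atrous convolution
is precisely to grow the receptive field (3 → 99 pixels here) without
resolution loss. Each conv is followed by batch normalization and leaky
ReLU (slope 0.3, reused network-wide). A 1×1 head maps to two classes
with a per-pixel softmax. Default widths per block are 16/32/48/64/64 —
the widths are a free parameter chosen for desk-scale trainability.
Training uses weighted cross-entropy with inverse pixel-frequency class
weights (a 90/10 background/lesion set weights lesion pixels 9×) under
SGDM with the defaults batch 16, lr 0.01, L2 0.005, momentum 0.9.

ROI extraction crops the mask's bounding box expanded by a margin and
zeroes pixels outside the mask; an empty mask falls back to the full
frame with a warning.

## Classification (N-DCNN)

Eleven conv blocks (3×3 conv → BN → leaky ReLU 0.3), with the middle
groups repeated 2, 4 and 2 times and 2×2 max pooling at group
boundaries. Channel schedule:

    8 | 16,16 | 32,32,64,64 | 128,128 | 128 | 2560 → GAP → dense(2) → softmax

The first layer slides 8 kernels of 3×3 over a 128×128×3 input. The final
block is a wide 3×3 feature-expansion conv before global average pooling
(the MobileNet-style "expand then pool" head); it carries most of the
weights and puts the network at 3,405,202 learnable parameters and 3,176
kernels — inside the design budget of 3.0–3.6 M parameters and 2.8–3.4 K
kernels that makes the model an order of magnitude smaller than
transfer-learned baselines. `build_ndcnn` raises if a schedule violates
the budget. Exact pooling positions and widths of the middle blocks are
free parameters; the budget is the binding constraint.

Training: softmax cross-entropy with inverse class-frequency weights
(negative log-likelihood — a loss must be nonnegative and minimized),
SGDM defaults lr 0.001, batch 32, momentum 0.99, L2 0.0005. The momentum
update is the classical velocity form `v' = γv − α∇L; θ' = θ + v'`.

## Numpy layer stack

No deep-learning framework is used: the networks run on an in-package
layer stack (`dermocad.nn`) with hand-written backward passes for
dilated convolution, batch normalization, leaky ReLU, max/global-average
pooling and dense layers. The dilated convolution is expressed as a sum
of shifted slices contracted by `einsum`, so its cost is independent of
the (possibly 128-pixel) padding. Gradients are validated against central
finite differences in the test suite; the forward pass is validated
against `scipy.ndimage` correlation with zero-inflated kernels and
against a direct triple-loop summation oracle.

Two numerical choices worth noting:

- **Batch-norm recalibration.** After very short trainings the
  exponentially averaged running statistics (momentum 0.1) lag the batch
  statistics badly, making inference-mode outputs inconsistent with
  training-mode outputs. Every training loop therefore ends with one
  full-momentum forward pass over (up to 64) training samples that pins
  the running statistics to the training distribution.
- All computation is float32; losses are accumulated in float64.

## Synthetic data

The generator renders a skin-colored background (≈ RGB 205/165/145), one
elliptical lesion with a sinusoidal radial border perturbation (three
seeded harmonics, k ∈ 3–8), Gaussian texture noise (σ = 4), and
optionally: dark hair strokes (quadratic Béziers, 1–4 px wide, drawn
without anti-aliasing so the ground-truth mask is pixel-exact), gamma/gain
contrast degradation (γ ∈ [1.5, 2.2], gain ∈ [0.85, 1.0]), and
near-duplicates (additive Gaussian noise, σ = 2, which keeps Pearson
correlation with the original above 0.99). MEL specs are darker,
multi-tone (a darker off-center patch emulating pigment-network
variation) and more border-irregular (amplitude 0.25–0.45) than BEN specs
(0.03–0.12), so the classes are separable by construction — a trivial
intensity threshold already exceeds 80 % accuracy, which is what makes
the tiny-training experiments meaningful. Every generator is a pure
function of (spec, seed).

What the synthetics deliberately do **not** model: pigment-network
texture, rulers, gel bubbles, ink markings, vignetting, multi-lesion
frames, light hairs, or the intra-class diversity of real dermoscopy.
Passing the property suites therefore shows the algorithms are
implemented correctly and behave as designed under controlled conditions;
it does not certify clinical performance, and published
accuracies on real dermoscopy archives are not reproducible at this
scale (they require the full image archive and GPU-scale training).

## Desk-scale evaluation protocols

The seeded suites in `dermocad.suites` size every experiment so the whole
battery runs in minutes on one CPU:

| suite | conditions |
| --- | --- |
| hair detection | 20 images, 128², 12 hairs of 1–3 px |
| atrous oracle | 50 random instances, rates {1,2,4,8} |
| classifier tiny-training | 60 train / 20 test clean images at 64², 15 epochs |
| segmentation tiny-training | 20 train / 10 test at 48×64, default widths, 20 epochs |
| contrast tiny-training | 30 train patches 32², 12 epochs, 20 test images 64² |
| two-arm comparison | 30 MEL + 30 BEN hairy/degraded images at 64², 3 seeds |

The two-arm pipeline uses the default 11-block classifier at 64×64 input
(the architecture is size-agnostic down to the pooling chain), a compact
8/16/16/24/24 ACNN, and an MCAN trained self-supervised on further
degradations of the dehaired training images — the pipeline never sees
the clean references.

## Known limitations

- The hair detector is dark-hair-only and tuned for 1–4 px widths at
  desk resolution; very thick or bright hairs are not handled.
- The wide expansion conv that realizes the parameter/kernel budget is a
  design reconstruction; other schedules satisfying the budget exist.
- Training determinism holds within one BLAS configuration (bit-identical
  reruns in the same environment); across BLAS builds results may differ
  in the last float digit.
- The correlation dedup is O(n²) per class and meant for desk-scale sets;
  a perceptual-hash prefilter would be needed at archive scale.
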