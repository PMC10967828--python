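# Methods

## The segmentation model

`octseg` segments a grayscale B-scan (rows = depth, columns = lateral
position, intensities in [0, 1]) into K = 5 ordered retinal regions with a
five-level encoder/decoder network plus one base stage.  Each stage is two
3×3 convolution → batch-norm → ReLU blocks; downsampling is 2×2 max
pooling, upsampling a learned 2×2 transposed convolution; a final 1×1
projection and per-pixel softmax produce class probabilities.  Channels
double per stage from `base_channels` (default 16, so 16→256 with a
512-channel base).

Two departures from the plain U-Net:

**Residual skips.**  The max-pooled pixel of every 2×2 window is already
processed by the deeper stages, so the skip path carries the feature map
with exactly that argmax pixel zeroed per window (ties break to the first
position in row-major window order — determinism needs a rule).  Scattering
the pooled values back into the zeroed positions reconstructs the input
exactly; the test suite asserts this identity on random maps.

**Hybrid attention.**  Skips 1–2 (shallowest) pass an edge-attention gate;
skips 3–5 a spatial-attention gate.

* *Edge attention.*  The skip map is enhanced with its edge response
  `F = x ∗ K_t + x ∗ K_l`, the 3×3 Sobel transverse/longitudinal derivative
  pair — the gradient operators inside the Canny detector.  The full Canny
  pipeline (non-maximum suppression, hysteresis) is not differentiable and
  is not used.  By linearity the two convolutions are computed as one
  convolution with the summed kernel; true-convolution semantics (kernel
  flip) are pinned by a delta-input test, and padding replicates the border
  so that zero-sum kernels annihilate constants everywhere.  Fusion of the
  enhanced edges with the initial features is addition.  The gate itself is
  the additive-attention construction of the attention-U-Net lineage —
  1×1 convolutions on the enhanced skip and on the (nearest-upsampled)
  deeper decoder feature, ReLU, 1×1 projection, sigmoid — because the
  coefficients α ∈ [0, 1] are specified but their computation is not; the
  block is a swappable component.  The block returns α ⊙ enhanced.
* *Spatial attention.*  Channel-wise max and average maps are stacked into
  a 2-channel tensor (the padding step that makes the two pooled maps
  stackable), passed through a sigmoid, and reduced to a single broadcast
  map by the channel mean — the mean keeps the block parameter-free, which
  is all the stated operations support.  The input is scaled elementwise by
  the map; every coefficient lies strictly in (0, 1).

Ablation layouts: A places the attention blocks inside the encoder stages
(self-gated, since no decoder feature exists there), B inside the decoder
stages, C uses edge attention on all five skips, D spatial attention on all
five; `baseline` removes attention entirely but keeps the residual skips
and channel schedule, giving the no-attention comparator of identical stage
capacity.

## Training protocol

Loss = α·CE + β·DiceLoss + γ·EdgeCE with weights (1, 0, 1).  CE is mean
per-pixel sparse categorical cross-entropy; DiceLoss (the β slot, default
off) is 1 − mean soft Dice; EdgeCE restricts CE to pixels within 2 px
(Chebyshev, via dilation of the 4-neighbour label-change map) of a label
boundary, the term that targets edge fidelity.  The α/γ reading of the
weight triple is a documented interpretation: the protocol names the
weights but binds them to a single stated loss.

AdaBound is implemented from its defining update rule (Adam moments with
per-parameter step sizes clipped into bounds that converge to
`final_lr = 0.1`; `gamma = 1e-3`, betas 0.9/0.999), since the optimizer is
part of the method and no framework supplies it here.  Initial learning
rate 0.001, batch size 4.  "Improvement" everywhere means a strict decrease
of validation loss below the best-so-far minus 1e-6; the plateau scheduler
multiplies the rate by 0.1 after 5 consecutive non-improving epochs
(counter resets on improvement or reduction), early stopping fires after
10, and the two policies share one improvement notion.  Every 100 epochs
the weights of the best validation-Dice epoch (ties broken by least loss)
are restored before continuing; 300 epochs is a hard cap.  Scheduler and
early-stop counters are preserved across checkpoint restorations.  6-fold
cross-validation splits are seeded permutations cut into folds whose sizes
differ by at most one.

## Synthetic phantoms

The generator emulates the structure the segmenter assumes: five ordered
tissue bands separated by four smooth non-crossing boundaries (cumulative
positive gaps for the mean depths, low-pass-filtered Gaussian wobble with a
configurable amplitude, default 4 px, clamped and order-enforced per
column), per-band mean reflectivities (defaults 0.05 / 0.65 / 0.45 / 0.85 /
0.25: dark vitreous, bright inner retina, medium outer retina,
hyperreflective RPE complex, dim choroid), multiplicative Gaussian speckle
(1 + N(0, σ), σ = 0.10, clipped to [0, 1]), and with probability 0.2 one
dark elliptical fluid-like pocket that darkens intensities but never
relabels pixels — the five classes are regions, fluids are intensity
anomalies inside them.  Every image/mask pair is a pure function of
`(seed, index)`.

What the phantoms do *not* model: physically accurate OCT speckle
statistics, vessel shadows, curvature/foveal pits, pathology-specific
lesion shapes, annotation noise, or 3D context.  Passing tests therefore
demonstrate that the pipeline is correctly implemented and can learn
layered geometry — not that the model reaches any particular accuracy on
clinical scans.

## Pre-processing and augmentation

Conditioning: strip all-black margins (rows/columns entirely below 1/255 —
robust to 8-bit quantization), bilinear-resize to 512×256 (rows×cols;
masks follow with nearest-neighbour and are never smoothed or equalized),
grayscale by channel mean, Gaussian smoothing (σ = 1 px, reflect borders),
then CLAHE.  CLAHE is implemented directly — per-tile 256-bin histograms
clipped at `clip_limit` × the uniform height (excess redistributed
uniformly), CDF look-up tables, bilinear blending between the four
surrounding tile mappings — because the single-tile case must reduce
exactly to global histogram equalization, which a brute-force oracle test
asserts.  Defaults (σ = 1, clip 2.0, 8×8 tiles) are the de-facto standard
values; none are printed anywhere authoritative, and all are exposed in
config.

Augmentation applies exactly nine named transforms per image — vertical
flip, horizontal flip, random snow, CLAHE, blur, invert, coarse dropout,
downscale, equalize — keeping each original, a ×10 expansion.  Masks are
transformed only by the two flips; the seven photometric transforms return
the mask byte-identical.  Parameter defaults follow the Albumentations
dialect for these names (snow threshold `snow_point·0.5 + 85/255` with
brightness ×2.5, box-blur kernel 3–7, eight 8×8 zero-filled dropout holes,
downscale ×0.25 with nearest resampling, CLAHE clip drawn from 1–4 on an
8×8 grid), adapted to single-channel float images.  Every stochastic choice
is a pure function of the augmentation seed, the source index and the
transform name.

## Evaluation

All headline statistics derive from one pooled (micro) pixel-level K×K
confusion matrix; per-image macro means are reported alongside.  Per class:
precision TP/(TP+FP), recall TP/(TP+FN), F1, Dice 2TP/(2TP+FN+FP); zero
denominators return 0 with a degeneracy flag rather than NaN so aggregation
stays stable.  Boundary IoU — no standard formula exists for the quoted
metric — is computed per class as the IoU of the two boundary bands
(pixels within a Euclidean disk of radius 2 px of the class contour, where
a contour pixel is a region pixel 4-adjacent to a non-region pixel and the
image frame does not count), averaged over classes present in the truth.
Agreement statistics: accuracy (trace/total), Hamming loss (1 − accuracy),
Cohen's kappa ((Po−Pe)/(1−Pe), Pe from marginals), Bennett's S
((Po − 1/K)/(1 − 1/K)), Bangdiwala's B in its marginal-product form
(Σnᵢᵢ²/Σrᵢcᵢ), the adjusted Rand index by pair counting on the contingency
table, and chi-squared degrees of freedom (K−1)².  Each is verified to
1e-10 against a first-principles brute-force oracle and, for kappa/ARI/
accuracy, against scikit-learn on expanded labelings.  Strength-of-
agreement labels use the Landis–Koch bands for the chance-corrected
statistics and the conventional B bands for Bangdiwala.

## Problem sizes and numerical choices

The engine runs float32 for training and preserves float64 inputs for
oracle tests; all layer gradients are checked against central differences.
The test suite and the acceptance script exercise learning at reduced,
CPU-friendly sizes chosen as the package's study conditions: the
convergence check trains a base-8-channel hybrid on 200 phantoms at 128×64
for 6 epochs and asserts held-out mean Dice ≥ 0.90, and the
attention-versus-baseline comparison repeats 10 seeded runs of both models
on 96 phantoms at 64×32 for 6 epochs each.

## Known limitations

* The attention-versus-baseline comparison, as computed by the acceptance
  test and script, currently favours the *no-attention* baseline on the
  synthetic phantoms: the hybrid wins only a minority of the seeded
  repeats (the script reports the exact count).  The phantom classes are
  separable by per-band intensity alone, so skip gating can only attenuate
  information there, and the Sobel enhancement responds strongly to the
  artificial holes that residual-skip zeroing punches into every pooling
  window.  Whether the hybrid's advantage emerges on real pathological
  scans at full training scale is outside what these phantoms can show.
* Reported full-scale accuracies from the literature require the real
  annotated dataset and GPU-scale training; nothing here reproduces them.
* The generator's speckle is a first-order surrogate; CLAHE and
  augmentation parameter defaults are conventional choices, not fitted
  values.
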