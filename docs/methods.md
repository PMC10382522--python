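# Methods

This note documents the models, numerical choices and limitations behind
`focalseg`, in the order data flows through the package.

## Focus measures

All nine operators are pure functions of a 2-D window, computed in double
precision regardless of input dtype. Design choices where the classical
definitions leave room:

- **Brenner** uses the lag-1 horizontal difference (not the lag-2 variant
  found elsewhere in the autofocus literature); the threshold θ on the
  squared difference defaults to 0 and is exposed as
  `MetricParams.brenner_theta`.
- **Vollath (F4)** sums the lag-1 autocorrelation over columns 1..W−1 and
  subtracts the lag-2 sum over columns 1..W−2; the lag-2 sum is empty for a
  2-column window. The score can be negative for adversarial inputs; on a
  constant window of value c it equals N·c² (asserted in tests).
- **Std** is implemented as printed in the autofocus literature as an
  autocorrelation-based contrast statistic, Σ i(x,y)·i(x+1,y) − HWµ², *not*
  as √variance. The out-of-range x+1 access at the last column is resolved
  by replicate-edge padding so a constant window scores exactly 0 and the
  measure is a pure contrast statistic; valid-region summation is available
  via `valid_only=True`.
- **Tenengrad** and **Laplacian** use valid-region convolution (no padding)
  so border pixels of small windows cannot inject artefacts; the Laplacian
  is the separable pair of 1-D [1, −2, 1] stencils per axis.
- **Entropy** uses 256 equal-width bins spanning the dtype range for
  8/16-bit integer windows (scores comparable across windows of one image)
  and the observed min–max range otherwise.
- **DWT** is a single-level orthonormal Haar decomposition; the score is the
  L2 norm of the concatenated LH/HL/HH detail bands over the L2 norm of the
  LL band, defined as 0 for an identically zero window.

Each metric is validated against an independent literal-loop transcription
of its defining sum (exact for integer inputs) and against qualitative
physics: monotone decrease under growing Gaussian blur of the Shepp–Logan
phantom, intensity-shift invariance (variance, Brenner), and the expected
scaling laws under intensity scaling (c² for the quadratic measures, c for
SMD, invariance for entropy and the DWT ratio).

## Sliding-window scan and fusion

A square window anchors on a lattice `0, s, 2s, …` plus one anchor flush
with each border, with the same stride in both axes; the window's scalar
score is painted over its footprint. Overlapping contributions are
**averaged** by default: averaging centres the score transition on the true
in-focus boundary, whereas keeping the pixelwise max (available as
`overlap_rule="max"`) dilates high-scoring regions by up to a full window
footprint, which favours recall over boundary precision. When the stride
exceeds the window size the lattice leaves gaps; uncovered pixels keep a
score of 0 and full coverage is restored by the multi-configuration fusion.

Raw maps from different window sizes live on incomparable scales (window
sums grow with window area), so each configuration's map is min–max
normalized to [0, 1] (a constant map degenerates to all zeros, not NaN)
before the **pixelwise maxima projection** across configurations. The fused
map is order-invariant and bounded in [0, 1].

Window sizes must scale with the field of view. The `ScanConfig` default
ladder (64/128/256 windows, 16–128 strides) matches ~2048-px micrographs;
`ScanConfig.for_shape` builds the equivalent ladder for other sizes —
windows spanning 1/16, 1/8 and 1/4 of the shorter side with strides of a
quarter window up to two windows (16/32/64 and 4/8/16/32 on a 256-px
slice). The scan itself reduces the derivative- and statistic-based metrics
to integral-image box sums, so its cost is essentially independent of the
number of windows; summation-order differences from a per-window evaluation
are at the 1e-10 relative level (tests compare at rtol 1e-8).

## Masking

Otsu's threshold (256 bins, via scikit-image, cross-checked in tests
against an exhaustive between-class-variance search) binarizes each fused
map with a **strict** comparison, `value > threshold`; a constant map
yields an all-false mask. IoU between two empty masks is defined as 1.0 so
a correctly all-false prediction on a fully out-of-focus slice scores
perfectly. Masked-out voxels are zeroed (not NaN) for viewer
compatibility. No morphological clean-up is applied between thresholding
and export.

## Synthetic focal stacks

The generator emulates a low-NA stereomicroscope focal series of a bulk
specimen. Geometry defaults: 20 planes, 8.55 µm apart (≈171 µm axial
range), 256×256 px at 0.79 µm/px.

- **Texture** (`filtered_noise`): white noise smoothed with a σ = 1 px
  Gaussian, min–max scaled to [0, 1] — fine speckle near the resolution
  limit, textured everywhere (focus is only observable where there is
  texture; the Shepp–Logan phantom, with its flat interior, is available as
  an alternative and is what the blur-monotonicity checks use).
- **Depth surface** (`smooth_random` default): a Gaussian random field with
  96 px correlation length, quantized by area-quantiles into three depth
  strata at 0, 0.5 and 1.0 of the axial range occupying 25 / 20 / 55 % of
  the field. This terraced geometry models bulky anatomy whose structures
  sit at distinct depth strata, and it is what gives focus-score histograms
  their bimodal in/out structure; the stratum areas put the first slice
  mostly out of focus and the last mostly in focus. A continuous
  `tilted_plane` ramp and a `flat` surface (used for monotone-sharpness
  stacks) are also available.
- **Blur model**: slice z renders each pixel with a Gaussian of
  σ = `sigma_per_um` · |z·Δz − d(y,x)| px. The default growth rate
  0.05 px/µm gives ~0.4 px per z-step and ~8 px at the far end of the
  stack. A pixel counts as in focus while σ ≤ `sigma_in_focus` = 2.25 px,
  i.e. a depth of field of ±45 µm (±5 z-steps), so each stratum stays in
  focus over a run of consecutive slices and ground-truth runs are
  contiguous per pixel.
- **Rendering**: spatially varying blur is approximated by a bank of 9
  uniformly blurred copies with nearest-σ assignment (quantization step
  ≈ 1 px; ground truth uses the exact σ). Slices with spatially uniform σ
  (flat surfaces) are rendered with the exact σ instead, which keeps
  axial sharpness strictly monotone for those stacks. Additive Gaussian
  noise defaults to 1 % of the dynamic range.

What the generator does **not** model: a physically correct widefield PSF
(defocus rings, spherical aberration), depth-dependent magnification,
scattering, refractive-index structure, or out-of-focus light *addition*
(real widefield slices contain haze from other planes, not just blur).
Passing tests therefore demonstrate the pipeline's behaviour under
idealized defocus blur, not performance on real micrographs.

## U-Net surrogate

Architecture: 3 encoder stages (3×3 conv + ReLU, 2×2 max pool), a
bottleneck conv, 3 decoder stages (nearest-neighbour ×2 upsampling, skip
concatenation with the mirror encoder stage, 3×3 conv + ReLU) and a 1×1
sigmoid head; channel widths 256-128-64-32-64-128-256 at full width, scaled
by `width_multiplier` (CPU experiments use 0.03125 → 8-4-2-1-2-4-8,
1622 parameters). No normalization layers, in keeping with the minimal
architecture. Inputs must be divisible by 8; `predict_stack` reflect-pads
and crops automatically. The parameter count is a pure function of the architecture
and pinned in tests.

The implementation is self-contained NumPy in float32: im2col convolutions
as BLAS matrix products, explicit per-layer gradients (verified against
numerical directional derivatives), and an Adam optimizer. Determinism is
bit-level given the config seed.

Training: total loss = focal (γ = 2, α = 0.25) + Dice (ε = 1e-6 smoothing)
+ binary cross-entropy, each weight 1 by default; probabilities are clamped
to [1e-6, 1−1e-6] inside the losses. Adam at 0.001, batch 16 for
pre-training on weak labels and batch 1 for fine-tuning, at most 1000
epochs with early stopping (patience 50 on validation loss; training loss
when no validation set is given) and best-weights restoration.
Augmentations are the eight dihedral transforms (flips and 90° rotations),
applied jointly to image and mask so the label semantics are preserved.
Pre-training inputs are square tiles cut from the slices (64 px in the CPU
experiments); whole slices of any /8 size can be predicted directly.

Scaled-down experiment sizes, chosen to keep the full suite in CPU-minutes:
weak-label training uses 64×64 tiles from 14 of the 20 slices of one
synthetic stack (32 tiles held out for validation, slices 16–19 never seen)
for at most 45 epochs; the single-image overfit check runs 1000 epochs on
one mixed-focus tile. Under these conditions the surrogate reaches held-out
IoU ≈ 0.9 against its weak labels and one stack inference runs ~2–3× faster
than the rule-based scan on the same core — the direction of the speed
claim, not an absolute benchmark.

## Known limitations

- The Std-pipeline IoU of ~0.75–0.85 on synthetic stacks is bounded by the
  window-footprint smear at stratum boundaries; sub-window boundary
  precision is not attainable with footprint painting.
- The surrogate is trained per-stack in the CPU experiments; cross-specimen
  generalization is untested here (it would require the real data path:
  many stacks, larger width, longer training).
- The scan's integral-image fast path accumulates box sums in float64;
  for windows with variance ~1e-9 of the squared mean, cancellation can
  reach the 1e-8 relative level — the per-window fallback (used for the
  entropy and DWT metrics) does not share this behaviour.
- `Vollath` and `stddev` mix autocorrelation lags across the replicate
  padding boundary only in `stddev`'s default mode; with `valid_only=True`
  the two use the same valid-pair convention.
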