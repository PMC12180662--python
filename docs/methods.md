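# Methods

## Overview

`sliceflow` localizes anomalies in 3D volumes (the motivating application is
brain MRI) by modelling the distribution of *normal* per-voxel features with
a conditional normalizing flow. Training uses only normal volumes; no
anomalous example or annotation is ever seen. The pipeline is:

1. **Slice encoding.** Each axial slice is passed through a frozen 2D CNN
   backbone; feature maps from two intermediate stages (default taps: layers
   2 and 3) are locally averaged over a p x p neighborhood (p = 3), bilinearly
   upscaled to the shallower tap's resolution (H0, W0), concatenated, and
   mean-pooled along the channel axis to a target embedding dimension
   (512 at full scale).
2. **Depth aggregation.** Per-slice feature grids are stacked and each
   voxel's vector is replaced by the mean over a centered window of w slices
   (default w = 3, replicated at volume ends; w = 1 disables aggregation).
   The mean is permutation-invariant within the window.
3. **Conditional flow.** A RealNVP-style stack of affine coupling layers
   (default 8; each subnet is two linear layers with one ReLU) maps each
   d-dimensional feature vector to a standard-normal latent, conditioned on
   a fixed 2D sinusoidal code of the voxel's (h, w) grid position. The
   log-likelihood is
   `log p(x) = -d/2 log(2 pi) - ||phi(x)||^2/2 + log|det dphi/dx|`.
4. **Anomaly synthesis and losses.** During training, anomalous features are
   synthesized by adding i.i.d. Gaussian noise N(0, sigma^2), sigma = 0.06.
   The objective is the mean negative log-likelihood of normal features plus
   an unweighted contrastive boundary term on the scalar log-likelihoods:
   a triplet loss with margin tau = 1 by default; boundary-guided
   semi-push-pull (hinges around the beta-th percentile of normal
   log-likelihoods, beta = 10) and pairwise ranking are available, as is
   disabling the term entirely. One volume's feature vectors form one batch;
   optimization is Adam at learning rate 0.001.
5. **Scoring.** Each voxel's anomaly score is `s(x) = 1 - exp(log p(x))`.
   The image (slice)-level score is the maximum voxel score in the slice.
   Pixel-level evaluation min-max normalizes within each volume, computes
   metrics per volume, and averages across volumes; slice-level evaluation
   normalizes across the whole dataset and pools all slices.

## Backbone adapters

The reference extractor is the ImageNet-pretrained wide 50-layer residual
network with width factor 2 (68.88 million parameters; the count is computed
from the architecture layout and checked in the tests). This package builds
the architecture and can run its forward pass, but ships no pretrained
weights; a weights file can be supplied. Before anomaly training, the
backbone can be adapted to the target imaging domain by encoder-decoder
contrast (EDC): a transposed-convolution decoder mirroring the tapped stages
reconstructs the encoder's feature pyramid from its deepest tap, and both are
trained with a global cosine distance whose encoder-branch targets are
stop-gradients; gradients reach the encoder only through the decoder's input.
The adaptation set must be independent of the training/test subjects. After
adaptation the encoder is frozen.

For CPU-scale runs and all tests, a small seeded CNN pyramid (`tiny`; four
3x3 conv+ReLU stages, taps at strides 4 and 8) replaces the wide backbone.
Because its weights are random apart from the EDC adaptation, the EDC stage
matters more at this scale than with a pretrained network: it is what makes
feature quality reproducible across seeds rather than an initialization
lottery.

## Numerical choices

- **Log-space score handling.** `s = 1 - exp(log p)` is faithful pointwise,
  but trained flows produce log-likelihoods spanning hundreds of nats, so the
  exponentiated score spans hundreds of orders of magnitude. Two operations
  are therefore performed on `log p`, which orders voxels identically
  (`s` is strictly decreasing in `log p`): (a) bilinear upscaling of the
  low-resolution score grid to the input resolution — interpolating the
  exponentiated scores would let one extremely normal neighbor swamp an
  anomalous cell; and (b) the min-max normalizations and all threshold sweeps
  inside the evaluators — min-max over a range of 1e50 collapses every
  informative value onto 1.0 in float64, destroying the ranking the metric
  is supposed to measure. `AnomalyMap` carries both the Eq-style scores and
  the underlying log-likelihood map; exp is capped at 700 to avoid float64
  overflow (affecting only the relative order of overwhelmingly normal
  voxels).
- **Score-map smoothing.** The low-resolution log-likelihood grid is
  Gaussian-smoothed within each slice (sigma = 1 grid cell by default)
  before upscaling, the usual anomaly-map smoothing of embedding-based
  detectors; it suppresses single-cell noise spikes that would otherwise
  dominate the per-slice maximum statistic.
- **Global feature standardization.** Features are shifted/scaled by a
  single scalar mean and standard deviation computed on the training
  features, so the embedding has unit scale. The noise SD sigma = 0.06 and
  margin tau = 1 are calibrated for unit-scale pretrained embeddings;
  without this, their meaning would silently depend on the backbone's output
  scale. Being a single affine map, it changes no rank ordering within or
  across volumes.
- **Coupling-layer details.** Alternating-half affine couplings with a fixed
  seeded channel permutation per layer, undone at the layer's exit so an
  identity-initialized flow (final subnet linear map zeroed) is exactly the
  identity transform. Log-scales are soft-clamped, `s <- 1.9 tanh(s/1.9)`,
  bounding the per-layer log-det. Training uses float32 parameters; a
  hand-written backward pass (verified against the autodiff engine to 1e-12)
  keeps volume-sized batches affordable on one CPU.
- **Gradient clipping.** The contrastive terms occasionally spike by two
  orders of magnitude on heterogeneous volume batches; the global gradient
  norm is clipped at 10 to keep Adam's moment estimates sane.
- **Tail parameter averaging.** With one volume per batch, the final
  parameters inherit substantial last-step noise; the detector averages the
  flow parameters over the last two training epochs (stochastic weight
  averaging; `avg_epochs`, 0 disables). This markedly reduces run-to-run
  variance of downstream metrics without changing the training dynamics.
- **BG-SPP boundary.** The percentile boundary b_n is treated as a constant
  of the batch during differentiation (the gradient of an order statistic is
  ill-defined at ties).
- **Eq-sign convention.** The training objective is the standard negative
  log-likelihood (minimized); one printed form of the objective in the
  source literature carries an extra leading sign, which is not followed.
- **Degenerate inputs.** Constant volumes rescale to all zeros; constant
  score maps normalize to all zeros; zero-division threshold metrics return
  0 with a logged warning; empty-mask volumes are excluded from pixel-level
  averaging with a logged count.

## Synthetic phantoms

The phantom generator emulates skull-stripped, registered, [0,1]-rescaled
axial brain volumes: a soft ellipsoidal head with concentric intensity
structure, smooth per-subject warping plus low-frequency intensity texture
(both scaled by `deformation_scale`, default 1.5 voxels), and i.i.d. voxel
noise (SD 0.02). Anomalous volumes add 1-3 ellipsoidal lesions with radii
3-6 voxels and additive contrast 0.35, smoothed with a 1-voxel Gaussian so
the lesion border is a genuine transition zone; the ground-truth mask marks
voxels shifted by more than half the contrast. Every volume is a pure
function of `(seed, index)` with separate substreams for structure, noise
and lesions, so cohorts extend without reshuffling and switching one source
of randomness off does not change the others.

What the phantoms do *not* model: MR physics (bias fields, coil profiles),
multi-modal contrast, anatomy beyond a deformed ellipsoid, pathology other
than compact intensity blobs, and scanner-to-scanner distribution shift.
Passing the synthetic benchmark therefore demonstrates that the pipeline's
machinery — encoding, aggregation, density estimation, scoring, evaluation —
recovers planted anomalies under realistic nuisance variation; it does not
certify clinical performance.

## The desk-scale benchmark

`sliceflow.benchmark.run_phantom_benchmark` trains the full pipeline at a
size chosen for a single CPU: 32x64x64 volumes, tiny backbone adapted by EDC
for one epoch on all slices of 3 normal phantoms from a disjoint cohort,
64-dim embedding, 4 coupling layers with hidden width 128 and a 32-dim
positional code, 6 epochs over 20 normal training volumes, evaluated on 10
anomalous + 10 normal held-out volumes. Pixel-level AUROC is typically
0.92-0.97 and slice-level AUROC 0.83-0.91 across seeds; with tail-averaged
parameters the triplet variant consistently improves pixel AUPRC over the
no-contrastive ablation, and w=3 depth aggregation over w=1 — without the
averaging, single-checkpoint evaluation buries these effects in run-to-run
noise at this scale.

## Known limitations

- No pretrained weights are bundled; full-scale results depend on supplying
  an ImageNet-pretrained wide-residual checkpoint.
- The flow conditions on in-plane position only (matching the slice-based
  design); depth position enters solely through the aggregation window.
- The PRO metric integrates to a false-positive-rate cap of 0.3 (community
  convention); thresholds are subsampled to at most 2048 quantiles on large
  inputs.
- Aligned pairing is the default for the pairwise ranking loss (linear cost);
  the full cross product is available via `prl_pairs="full"`.
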