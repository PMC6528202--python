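# Methods

## Problem and model

The package learns a mapping from retinal landmark masks to color fundus
photographs with conditional adversarial training. A generator *G*
receives a conditioning image — by default the three-channel stack of
vessel-tree, optic-disc and optic-cup masks — and emits an RGB image; a
discriminator *D* receives the channel-concatenation of conditioning and
a candidate photograph and emits a spatial map of patch-level real/fake
probabilities. The adversarial value function is the standard min–max
objective; we train on its decomposition into

* discriminator loss: −E[log D(c, x)] − E[log(1 − D(c, G(c)))]
  (binary cross-entropy against labels real = 1, fake = 0), and
* generator adversarial loss, in two variants: the *literal* minimized
  quantity E[log(1 − D(c, G(c)))], kept for exact-formula tests, and the
  *non-saturating* form −E[log D(c, G(c))] used as the training default
  because the literal form has vanishing gradients while the
  discriminator is winning.

Logarithms are natural; losses are reported in nats.

For paired training the generator objective adds a global L1
reconstruction term with weight λ = 0.5:
*L(G) = L_adv + λ·E‖x − G(c)‖₁*. The L1 term is computed between the
target and G(c); a formulation in which G is additionally conditioned on
the target image itself would make the reconstruction problem trivial
and is treated as a typo. For unpaired training two generator/
discriminator pairs are kept and the objective is
*L = L_GAN(G₁,D₂,A,B) + L_GAN(G₂,D₁,B,A) + λ·L_cyc(G₁,G₂)* with the
cycle term E‖G₂(G₁(a)) − a‖₁ + E‖G₁(G₂(b)) − b‖₁ and λ = 10 (the
customary weight for this objective; no value is prescribed by the
paired recipe, which fixes only λ = 0.5).

An optional MSE-only warmup (`mse_warmup_iters`, default 0) can
initialize the generator with a pure L2 regression phase before
adversarial updates begin. An alternative reading of "MSE
initialization" — replacing the BCE adversarial objective with a
least-squares one — is possible but not implemented; the warmup reading
keeps the documented BCE formulas exact.

## Architectures

All four generator families squash their output through tanh to
[−1, +1]; masks are mapped {0,1} → {−1,+1} and 8-bit images
[0,255] → [−1,+1] on the way in (channel order: vessel, disc, cup — any
fixed order works, this one is pinned and tested).

* **U-net** — encoder of stride-2 4×4 convolutions (channel widths
  doubling per level, capped at 8× the base width), decoder of
  nearest-neighbour upsampling + 3×3 convolution, skip connections
  concatenated at every resolution level, feature normalization and
  ReLU/LeakyReLU(0.2) activations. Input H and W must be divisible by
  2^depth; violations raise a configuration error naming the constraint.
* **ResNet-6 / ResNet-9** — 7×7 stem, two stride-2 downsampling
  convolutions, 6 or 9 residual blocks at the bottleneck width, two
  upsampling stages, 7×7 head.
* **ResU-net** — the U-net skeleton with each per-level convolution
  group replaced by 1–3 residual blocks at that level's width (widths
  identical to the base U-net). The originating description of this
  hybrid is ambiguous about the exact substitution; "replace each
  two-convolution group per level with n residual blocks" is the
  reading implemented here, chosen as the most literal one, and the
  block count is exposed as a parameter (1 is the best-performing count
  in the source experiments).
* **Residual block** — x + F(x) with F = conv3–norm–ReLU–conv3–norm.
  There is no post-addition activation, so zeroing every branch
  parameter makes the block an exact identity; this limit is asserted in
  the tests.
* **Patch discriminator** — stride-2 4×4 conv/norm/LeakyReLU stack
  (widths 64→512 at the default base width, 4 layers), 3×3 head, sigmoid
  output. Depth and receptive field are not prescribed by the source
  description beyond "convolution stack ending in a sigmoid"; the patch
  formulation is the established reading for this family of models. The
  sigmoid output is clamped to (10⁻⁶, 1 − 10⁻⁶) so log-losses stay
  finite; at zero weights every output is exactly 0.5.

Normalization uses batch statistics over (batch, height, width) per
channel with running estimates for inference; at the default batch size
of 1 this coincides with instance normalization, which is how "batch
normalization at batch size 1" is made well-defined. Weight
initialization is zero-mean Gaussian, std 0.02, from an explicit seeded
generator. Dropout is deliberately absent everywhere.

### Compute backend

The networks run on `fundusgan.nd`, a compact reverse-mode autodiff
engine over float32 NumPy arrays (im2col convolution, nearest-neighbour
upsampling, channel concat, activations, the normalization above, Adam).
Its gradients are verified against central finite differences, and the
convolution against an independent correlation routine, in
`tests/test_nd.py`. This keeps the package dependency-light and makes
every experiment bit-reproducible on CPU.

## Training recipe

Adam with learning rate 2·10⁻⁴, β₁ = 0.5 ("momentum 0.5" is read as
Adam's first-moment coefficient, its conventional name in the cited
frameworks), β₂ = 0.999; batch size 1; constant learning rate (a linear
decay option exists but defaults off, since no schedule is prescribed
beyond the initial rate); 200 epochs by default. Per batch the
discriminator steps first on the detached fake, then the generator steps
through a fresh discriminator forward pass; the order is fixed for
reproducibility. Unpaired training permutes each domain independently
per epoch and runs max(|A|, |B|) iterations per epoch, cycling the
shorter domain. All shuffling, sampling and initialization derive from
the config seed; identical (dataset, config) reproduce identical loss
histories. No augmentation is applied by default: the
resize-from-286-to-256 step used with real datasets is implemented as a
plain resize, and an optional resize-then-random-crop jitter flag is the
place to add the augmentation reading of that step.

## Fundus phantom

The phantom supplies paired data with exact ground truth so the whole
pipeline is testable without clinical images. Geometry: a fundus circle
(radius 0.95 of the half-width); an optic disc (default radius
0.14 × image size, placed upper-temporally) that must fit inside the
fundus circle; a concentric cup of radius round(CDR × disc radius),
CDR ∈ (0, 1), so cup ⊆ disc holds by construction and the
equivalent-radius ratio √(area_cup/area_disc) recovers the requested CDR
within 5% for disc radii ≥ 20 px (rasterization dominates below that).
Discs are circles by default with an optional axis-ratio parameter.

Vessels grow as recursive binary trees from roots on the disc boundary
(2–4 roots chosen by the seeded stream, or a fixed count via
`n_vessel_roots`), heading radially outward with ±32° branching, a
per-segment angle jitter (default 18°), stroke width decaying by 0.8 per
level from a root width of image size / 48, and segment length decaying
by 0.82 from 0.34 × fundus radius. Each root's tree is connected;
the union of several root trees need not be one connected component.
With the default parameters the vessel foreground fraction lies in
[0.02, 0.20] across seeds (checked over 100 seeds), bracketing the
vessel density of real fundus photographs. Defaults were calibrated once
against that envelope and then frozen.

Rendering paints fixed-color layers in order — dark exterior (8,8,8),
reddish-orange base field (175,95,45) with a radial vignette falling to
70% at the rim, disc (220,170,100), cup (245,215,150), vessels
(105,30,25) on top so they remain visible inside the disc — then adds
Gaussian pixel noise (std `noise_sigma`, default 5 gray levels) and
clips to [0,255]. The fixed palette makes region statements exact at
zero noise (cup brighter than disc rim brighter than base field; vessels
darker in green), which the tests assert. Per-sample randomness is
spawned from the dataset seed by sample index, so datasets are
bit-reproducible and generation could be parallelized per sample.

What the phantom does *not* emulate: camera optics and realistic
texture, artery/vein distinction, tortuosity statistics of real
vasculature, pathology (exudates, hemorrhages), inter-image illumination
variation. Consequently, passing phantom-scale tests demonstrates the
*mechanics* of the pipeline — that the encodings carry or destroy the
intended information, that the models can fit paired data, that metrics
are computed correctly — not clinical realism of the synthesized images.

## Conditioning encodings and the ablation

`compose_mcml` is lossless: splitting the 3-channel stack returns the
three masks exactly. `fuse_one_channel` paints disc at gray level 128
and vessel at 255 over a 0 background in one channel; a vessel pixel
inside the disc is then indistinguishable from one outside, and the test
suite exhibits two distinct (vessel, disc) pairs with identical fused
encodings. `vessel_only` is the single-mask baseline of earlier
vessel-to-fundus synthesis work.

The mechanism experiment (`fundusgan.experiments.encoding_ablation`)
makes the conditioning difference measurable at desk scale: 8 phantoms
share one vessel tree while disc/cup position, radius and CDR vary, so
the vessel channel carries no information about disc placement. After
identical short training (40 epochs, ResU-net base width 8, depth 3,
64×64), the vessel-only model necessarily outputs the same image for
every sample (asserted), so its disc-region L1 cannot fall below the
level of a sample-independent predictor; empirically it lands at or
above the dataset-mean image's level, while the multi-channel model
falls well below it at every tested seed. This is the scaled-down
analogue of the qualitative disc/cup-region comparisons that motivate
multi-channel conditioning.

## Metrics

SSIM follows the canonical windowed formulation: 11×11 Gaussian window
(σ = 1.5), k₁ = 0.01, k₂ = 0.03, data range 255, covariance normalized
by the window weights. Color images are scored per channel and averaged
(a grayscale mode via luminance weights is available; which mode a given
publication used is often unstated, so both are exposed and color is the
default). PSNR = 10·log₁₀(range²/MSE) pooled over pixels and channels.
The implementation wraps scikit-image and is checked against an
independent brute-force per-window implementation to 10⁻⁶, plus closed
forms (uniform +5 offset → 20·log₁₀(255/5) ≈ 34.151 dB; constant images
100 vs 150 → ≈ 0.92309). Identical pairs yield an explicit +inf PSNR
sentinel, excluded from directory means with a warning rather than
capped. Region-restricted SSIM crops to the ROI bounding box, discards
windows not fully inside it, and averages the SSIM map weighted by the
ROI mask; for rectangular ROIs this equals plain SSIM of the crops.

## Problem sizes and numerical choices

Tests and the reproduction script run at 64×64 (32×32 for the smallest
unit tests) with narrow networks (base widths 4–16), chosen so each
experiment demonstrates its mechanism in seconds to a couple of minutes
on one CPU; headline-quality synthesis at 256–512 px with width-64
networks and 200-epoch schedules uses the same code paths but is a
GPU-scale undertaking outside the test envelope. Reference points at
desk scale: the single-pair overfit run (ResU-net, one block, width 16,
300 iterations, seed 0) reduces reconstruction L1 to ≈ 0.11 of its
starting value; the conditioning ablation separates multi-channel
(≈ 0.17–0.20 disc-ROI L1) from vessel-only (≈ 0.35–0.46) at seeds 0–2.
Numerical conventions: float32 arithmetic; sigmoid clamp 10⁻⁶;
normalization epsilon 10⁻⁵; Adam epsilon 10⁻⁸; binarization threshold
127 (midpoint, idempotent on {0,255} masks); nearest-neighbour resizing
for masks and bicubic for photographs, direct resize without padding.

## Known limitations

* Training at realistic resolutions is slow on the NumPy backend; the
  package is an instrument for studying conditioning and architecture
  choices, not a production image factory.
* Batch sizes > 1 are supported but the normalization then mixes batch
  statistics across samples, which changes training dynamics relative to
  the batch-1 default.
* The unpaired (cycle) path is exercised at toy scale in the tests;
  its statistical behaviour at realistic scale is not characterized
  here.
* Checkpoints store weights and architecture spec but not optimizer
  state; training cannot be resumed mid-run, only restarted.
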