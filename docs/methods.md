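# Methods

`virtstain` implements a two-stage virtual H&E staining pipeline for
histology tiles, together with the synthetic data, objectives, and metrics
needed to exercise it end to end on a CPU.

## Problem setting

Paired supervision for virtual staining — an autofluorescence image of an
unstained section plus a pixel-aligned H&E image of the same section — is
expensive to collect, and in the regime this package targets the two pools
are heavily unbalanced (hundreds of stained tiles, a few dozen unstained
ones). The pipeline therefore proceeds in two stages:

1. **Stage 1 (unpaired):** learn a stained→unstained translator from
   unpaired pools, and run it over the stained pool to *manufacture* an
   aligned paired dataset.
2. **Stage 2 (paired):** train a conditional image-to-image generator on
   those pairs to perform the actual virtual staining
   (unstained → stained).

## Stage 1: domain-consistency CycleGAN

The base game is a CycleGAN: generators G₁ (stained→unstained) and G₂
(unstained→stained), least-squares patch discriminators per domain, and the
two-sided cycle reconstruction ‖G₂(G₁(x))−x‖₁ + ‖G₁(G₂(y))−y‖₁. Two
modifications address the failure mode seen when the target domain is
feature-sparse (hole/cavity artifacts in generated tiles):

- **Input buffers + domain-consistency networks.** Each domain keeps a
  bounded FIFO buffer (default capacity 256; tests use smaller) refilled
  every step with heavily augmented real tiles. An auxiliary two-input
  discriminator C per direction receives two buffered same-domain tiles as
  a "same" pair and (buffered tile, generated tile) as a "mixed" pair. As a
  min–max objective written with squared terms the maximizing player's
  payoff is unbounded, so the trainable form here is the least-squares
  convention: C minimizes (C(same)−1)² + (C(mixed)−0)², the generator
  minimizes (C(mixed)−1)². The published min–max form is available as an
  `as_printed=True` audit mode of `domain_consistency_loss`.
- **Separable-convolution generator.** The default stage-1 generator
  replaces the residual blocks of the Johnson architecture with
  Xception-style blocks (depthwise then pointwise convolution) and removes
  instance normalization from the body; up/down-sampling convolutions are
  depthwise-separable as well. Per-channel normalization interacting with
  residual summation is the suspected cause of the hole artifacts, so the
  redesign both removes the normalization and strengthens cross-channel
  mixing. The instance-norm residual generator is kept as the ablation
  baseline (`build_resnet_generator`).

The augmentation chain used to fill the buffers is: random jitter
(translation), horizontal/vertical flips, jitter rotation (bilinear upscale
by a zoom factor, rotate a small uniform angle, center-crop back), and
elastic deformation (Gaussian-smoothed uniform displacement field, scaled
by α, bilinear resampling with reflected borders). Identity settings
short-circuit each step, so the identity policy is a bit-exact no-op —
a property the tests rely on.

Architectural note: the domain-consistency network downsamples each input
three times with stride-2 separable convolutions, concatenates the two
feature stacks, and reduces them with 1×1 convolutions to one channel.
Because 1×1 kernels cannot change spatial size, its 1/8-resolution map is
center-cropped to the patch critic's analytic output size (e.g. 30×30 for a
256×256 input) so the two discriminators share one output contract.

## Stage 2: PFFN with WGAN-GP, L1 and feature matching

The stage-2 generator is the Parallel Feature Fusion Network (PFFN):

- an average-pooling pyramid (window = stride = 2^(s−1)) produces scales
  8…256 for a 256-pixel tile (proportionally fewer for smaller tiles);
- each scale passes through a FromRGB module — three parallel sampling
  branches (stride-2 convolution, average-pool + convolution, max-pool +
  convolution), concatenated and fused by a 1×1 convolution to the
  network-wide feature width (512 by default; reduced in tests) at half the
  scale's resolution;
- each scale then feeds a UNet-style extractor whose depth is tied to scale
  (8/16 → depth 2, 32/64 → depth 4, 128/256 → depth 6). Besides the
  conventional same-level skips, each encoder level sends an extra
  (average-pooled) skip to the decoder level one step deeper — a pruned
  UNet3+ pattern; deeper fan-out is omitted because the subnets are
  shallow;
- a fusion decoder merges the per-scale features coarse-to-fine
  (upsample, concatenate, 1×1 fuse, refine), ending in a 3-channel head
  with tanh onto [−1, 1].

The conditional critic is a 70×70 patchGAN over the channel-concatenated
(condition, target) pair; it exposes its five per-layer activations for the
feature-matching loss. The stage-2 objective is

    L = L_adv + λ_pix · E‖y − G(x)‖₁ + λ_fm · (1/N) Σᵢ ‖Dᵢ(x,y) − Dᵢ(x,G(x))‖₁

with `adv_variant` selecting WGAN-GP (default), non-saturating logistic +
R1, or least-squares adversarial terms. The gradient penalty interpolates
only the target image (the condition is held fixed) with per-sample
ε ~ U(0,1), and penalizes (‖∇_x̂ D(x, x̂)‖₂ − 1)². R1 penalizes the squared
gradient norm at real samples, weighted γ/2.

## Parameters and defaults

| parameter | default | notes |
| --- | --- | --- |
| λ_gp | 10 | WGAN-GP penalty weight |
| λ_pix | 100 | pixel L1 weight (pix2pix convention) |
| λ_fm | 10 | feature matching weight |
| λ_cyc | 10 | cycle weight (stage 1) |
| λ_dc | 1 | domain-consistency weight (stage 1) |
| γ_R1 | 10 | R1 weight for the logistic variant |
| optimizer | Adam, lr 2e-4, β = (0.5, 0.9) | GAN practice |
| critic steps | 1 | per generator step; configurable |
| feature width | 512 | PFFN channel convention; 32 or less in tests |
| buffer capacity | 256 | stage-1 input buffer, FIFO |

None of the loss weights or optimization hyper-parameters are prescribed by
the problem itself; the values above are the community-standard choices.
`critic_steps=1` (rather than the 5 often used with WGAN-GP) keeps
CPU-scale runs inside reasonable wall-clock budgets and proved sufficient
for the desk-scale convergence checks; it is a single config knob.

## Numerical substrate

No GPU autodiff framework is assumed: the networks run on `virtstain.nn`, a
compact numpy reverse-mode engine whose vector-Jacobian products are
themselves built from engine primitives, so `grad(..., create_graph=True)`
yields differentiable gradients. This is the property the WGAN-GP and R1
penalties require (the critic loss contains an input-gradient norm that is
itself differentiated during the critic update). Convolution is expressed
as im2col + matmul; im2col and its adjoint col2im are mutually-defined
primitives, giving arbitrary-order derivatives through convolutions. The
engine is verified against central differences, including a second-order
check through a convolutional gradient-penalty term. Everything runs in
float64; a 300-step stage-2 run at the test scale takes on the order of a
minute on one CPU core.

## Synthetic histology

The generator emulates the statistical structure the method assumes without
any real data: elliptical nuclei (Poisson count at a chosen density,
uniform centers, random axes/orientation) surrounded by a cytoplasm halo
(the nucleus ellipse scaled 2.2×). The default dataset regime is 400
stained and 80 unstained tiles, unpaired — the unbalanced-pools situation
stage 1 exists to handle. Two renders share each geometry:

- **stained:** H&E-like palette (blue-purple nuclei, pink cytoplasm, bright
  background) plus clipped Gaussian noise (default σ = 0.02 in [0,1]
  units);
- **unstained:** a single intensity field (bright cytoplasm at
  `fluor_gain`, nuclei quenched to 40% of it, dark background) times a
  fixed RGB tint, making the three channels exact scalar multiples of each
  other — inter-channel correlation 1.0 before noise, which encodes the
  near-monochrome assumption about autofluorescence. That assumption is
  ours; the channel statistics of real autofluorescence are not
  characterized in the source material.

The tumor-class label (K = 4) tints the *entire* stain palette slightly
(a class-dependent color cast applied to nucleus, cytoplasm and
background). An earlier design tinted only the cell colors, but tiles that
happen to contain no nuclei then carry no class signal at all, making the
label unidentifiable on sparse tiles; the global cast guarantees every
stained pixel is informative, which is what lets a small classifier reach
high held-out accuracy at desk scale.

What this synthetic world does *not* model: optics (PSF, vignetting),
stain variability across labs, tissue texture inside cells, spatial class
structure (the class is a tile-level property). Passing tests therefore
demonstrate that the machinery — objectives, architectures, training
dynamics, metrics — behaves as specified, not that the method reaches
clinical quality on real slides; the published clinical-scale metric values
require the original private data and GPU-scale training and are out of
scope here.

## Evaluation

FID is computed from pluggable embedders (raw/pooled pixels for
self-contained tests; a trained classifier's penultimate features in the
full pipeline) as ‖μ₁−μ₂‖² + tr(Σ₁+Σ₂−2(Σ₁Σ₂)^½), with covariance over n−1
and the matrix square root via eigendecomposition of the symmetrized
product S₁^½S₂S₁^½ (negative eigenvalues clipped at a −1e-8 relative
tolerance, larger violations raised as errors). IS is the exponentiated
mean KL between conditional and marginal class distributions; the Mode
Score is exp(E[KL(p(y|x)‖p*(y))] − KL(p̄(y)‖p*(y))) against the real
marginal, which reduces to IS when the marginals coincide. A
lower-is-better reading of raw IS is only coherent as proximity to the real
data's score, so reports also carry `is_gap = |IS_fake − IS_real|`.

The visual-simulation harness trains a reduced convolutional classifier
(two strided conv layers, global average pooling, linear head, on tiles
average-pooled to 16×16) on labeled stained tiles and measures the fraction
of generated tiles classified as their source tile's label. A
permuted-label control should sit at chance (1/K).

## Degenerate inputs and tie-breaks

- Generator upsampling uses nearest-neighbour resize followed by a
  convolution (resize-conv) rather than transpose convolution; the choice
  was open, and resize-conv avoids checkerboard artifacts.
- Zero-density geometries render as constant background tiles; all
  operations accept them.
- `max`-pooling breaks ties by first argmax (numpy convention).
- The gradient-penalty norm adds 1e-12 under the square root to keep the
  derivative finite at zero gradient.
- Checkpoints store all network parameters plus the constructor
  configuration; loading reproduces forward passes bit-for-bit.
- All randomness flows from per-component `numpy` generators seeded from a
  single run seed by fixed offsets; identical (config, seed) runs produce
  identical logs and artifacts on one device.

## Known limitations

- Desk-scale widths (feature width 8–32 in tests) are far below the
  512-channel default; convergence behavior at full width is not exercised.
- Stage-1 runs in the test suite are short (~100 steps); they verify the
  training signal points the right way (output statistics move toward the
  target domain), not full convergence.
- The numpy engine is single-device and unbatched across devices; it is a
  verification substrate, not a performance claim.
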