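# Methods

## The model

`virtmihc` maps 4-channel autofluorescence (AF) images of unstained tissue
(DAPI, FITC, TxRed, Cy5 filter channels) to brightfield-equivalent stained
images.  One conditional generator serves three stains; the stain is
selected by a *digital staining matrix* (DSM): a constant conditioning
plane concatenated with the AF channels, carrying the code −1 (ERG),
1 (PanCK) or 2 (H&E).  Codes are fed to the network raw — the encoding is
treated as literal input values, not normalized or one-hot expanded.

Three networks are trained jointly:

- **Generator G** — an attention U-Net: 4 encoder levels, each a
  3-convolution residual block (with a convolutional residual path and
  Leaky-ReLU slope 0.1) followed by 2×2 max pooling that halves the
  spatial dimensions and doubles the channels; a bottleneck residual
  block; 4 decoder levels with 2× bilinear upsampling and additive
  attention gates (3 convolutions + sigmoid) on the skip connections; a
  final residual block and a 1×1 convolution to 3 channels.  Input is
  5 channels (4 AF + DSM); spatial dims must be divisible by 16.
- **Discriminator D** — a convolution stem to 64 channels (Leaky ReLU),
  five 2-convolution residual blocks whose second convolution strides 2
  and doubles the width, global average pooling and two dense layers
  producing a realism score.  D is conditioned on the stain by
  concatenating the DSM as a fourth input channel; the sigmoid is folded
  into the stable binary cross-entropy, so D returns a logit.
- **Registration module R** — a residual U-Net taking the generator
  output and the target (6 channels) and predicting a 2-component
  per-pixel displacement field.  Default depth is 7 encoder/decoder pairs
  (inputs divisible by 128, satisfied by 512-pixel training crops); the
  bottleneck doubles the channels, applies 3 residual blocks and halves
  them again.  The output convolution is zero-initialized so training
  starts from the identity warp, and carries a fixed x10 output scale
  (flow-network practice: adaptive optimizers bound per-step weight
  motion, so an unscaled head cannot reach multi-pixel fields in short
  runs).  The scaled-down preset uses depth 4 and predicts the field on
  an 8x-coarser grid with bilinear upsampling to full resolution —
  staining-induced distortion is smooth at large scales, and the coarse
  parametrization conditions few-step optimization.

The warp operator "∘" resamples an image along the field with bilinear
interpolation and border replication, in pixel units, (row, col) order,
gather semantics (output samples input at x + T(x)).  It is
differentiable in both the image and the field.

## Objectives

With coefficients α, β, γ = 10, 10, 10⁻⁴ and λ, μ = 20, 10, φ = 1:

    l_G = α·L_φ(target, G∘T) + β·BCE(D(G, c), 1) + γ·TV(G)
    l_D = BCE(D(G, c), 0) + BCE(D(target, c), 1)
    l_R = λ·L_φ(target, G∘T) + μ·SMTH(T),   T = R(G, target)

L_φ is the Huber loss normalized by the pixel count (per channel, then
averaged over channels — the channel reduction is a choice; the printed
form is single-channel).  TV is a *raw sum* of absolute forward
differences while the Huber term is a mean; the scale mismatch is
deliberate and compensated by γ = 10⁻⁴.  SMTH is the mean squared forward
difference of the field, summed over its two components.  TV and SMTH use
interior forward differences only (no padding).  BCE is computed from
pre-sigmoid logits in softplus form for stability.

Gradient routing: in l_G the field T is a constant (gradients flow
through the warp into G's output but not into R); in l_R only R's
parameters receive gradients (G's output enters detached); l_D touches
only D.  The schedule is 4 generator updates (each with a riding R
update) per discriminator update.  All three use Adam; the full-scale
preset keeps library-default moments (0.9, 0.999) while the scaled-down
preset uses (0.9, 0.99) — with only a few hundred steps, the 1000-step
variance memory of beta2 = 0.999 lets one early gradient spike freeze a
network for the rest of the run.  Moment accumulators are kept in
float64 because float32 squared-gradient accumulators can overflow.

## Numerical backend

The networks run on a small reverse-mode autodiff engine written on numpy
(`virtmihc.autodiff`): tape-based, NCHW layout, im2col convolutions,
2×2 max pooling, matrix-form bilinear 2× upsampling, and a differentiable
grid sampler for the warp.  Gradient correctness is enforced by
finite-difference checks in the test suite (float64, tolerance 1e−4
relative).  Training tensors are float32.

## Tissue phantoms

The phantom module replaces the proprietary TMA imagery with a generative
tissue model in which every evaluation statistic has known ground truth.
One latent geometry per tile: stromal background with occasional
background gaps, smoothed-blob epithelial regions, vessels (a circular
lumen ringed by small endothelial nuclei with enforced spacing so DAB
connected components never merge under closing), and non-overlapping
elliptical generic nuclei (semi-axes 2–5 px by default).  A smooth
multiplicative *tissue-density* field (Gaussian-filtered noise,
amplitude 0.25, correlation length ≈ 6 px) modulates both AF intensities
and chromogen uptake — emulating the shared intensity texture of real
tissue, and giving registration and the generator a dense learnable
signal that piecewise-flat phantoms lack.  Default chromogen depths:
H&E — hematoxylin 0.9 on nuclei, eosin 0.35/0.55 on stroma/epithelial
cytoplasm; ERG — DAB 0.8 on endothelial nuclei; PanCK — DAB 1.0 on the
epithelial mask (strong diffuse cytoplasmic staining); both IHC recipes
use a clearly visible hematoxylin counterstain (0.7) as in routine
practice.

Stains are rendered by the Beer–Lambert model rgb = exp(−Σ c_k·v_k) with
the classical hematoxylin/eosin/DAB optical-density vectors (unit norm;
configurable per recipe).  Natural-log optical density is used on both
the rendering and deconvolution sides so the round trip is exact; the
recovered concentrations are therefore in natural-log OD units (a factor
ln 10 larger than decadic conventions — masks are unaffected).  The H&E
recipe places hematoxylin on nuclei and eosin on stroma/epithelial
cytoplasm; ERG places DAB only on endothelial nuclei; PanCK places DAB
only on the epithelial mask (cytoplasm plus nuclei inside epithelium),
each over a hematoxylin counterstain.

AF rendering is a linear compartment mixture (DAPI bright on nuclei,
FITC on stroma, TxRed on epithelium, Cy5 on vessel lumina) times the
density field, plus optional Gaussian noise (default sd 0.02 for training
cohorts).  No attempt is made to model real fluorophore spectra; only the
relative contrast between compartments matters for learning.  Phantom
generation is a pure function of (spec, seed).

Misalignment fields emulating staining-induced distortion are
Gaussian-smoothed random vector fields, normalized to a chosen maximum
amplitude (capped at 10% of the image side so the warp stays invertible).
The default correlation length is half the image side: chemical
processing distorts tissue at large scales, and at this smoothness the
field's SMTH cost is small against the Huber gain of re-alignment.

What the phantoms do *not* model: real fluorophore emission spectra and
bleed-through, optical aberrations, scanner color profiles, staining
artifacts beyond smooth distortion, and the histological diversity of
real thyroid cores.  Passing tests therefore demonstrate that the
framework's machinery (conditioning, registration-in-the-loop, metrics)
behaves correctly, not that the model reaches clinical image quality.

## Presets and scaled-down experiments

The `paper` preset carries the full-scale settings (512×512 crops, base
width 64, depth-7 R, Adam 2e−5/2e−6/2e−6, batch 4, 4:1 schedule); it is
configuration only — a 72-hour GPU run is outside the scope of this
package.  The `tiny` preset is the scaled-down study used by the tests
and the acceptance script: 64×64 tiles, base width 8, depth-4 R
(coarse-grid displacement head), batch 4, the same loss coefficients and
schedule, Adam 1e−3 (G) / 1e−4 (D) / 1e−3 (R) with moments (0.9, 0.99),
and a linear generator output head (a sigmoid head saturates at this
scale, which freezes backpropagation through the encoder; outputs are
clipped to [0, 1] at inference).  These settings were calibrated on
pilot runs of the phantom task and then frozen.

Three initialization choices matter for short-run stability and are
used at every scale: the last convolution of each residual block starts
at zero (identity-dominant initialization, the standard substitute for
normalization layers in norm-free networks), the discriminator's final
dense layer starts at zero (D opens exactly at chance with zero input
gradient, so early adversarial pressure on G reflects learned
discrimination rather than the random initialization — without this the
β = 10 adversarial term swamps the small Huber residuals at desk scale),
and the registration head starts at zero (identity warp).

Scaled-down problem sizes: multiplex training uses 12 training phantoms
(×3 stains) and 4 held-out phantoms at 64×64, 500 generator updates;
the registration-recovery experiment uses 8 texture-rich phantom pairs
(35 small nuclei per tile) misaligned by known smooth fields of 4 px
amplitude, trained for 300 steps.

## Evaluation

PSNR uses the peak of the histochemical reference (not a fixed dynamic
range), MSE with W·H normalization pooled across channels; identical
images report infinite PSNR as a documented sentinel.  SSIM is computed
on luminance with the standard Gaussian window (σ = 1.5) and stabilizing
constants.  The perceptual distance is a layer-weighted mean squared
distance of unit-normalized feature maps behind a pluggable extractor
interface; without a pretrained backbone the metric is reported as
absent, and an identity extractor (degenerating to normalized MSE) exists
for offline testing.  DAB masks come from Otsu's threshold followed by
dilation then erosion (disk radius 2, configurable; the order follows the
published description).  Nuclei statistics use 8-connected components with a
4-pixel minimum component area (single-pixel specks from noise leaking
through the deconvolution are not nuclei; the floor is configurable and
0 gives the raw count).
D-IoU mean-pools masks over non-overlapping 8×8 blocks, binarizes at
> 0.01, and defines the empty/empty case as 1.  Paired comparisons use
the standard two-tailed paired t-test, with an infinite-statistic
sentinel for zero-variance nonzero differences.

## Design choices where the design was open

- Generator output activation: sigmoid to [0, 1] (switchable to linear).
- Generator base width 64 (unstated at full scale); 8 in the tiny preset.
- Discriminator conditioning by DSM channel concatenation.
- No normalization layers anywhere (the architecture description lists
  only convolutions, residual paths and activations).
- Residual-block kernels 3×3; residual paths are 1×1 convolutions.
- R trained jointly from scratch (no pretraining), one R update per
  generator update.
- Tiling at inference: 64-px overlap with cosine feathering; weights sum
  to one, so zero-overlap tilings stitch bit-exactly.
- Checkpoints store all parameters, Adam moments, step counter, config
  and RNG streams, so interrupted runs resume bit-identically.

## Known limitations

GAN quality at 500 CPU steps is far below the published full-scale
model; held-out SSIM thresholds in the acceptance tests certify that the
multiplexing and registration machinery learns, not clinical fidelity.
The D-IoU zero-padding path slightly dilutes blocks at ragged borders.
Spatially varying DSMs (micro-structured staining) are exposed only as an
experimental input and are untested.
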