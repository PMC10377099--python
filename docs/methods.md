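# Methods

## Model

The fusion operates on Z ≥ 2 co-registered single-channel slices with values
in [0, 1] (a structural MRI-like slice and the BT.601 luminance of a
pseudo-colored PET-like slice, in the standard two-modality case). A
VGG-style convolutional trunk — stacked 3×3 convolutions with ReLU and 2×2
max pooling between the five convolution blocks — provides deep features; a
tap at block b returns the ReLU output of the block's last convolution,
before that block's pooling, so block b has spatial side
ceil(side / 2^(b−1)).

Per tapped block and per source: the feature stack is collapsed to a single
activity map (channel mean by default; channel sum available), upsampled to
image resolution, and the per-pixel softmax across sources converts
activities to convex weight maps that sum to one at every pixel. Each source
is passed through a transposed-convolution enhancement layer, and the
block-level fusion is the weighted sum of the enhanced sources. The final
image is the per-pixel maximum over the block-level fusions, clipped to
[0, 1].

Assumptions: inputs are already registered (the preprocessing module offers
morphology, integer shift, rotation, and kernel sharpening for residual
conditioning, with zero-magnitude alignment defaults); intensities are
comparable after each modality is mapped to [0, 1]; and the fusion weights
need only *relative* feature activity, which is why untrained-but-fixed
convolution weights suffice.

## Parameters that matter

| parameter | default | meaning / rationale |
|---|---|---|
| `backbone.variant` | `vgg19` | trunk topology (vgg11/16/19); deeper variants change channel widths and parameter counts, not the fusion algebra |
| `backbone.weights_source` | `fixture` | seeded He-normal weights, zero biases; deterministic and offline. `pretrained` (ImageNet via torchvision, with channel mean/std normalization) raises a clear error when that stack is absent |
| `backbone.tap_blocks` | `{1}` | blocks contributing a block-level fusion; shallow taps keep full-resolution weight maps and empirically fuse best, so the default is the shallowest block |
| `activity_mode` | `mean` | channel mean keeps activity scales comparable across blocks with different widths; `sum` is the literal channel total |
| `upsample_mode` | `bilinear` | weight/activity upsampling; bilinear stays within the value range, `nearest` preserves the value set |
| `transconv` (K, S, P, init) | 3, 1, 1, `identity` | shape-preserving enhancement layer. No training procedure exists for it here, so the default identity kernel makes enhancement an exact no-op baseline; `smoothing` and seeded `random` kernels exercise non-trivial enhancement |
| `eq7_operator` | `apply` | `apply` weights the enhanced source (keeps fusion a convex combination under the identity kernel and preserves the self-fusion identity); `hadamard` additionally multiplies by the raw source — a literal reading retained for fidelity, at the cost of squaring intensities |
| scalarization `alpha`, `beta` | 0.5 / 0.5 | weights on the loss-like and parameter-count objectives after per-objective min-max normalization over the candidate pool; normalization is required because the raw objectives differ by ~7 orders of magnitude |
| entropy `bins` | 256 | histogram bins over [0, 1], matching the 8-bit convention |
| SSIM window | 11×11 Gaussian, σ = 1.5, K1 = 0.01, K2 = 0.03, L = 1 | the canonical configuration of the standard SSIM reference |

## Design choices at genuinely open points

- **Softmax weights.** The weight map uses a true softmax (exponential in
  numerator and denominator), computed after subtracting the per-pixel
  maximum — exact by shift invariance, not an approximation.
- **Morphology semantics.** Dilation is the neighborhood maximum and erosion
  the minimum (the textbook definitions, verifiable by duality); the default
  preprocessing pairs dilation with the structural modality and erosion with
  the functional one. Border policy: geometric ops fill vacated pixels with
  0; convolution-type ops reflect-pad, so sharpening does not invent energy
  at edges.
- **Transposed convolution.** Implemented with the standard scatter-add
  semantics: input value (h, w) contributes x·k[i, j] at output
  (hS − P + i, wS − P + j), so the default spec preserves shape and the
  identity kernel is an exact identity. Output size (H−1)S − 2P + K; specs
  yielding non-positive sizes are rejected.
- **Where the softmax runs.** Activity maps are upsampled to image
  resolution *before* the softmax. Both orders preserve per-pixel
  normalization (bilinear interpolation is linear), but this order keeps the
  self-fusion identity bit-exact; block-resolution weight maps are still
  accepted by `fuse_layer`, which upsamples them itself.
- **Preprocessing order.** Morphology → geometry (shift/rotation) →
  sharpening; alignment magnitudes default to zero because inputs are
  assumed pre-registered.
- **Evaluation protocol.** With no ground-truth fused image, quality is
  reported per modality: SSIM/PSNR/MSE of fused-vs-source, plus the fused
  image's entropy.
- **Pareto machinery.** Generic over named hyperparameters and objective
  directions; feasibility is a user-supplied predicate applied before front
  extraction; selection is the scalarized argmin restricted to the front,
  ties broken by lower first objective then input order. Only enumeration
  over supplied candidates is supported (no evolutionary search).

## Numerical notes

- Exact identities relied on by tests: softmax of equal activities is exactly
  0.5 per source; 0.5·x + 0.5·x = x in IEEE arithmetic; identity-kernel
  transposed convolution returns the input array unchanged — together they
  make self-fusion (fusing a slice with itself) bit-exact.
- Weight sums deviate from 1 by at most ~1e-16 per pixel; tests allow 1e-6.
- Pooling uses ceil semantics (partial edge windows) so tapped shapes follow
  ceil(side / 2^(b−1)) for any input side.
- PSNR of identical images is reported as an `inf` sentinel; entropy of a
  constant image is exactly 0 bits.
- Fixture weights are He-normal scaled (std √(2/fan_in), float32, zero
  biases) from `numpy.random.default_rng(seed)` and memoized per
  (variant, seed); all fusion arithmetic downstream of the features is
  float64.

## What the phantom generator emulates — and what it does not

Each phantom pair shares one elliptical "head" geometry: the structural slice
has a bright skull ring, a quantized (sharp-plateau) tissue texture, and dark
ventricles — high spatial-frequency content; the functional slice is a smooth
base-plus-Gaussian-hotspot uptake field rendered through a hot
black→red→yellow→white colormap — low spatial frequency, strictly less
gradient energy than the structural slice. Misalignment (integer shift,
rotation) is applied to the functional slice with the ground truth returned,
and seeded Gaussian noise (σ = 0.01 by default, a mild acquisition-noise
level) degrades both. Everything derives from `numpy.random.default_rng(seed)`
with no global state.

The phantoms do **not** emulate anatomy, partial-volume effects, scanner
point-spread functions, intensity non-uniformity, or registration error
beyond rigid shift/rotation. Passing tests therefore demonstrate the
*algebraic and statistical* correctness of the pipeline (normalization,
identities, determinism, metric values, trend direction), not clinical fusion
quality on real MRI/PET data.

## Problem sizes

Batch-level checks (depth-ablation trend, acceptance script) use 64×64
phantoms in batches of 6–10 with the full-width VGG19 trunk; single-pair
checks use 48×48 phantoms; operation-level oracles run on 8×8 random arrays.
These sizes were chosen as the smallest at which every structural element of
the phantom (skull ring, ventricles, hotspots) is still resolved.

## Known limitations

- The depth-ablation direction (shallow taps fusing at least as well as deep
  taps) is checked softly: it is a data-dependent trend, and a particular
  phantom seed may violate it; the suite records a warning rather than
  failing.
- `weights_source="pretrained"` requires torchvision at run time; the
  package itself ships no trained weights.
- The transposed-convolution layer is fixed, not learned: no training loop,
  loss, or label source is defined for the fusion path.
- The CLI exposes two-source fusion; the library (`fuse_sources`) accepts
  any number of registered sources.
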