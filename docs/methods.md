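# Methods

## Model

The generator maps a single-channel low-resolution slice in [0, 1] to an
`r`-times larger slice (`r ∈ {1, 2, 3, 4}`):

```
head:   3×3 conv (1 → C), PReLU
trunk:  n_res_blocks × [3×3 conv → LayerNorm → PReLU → 3×3 conv, + skip]
        3×3 conv, + global skip from the head output
attend: PCFB (chunk channels into n groups → SimAM per group → concat)
recon:  per upsampling stage f: 3×3 conv (C → C·f²) → PixelShuffle(f) → PReLU
        1×1 conv (C → 1)
```

`r = 1, 2, 3` use one stage (`f = r`); `r = 4` stacks two ×2 stages.
Defaults: `C = 64`, 16 residual blocks, `n = 2` chunks (a compact
SRResNet-class trunk); the test and smoke configurations shrink this to
2 blocks × 16 features, which keeps every structural property (shape
contracts, parameter neutrality, gradient flow) while fitting comfortably
in CPU budgets.

### SimAM / PCFB

For each sample and channel, with spatial mean `û`, squared deviation
`d_t = (t − û)²` and variance `σ̂²`, the inverse energy is computed directly
as `1/e = d_t / (4(σ̂² + λ)) + 1/2` (never by forming `e` and inverting, so
tiny `d_t` cannot overflow) and the map is reweighted by `sigmoid(1/e)`.
Consequences used by the tests: `1/e ≥ 1/2` always; a constant channel has
`d_t ≡ 0`, hence weight `sigmoid(1/2) ≈ 0.62246` everywhere — this identity
also resolves the `λ = 0` constant-channel division by zero.

Open choices, resolved as follows:

* **Variance convention.** The variance denominator uses `HW − 1`
  (`ddof=1`), matching the published SimAM reference derivation; `ddof=0`
  is exposed as a switch since the prose ("standard deviation of the
  characteristic map") does not disambiguate.
* **Statistics scope.** `û, σ̂²` are per sample and per channel over spatial
  positions only — the SimAM convention.
* **λ = 1e-4** (the SimAM published default; the source text never states
  a value), configurable.
* **Chunking** is contiguous channel ranges, so `merge(chunk(x, n)) == x`
  bit-exactly; the split pattern is otherwise unspecified in the source.
* **PCFB placement**: once, between trunk output and reconstruction head;
  optionally also after every residual block (`pcfb_every_block`).  Either
  way the block holds zero parameters, so the parameter count is unchanged.

### Normalization and activations

LayerNorm normalizes each sample independently of the batch; the default
mode standardizes jointly over (channel, height, width) — the simplest
reading of "normalizes each single batch" — with a per-spatial-position
channel-only mode behind a switch.  Affine scale/shift are per channel.
PReLU carries one learnable slope per channel, initialized at 0.25.

The reconstruction-block order (the source lists "3×3 convolution, 1×1
convolution, PReLU, and PixelShuffle" without an order) is fixed here as
3×3 conv → PixelShuffle → PReLU → 1×1 conv: the 3×3 conv supplies the `r²`
channel groups the shuffle consumes, and the 1×1 conv projects the
activated high-resolution features to one channel.

## Losses

`L = L1 + α·L_per + β·L_edge`, defaults α = 0.3, β = 0.1.  All terms are
means over every entry (batch, channel, pixel), which makes α and β
scale-free in image and batch size.  The perceptual and edge terms use L1
distances, following the printed formulas (their prose mentions Euclidean
distance; the subscript-1 norms were followed).  "Gradient loss" and
"edge-aware loss" name the same term.

* **Perceptual extractor** is an injected deterministic callable.  The
  default is a fixed, seeded stack of random 3×3 convolutions with
  rectifiers (`RandomConvExtractor`) — random deep features are a standard
  training-free proxy for learned perceptual features, and they keep the
  package fully offline.  Identity and custom extractors plug in through
  the same handle.
* **Edge operator**: 4-neighbor Laplacian `[[0,1,0],[1,−4,1],[0,1,0]]` with
  replicate padding, chosen because it annihilates constants exactly (so
  the edge loss is invariant to constant offsets); the 8-neighbor variant
  sits behind a flag.

## Degradations

* **BD** — separable resampling with the Keys cubic kernel (a = −0.5),
  output pixel `i` centered at input coordinate `(i + 0.5)/scale − 0.5`,
  kernel dilated by the scale on downsampling (antialiasing), border taps
  clamped, weights normalized (constants are exact fixed points).
* **TD** — centered 2-D DFT, central `(H/s)×(W/s)` block retained (even
  lengths use the asymmetric-bin convention: frequencies `−m/2 … m/2 − 1`),
  inverse DFT on the small grid, real part, scaled by `1/s²` so the DC
  coefficient — the mean intensity — is preserved.  The operator is linear
  before the final clip to [0, 1]; `clip=False` exposes the raw linear map.
* Scales must divide the image dimensions (study volumes are trimmed so
  several scales fit); no padding is attempted.

## Synthetic data

Phantoms emulate 240×240 gray-scale brain slices: a constant background,
overlapping anti-aliased ellipses of varying intensity ("tissue"), mild
Gaussian blurring, a smoothed Gaussian random field *inside tissue only*
(intra-tissue texture, amplitude 0.08, correlation length 1 px), and
additive noise (sd 0.01), clipped to [0, 1].  Texture and noise defaults
were calibrated once so that the bicubic ×2 BD baseline scores on phantoms
at the level reported for real T1/T2/PD slices (PSNR ≈ 32 dB,
RMSE ≈ 0.025); pure smooth-ellipse images would put that baseline near
38 dB, which no real MR dataset shows.  Everything is deterministic per
(spec, seed); there is no ambient random state.

What the phantoms do **not** emulate: Rician noise statistics of magnitude
MR, anatomy-specific structure, bias fields, motion or Gibbs artifacts, and
3-D continuity across slices.  Passing tests therefore demonstrate the
correctness of the operators and the training machinery on MR-like
statistics, not clinical performance.

Patch pairs: the LR offset `(i, j)` is uniform, the HR patch is the exactly
corresponding region at `(s·i, s·j)`.  In BD mode the LR patch is produced
by re-degrading the HR patch — the cubic kernel's footprint crosses patch
borders, so a crop of the full LR image could not be degradation-consistent
at its border ring; re-degrading makes `downsample(hr_patch) == lr_patch`
hold bit-exactly by construction.  TD is a global-spectrum operation, so
there both members are crops.  Augmentation applies the same seeded
horizontal flip / quarter-turn to both members.  Splits are 70/10/20 with
floor counts for train/val and the remainder to test, per item (the source
does not say whether its split is per volume or per slice).

## Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) at a constant 1e-3 (optional step
decay behind config), batch 16 patch pairs of 24×24 LR pixels sampled with
replacement, Xavier-uniform convolution weights, zero biases.  Every
`val_every` iterations the model is scored on the validation split and the
best-PSNR parameters are checkpointed; the returned model carries that
checkpoint (the source is silent on checkpoint policy).  A non-finite loss
aborts with a diagnostic dump (iteration, loss components, recent history,
parameter norms).  Runs are bit-reproducible from the config seed on one
worker.

The smoke configuration used by the acceptance checks (2 residual blocks,
16 features, 32 phantoms, 200 iterations) is sized for a single CPU.  Two
hundred iterations demonstrate optimization health — the composite loss
falls by ~5× and validation PSNR climbs steadily (≈ 22 → 29 dB) — but not
convergence: measured learning curves put parity with the ≈ 31.5 dB bicubic
baseline around iteration 400–600, and the published protocol trains for
millions of iterations.  The bicubic-parity margin in the acceptance suite
is therefore expected to stay unmet at 200 iterations; it is asserted
anyway rather than weakened, and this is the one known-red check.

## Metrics

RMSE on the [0, 1] scale; PSNR with the 8-bit dynamic range (consistent
with RMSE ≈ 0.02 alongside PSNR ≈ 34 dB); identical images return an
infinite PSNR sentinel rather than raising.  SSIM defaults to the standard
windowed estimator (11×11 Gaussian, σ = 1.5, population covariances;
cross-checked against scikit-image) with a whole-image "global" mode for
closed-form checks; `ssim(x, x) = 1` holds exactly in both modes.

## Numerical notes

* All computation is float64.
* The autodiff core (`mrisr.autodiff`) is a ~20-primitive reverse-mode
  tape over numpy: broadcasting arithmetic, axis reductions, shape ops,
  zero/replicate spatial padding, and stride-1 im2col convolution.  Its
  gradients are finite-difference-tested primitive by primitive, and the
  full composite-loss gradient is finite-difference-checked through the
  assembled network (≤ 1e-3 relative).
* `|simam(x)| ≤ |x|` elementwise (sigmoid weights lie in (0, 1)); PReLU
  uses the subgradient 0 at the kink; `abs` uses `sign`.
* Checkpoints store every named parameter array plus the model config and
  seed; the parameter round trip is bit-exact.
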