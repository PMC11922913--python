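# Methods

`mammofusion` implements a complete, self-contained version of a mammogram
classification pipeline: multi-fusion contrast enhancement of grayscale
breast images, a compact residual depth-wise convolutional network (RDN) for
benign/malignant classification, the surrounding preprocessing / split /
evaluation protocol, and a synthetic phantom generator that makes the whole
pipeline runnable and testable without any clinical data.

## Contrast enhancement

All operators act on `GrayImage`, a 2-D integer grid with an explicit level
count `L` (256 for 8-bit input).

**Histogram equalization (HE).** With `H(k)` the level-`k` count of an
`n × m` image, the normalized histogram is `N(k) = H(k)/(n·m)`, the CDF is
`CDF(j) = Σ_{k≤j} N(k)`, and the transfer map is
`P(x) = round((L−1)·CDF(x))`. Rounding is *half-up* (`floor(v + 0.5)`),
applied consistently so lookup tables are bit-exact against oracle
evaluation. The CDF is computed as `cumsum(H)/(n·m)` — one division of the
integer cumulative counts — because accumulating the per-level quotients
instead shifts exact `.5` ties by one ulp and flips the rounded value.

**CLAHE.** The image is partitioned into a `tile_grid` (default 8×8) of
near-equal tiles. Each tile histogram is clipped at
`clip_factor × tile_pixels / L` (default `clip_factor` 2.0, the common
convention; the integer cap is `max(floor(limit), 1)`), the clipped excess is
redistributed evenly over all bins, and the integer remainder is assigned one
unit per bin starting at bin 0 — a deterministic tie-break that conserves
tile mass exactly. Redistribution is single-pass: bins may end slightly above
the cap, which still bounds local contrast amplification. Each tile's clipped
histogram is equalized with the HE formula above; pixels are mapped by
bilinear interpolation between the four tile maps whose centers surround
them, clamped at image edges (edge/corner pixels fall back to the available
2/1 maps). An `interpolation="none"` mode maps each pixel through its own
tile only; it exists for reference testing, not for production use. With one
tile and a non-binding clip, CLAHE reduces to global HE bit-for-bit — a
regression anchor in the test suite.

**Inversion.** `out = (L−1) − in`, an involution; useful for emphasizing
dark structures on bright backgrounds.

**High-boost sharpening.** The low-pass component is a Gaussian blur
(`scipy.ndimage.gaussian_filter`, reflect boundary, kernel truncated at
4σ). The high-pass residual is `f − lowpass(f)`, and high-boost is
`A·f − lowpass(f) = (A−1)·f + highpass(f)` with amplification `A > 0`
(default 1.5, blur width σ = 2 px). The two algebraic forms agree to
round-off before range handling; the result is clipped to `[0, L−1]` once,
at the end, then rounded half-up. Reflect padding keeps the blur
mean-preserving, so constants are fixed points of both low-pass and
high-boost (with `A` accounting for the multiplicative term).

**Fusion recipes.** `FusionConfig` is an ordered step list applied
left-to-right; empty means identity. The default recipe is
`[clahe, high_boost]`, with inversion available as an optional step: the
source material illustrates CLAHE-only, inversion-only and combined variants
without fixing one canonical composite, so the default here is the package's
own choice and every recipe is expressible.

Color input is collapsed to BT.601 luminance before enhancement; the
enhanced single channel is replicated to three channels for the network.

## The residual depth-wise network

The default architecture (input side 128, channels 3):

| layer | output shape |
|---|---|
| input | (128, 128, 3) |
| conv 32 @ 3×3, same, ReLU | (128, 128, 32) |
| depthwise 3×3 (+BN, ReLU) | (128, 128, 32) |
| pointwise conv 32 @ 1×1 | (128, 128, 32) |
| shortcut pointwise 32 @ 1×1 (from the first conv) | (128, 128, 32) |
| add (skip connection) | (128, 128, 32) |
| pointwise conv 64 @ 1×1, ReLU | (128, 128, 64) |
| depthwise 3×3 (+BN, ReLU) | (128, 128, 64) |
| pointwise conv 64 @ 1×1, ReLU | (128, 128, 64) |
| dropout 0.5 | (128, 128, 64) |
| flatten | (1 048 576,) |
| dense 1, sigmoid | (1,) |

Design points, several of which resolve internal contradictions in the
source material and are therefore package decisions:

- **Input side 128 with `same` padding is canonical.** A `valid`-padding
  mode is retained (a 3×3 kernel shrinks each side by 2, e.g. 128 → 126, and
  a 2×2 max pool halves 126 → 63); under `valid` padding the residual
  branches have different spatial sides, so the default network refuses to
  build and names both shapes.
- **Binary sigmoid head** (1 unit) rather than a softmax pair; the positive
  class is malignant.
- **Batch normalization** follows each depthwise convolution, before the
  activation (momentum 0.9, ε = 1e-5). Running statistics are state, not
  trainable parameters, and are excluded from `count_parameters`.
- **Dropout 0.5** sits before flatten. It leaves shapes unchanged, so the
  canonical shape-table comparison excludes dropout rows
  (`ShapeTable.without("dropout")`).
- **Flatten is literal**: the full 128×128×64 map feeds the dense unit (no
  global pooling), giving a ~1.05 M-parameter head. This is implemented as
  specified; its statistical cost at small sample sizes is documented below.
- **Weights** are He-normal initialized from a seeded generator; everything
  downstream (dropout masks, shuffling) derives from explicit seeds, so runs
  are bit-reproducible.

The numerical implementation is pure NumPy: im2col (`sliding_window_view`)
convolutions with BLAS contractions, hand-derived backward passes (the input
gradient is the full correlation with the spatially flipped kernel), and the
standard batch-norm backward through the batch statistics. Correctness is
enforced by a finite-difference gradient check (10 random parameters,
relative tolerance 1e-4) and by a constructive equivalence test: a depthwise
+ pointwise pair with rank-1 weights reproduces a brute-force standard
convolution exactly.

The binary cross-entropy gradient is injected at the output pre-activation
as `(p − y)/batch`, the numerically stable combined sigmoid/cross-entropy
form. Reported probabilities are clamped to the open interval (0, 1).

## Protocol

- **Preprocessing:** resize to the target side (bilinear, via Pillow),
  replicate grayscale to 3 channels, divide by 255. Idempotent on
  already-normalized, already-sized input. Non-8-bit input is rejected.
- **Split:** 80/10/10 train/validation/test. Validation and test sizes are
  `round(f·n)`; the remainder goes to train. Stratified by class (same
  rounding per class) unless a class has fewer than 3 items, in which case
  the split degrades to unstratified with a warning. Seeded and
  deterministic.
- **Augmentation (optional, off by default):** horizontal flip with
  probability 0.5 and rotation uniform in ±10°, label-preserving and
  deterministic per seed.
- **Training:** mini-batch Adam (defaults lr 1e-3, batch 32, 10 epochs) or
  SGD; optional inverse-frequency class weighting for imbalanced data (off
  by default). Loss divergence aborts with a diagnostic. Per-epoch train and
  validation loss/accuracy are recorded.
- **Evaluation:** probabilities ≥ 0.5 predict malignant (ties count as
  positive). Confusion counts feed the five metrics (accuracy, precision,
  recall, specificity, F1); any zero denominator yields an explicit
  undefined marker, never a silent zero. Metrics are fractions internally,
  percentages only at presentation.

## Synthetic phantoms

Each phantom is an elliptical breast region on a dark field, filled with a
smoothed-white-noise fibroglandular texture (blur width 6 px at 128 px,
base level 90 ± 18 gray levels), one bright lesion (peak contrast 70
levels), and additive Gaussian acquisition noise (σ = 6 levels). Benign
lesions have a constant boundary radius (drawn from 10–18 px at 128 px,
Gaussian radial profile). Malignant lesions perturb the boundary radius
with low-order random lobulation scaled by `irregularity` (default 0.4) plus
6–12 narrow Gaussian spicule rays — the spiculated-mass morphology that
marks malignancy on real mammograms. These defaults were chosen once as a
plausible geometric caricature: lesions a tenth of the image side, texture
and noise strong enough that single pixels are uninformative, and a
boundary perturbation clearly visible at full resolution.

The ground truth records lesion center, radius, spicule count and a
boundary-roughness score (circumferential std/mean of the boundary radius).
At defaults the roughness score separates the classes essentially perfectly
(AUC > 0.9 required by the tests; measured ≈ 1.0), and with
`irregularity = 0` and a fixed radius the classes are indistinguishable
(AUC ≈ 0.5) — a separability dial that gives the training smoke test a
known-learnable signal. All randomness flows from one seed; phantoms are
bit-reproducible, and datasets can be written as PNG class folders (PNG
avoids JPEG nondeterminism) with a ground-truth CSV sidecar.

What the phantoms deliberately do **not** model: real anatomy (pectoral
muscle, skin line, CC/MLO view geometry), calcifications, detector physics,
or the intensity statistics of any scanner. Passing tests on phantoms
demonstrate that the pipeline is wired correctly and can extract a known
morphological signal — they say nothing about clinical performance.

## Problem sizes and what the tests show

The test suite trains a scaled RDN (input side 32, block widths 16/32) on
200 default phantoms for 10 epochs; it reaches ≥ 90 % *training* accuracy
for at least 2 of 3 seeds in about half a minute per seed on one CPU — a
learning-capability smoke test, chosen at a scale where the NumPy
implementation is quick.

Generalization at these sizes is a different matter, and the package is
explicit about it: with a few hundred training phantoms, a literal
flatten→dense head (tens of thousands of parameters even at reduced
resolution) can memorize the training set while validation/test accuracy
stays near chance, and aggressive downsampling erases the few-pixel spicule
signal. The worked example in the README shows exactly this behavior. Strong
held-out performance of this architecture requires sample sizes and
resolutions (thousands of real images at full resolution) far beyond a
desk-scale synthetic run, which is why no headline-metric reproduction is
attempted anywhere in the package.

## Known limitations

- Convolutions are stride-1 only; `same` padding requires odd kernels.
- CLAHE redistribution is single-pass (no iterative re-clipping).
- The NumPy implementation targets correctness and reproducibility, not
  throughput; full-resolution (128 px) training of the default network is
  minutes-per-epoch territory on one CPU.
- No DICOM ingestion; 8-bit PNG/JPEG only.
- No ROC/AUC reporting or probability calibration.
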