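# Methods

## Model and training procedure

`dafh` trains a supervised hashing network end to end. The forward pass is
backbone → CBAM attention on an intermediate "tap" feature map →
inter-layer fusion → two heads: a softmax classifier and a hash projection
of length L squashed by the learnable quantizer tanh(α·x + b), α > 1. The
binary code is the elementwise sign of the continuous code.

Assumptions built into the design:

- **Single 2-D grayscale slices.** Images are per-image min–max normalized
  to [0, 1] and resampled to a square side (default 224 px; tests and the
  shipped tiny backbone use 64). No 3-D context, no modality-specific
  intensity calibration (e.g. Hounsfield units).
- **Relevance = shared class label.** Retrieval evaluation counts a
  database item as correct iff its label equals the query's.
- **Database = training set.** The 80% side of the stratified split serves
  both as the training corpus and as the retrieval database; the 20% side
  is queries only. When the two sets overlap (self-querying a database),
  the entry with the query's exact source id is excluded from its own
  candidate list.
- **The backbone is an interface.** Anything that returns the (final, tap)
  feature-map pair plugs in. The shipped `TinyBackbone` (4 × [3×3 conv,
  ReLU, 2×2 average pool], channels 8-16-32-32, tap at the penultimate
  block) is a fully functional CPU-scale extractor, and every architectural
  property test runs against it.

The training loop samples, within each shuffled mini-batch, one triplet per
eligible anchor (positive uniform among same-class others, negative uniform
among other classes; anchors without a partner are skipped and counted),
runs one forward pass per batch, gathers the triplet rows, and minimizes

    total = λ·(focal_a + focal_p + focal_n) + β·triplet

by Adam with L2 weight decay. Validation (MAP@10, MAP@1 of the query set
against the database set) runs after every epoch; the best-by-MAP@10 and
last checkpoints are kept.

## Parameters that matter

| parameter | default | units / range | rationale |
|---|---|---|---|
| hash length L | 32 | bits | typical operating points 16/32/48 |
| epochs | 50 | — | reference setting |
| learning rate | 1e-4 | — | reference setting (Adam) |
| weight decay | 1e-4 | — | regularization rate, read as Adam L2 |
| focal γ | 1.5 | — | reference setting; γ=0 is exactly cross-entropy |
| triplet margin | 0.5 | code-space distance | reference setting |
| λ, β | 1/3, 1 | — | λ=1/3 averages the three focal terms; β=1 matches a plain focal+triplet sum |
| batch size | 32 | images | unstated in the reference protocol; config-driven |
| split ratio | 0.8 | — | database : query = 8 : 2, stratified per class |
| IQR factor | 1.5 | — | conventional Tukey fence |
| α init | 1.1 | — | gentle start; steepness is free to grow during training |

Augmentation ranges (all configurable): additive Gaussian noise sd ∈
[0, 0.05], Gaussian blur sd ∈ [0, 1.5] px, brightness delta ∈ [−0.2, 0.2],
rotation ∈ [−15°, 15°], isotropic scale ∈ [0.9, 1.1]. The union
{noise, blur, brightness, rotation, scaling} is available; applications can
restrict to any subset.

## Synthetic data generator

`generate_synthetic` emulates the regularity that distinguishes imaging
series of different anatomical sites: each class has a deterministic
signature (3–5 bright Gaussian blobs at class-specific positions, peak
amplitude 0.45, plus an oriented sinusoidal grating of class-specific
orientation and frequency, amplitude 0.15) on a 0.40 background. Per-image
nuisance — a random grating phase, a random linear illumination ramp
(slope ≤ 0.08), optional additive Gaussian noise — provides within-class
spread. The amplitudes were set so that the classes are linearly separable
on raw pixels at zero noise (a nearest-centroid classifier reaches 100%
training accuracy, which the test suite asserts), making retrieval quality
a meaningful learning signal.

What the generator does **not** emulate: modality physics, 3-D anatomy,
inter-scanner variation, label noise, and the long-tailed within-class
diversity of real archives. Consequently, a perfect MAP on this corpus
shows the optimization and retrieval machinery works; it does not predict
absolute MAP on clinical data.

One measured consequence worth stating plainly: because the class signal is
geometrically strong, an **untrained** random-weight network is *not* at
chance on this corpus. Over a 20-seed Monte-Carlo (2 balanced classes,
16-bit codes) untrained MAP@1 averages ≈ 0.70, bimodal between 0.5 — seeds
whose codes collapse to a single constant word, where deterministic
tie-breaking yields the chance rate — and 1.0 — seeds where the random
projection of the convolutional features already separates the classes, as
random features that approximately preserve input geometry are known to
do. The test asserting the chance-level expectation is kept in its literal
form and fails by design on this generator; the acceptance script reports
the measured value.

## Numerical choices

- **Autodiff core.** A minimal reverse-mode engine on float64 numpy arrays
  (broadcast arithmetic, matmul, stride-1 convolution, 2×2 average pooling,
  sum/mean/max reductions, tanh/sigmoid/ReLU/exp/log/softplus/clamp,
  reshape/concat/row-gather). Gradients of every primitive are verified
  against central finite differences; an end-to-end check confirms
  d(total)/dα and the hash-head gradients to 1e-4 relative.
- **α constraint.** α = 1 + softplus(a_raw), so α > 1 holds by construction
  at every optimizer step; the training loop asserts it anyway.
- **Shared quantizer bias.** The hash-layer bias b₂ enters both the linear
  map and the quantizer argument (code = tanh(α(W₂x + b₂) + b₂)); a config
  flag switches to a separate quantizer bias.
- **log floor.** p_y is clamped to [1e-12, 1] before the focal log.
- **Triplet distance.** Euclidean on continuous codes, with a 1e-12 floor
  inside the square root so the gradient stays finite when codes coincide;
  squared-Euclidean available by flag. Binarized codes are never used in
  the loss (zero gradient).
- **Binarization tie.** sign(0) → +1, a deterministic measure-zero rule.
- **Hamming ranking ties.** Equal distances break by ascending database
  index; rankings are therefore identical across platforms and match a
  brute-force stable sort exactly.
- **MAP@k normalization.** AP at cut-off k divides by min(n_gt, k), so a
  perfect truncated list scores 1 and MAP@1 equals top-1 accuracy; the
  raw full-corpus normalization is available by flag.
- **Degenerate inputs.** Constant images min–max scale to all zeros; IQR
  cleaning refuses < 4 images; an all-identical corpus has collapsed fences
  and removes nothing; a non-finite fence factor keeps everything; classes
  with < 2 members refuse to split; single-class batches yield an empty
  triplet set with a warning; non-finite training loss aborts with the
  offending step named.
- **Rounding in the split.** Per-class database counts use round-half-to-
  even of ratio·n_c; shortfalls go to the query side.
- **Seeding.** One global seed fans out via `numpy.random.SeedSequence`
  substreams to synthesis, splitting, augmentation, weight initialization
  and triplet sampling; every derived seed stays below 2³¹. Two runs with
  one seed produce bitwise-identical histories on CPU.

## Open design choices

- **Vectorization before fusion.** Concatenating two conv feature maps for
  a linear layer needs a flattening step the architecture sketch leaves
  open; global average pooling is used for the fusion-head operands, and a
  raw flatten (explicitly a Flatten) for the CBAM map entering the hash
  branch.
- **Classifier input.** The classifier reads the first fusion layer's
  output linearly; a config switch interposes a ReLU.
- **IQR statistic.** The fence is applied independently to per-image mean
  and per-image variance; an image is dropped if either fails. Corpus-wide
  by default, per-collection by config.
- **Validation depth.** MAP@10 (the headline metric) drives model
  selection; MAP@1 is logged alongside.
- **Triplet mining.** Uniform random within batch; semi-hard mining exists
  behind a flag but is off by default.

## Problem sizes used in tests

The end-to-end suite trains the tiny backbone on 200 synthetic images
(4 × 50, side 64, L = 16) for 8 epochs at learning rate 1e-3 / batch 16 —
about 15 s on one CPU core — and smaller 2-class corpora (side 32) for the
determinism and structural checks. These sizes were chosen as the smallest
at which retrieval quality is a meaningful signal.

## Known limitations

- Pure-numpy training is CPU-bound; the shipped backbone is deliberately
  small. Large pretrained extractors are out of scope (the backbone
  interface accepts them, but no weights are distributed).
- No 3-D volumes, DICOM windowing/HU calibration, or de-identification.
- No approximate nearest-neighbour index; retrieval is an exact linear
  scan, appropriate up to ~10⁵–10⁶ codes.
- Reported synthetic-corpus MAP values overestimate what the same recipe
  achieves on real multi-site archives (see the generator section).
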