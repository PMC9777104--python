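# Methods

This note records the scientific and numerical choices behind `stainseg`:
what the models compute, which knobs matter, what the synthetic data does
and does not emulate, and where the design was genuinely open.

## Problem setting

Binary nuclei segmentation in H&E-stained whole-slide image (WSI) patches,
under strong inter-laboratory variation in stain color. Rather than
normalising color as a preprocessing step, the encoder is pretrained with
a contrastive objective on unlabeled patches drawn from many stain
conditions, so that its representation becomes insensitive to the color
nuisance while staying sensitive to nuclear morphology. The pretrained
encoder is then fine-tuned end-to-end (not frozen, though a
`freeze_encoder` flag exposes the alternative) inside a supervised
segmentation network.

## Encoder

Five stages S0–S4, hybrid convolution/transformer in the CoAtNet mold,
each stage halving the spatial side: `side(s_k) = input_size / 2^(k+1)`.
The `full` preset uses the published CoAtNet-0 scale — channels
(64, 96, 192, 384, 768), depths (2, 2, 3, 5, 2), 8 attention heads — since
the backbone reference does not pin a variant; the `tiny` preset
(16, 24, 32, 64, 128), depth 1 per stage, 2 heads, exists so that every
behaviour is testable on one CPU in seconds. Input sizes must be divisible
by 32; at 256 the bottleneck map is 8×8, and at the 224 contrastive input
size it would be 7×7, which is why the contrastive loop resizes its views
to the configured `input_size` rather than hard-coding 224.

Stage internals:

* S0: two 3×3 convolutions (the first stride-2), each BN + GELU, then a
  WHDC block.
* S1: MBConv blocks (1×1 expand ×4 → 3×3 depthwise → squeeze-excitation
  with hidden width `in_channels // 4` → 1×1 project; residual when
  shapes match; first block stride-2), then a WHDC block. The WHDC blocks
  in S0 and S1 share hyperparameters but have independent learned
  parameters — "same setting" is read as same configuration, not shared
  weights.
* S2: identical to S1 without WHDC.
* S3/S4: stride-2 max-pool at entry followed by a 1×1 projection to the
  stage width, then pre-norm transformer blocks (multi-head self-attention
  with a learned relative position bias indexed by 2D token offset, FFN
  expansion 4). The bias table is sized for the stage's fixed grid; a
  mismatched sequence length is a validation error rather than an
  interpolation.

Normalisation follows the usual hybrid convention: batch norm in conv
stages (momentum 0.1, eps 1e-5), layer norm in transformer stages.

## WHDC block

Four cascaded 3×3 dilated convolutions, rates (3, 6, 9, 18), padding equal
to the rate so C, H, W are all preserved (effective kernel span at rate 18
is 37 pixels — wider than many maps, which zero padding handles). Each
branch is BN + GELU. The "self-weighting" gates are scalars per branch and
sample: `w_k = sigmoid(linear(GAP(branch_k)))`. Two readings were
possible — scalar gates or per-channel vectors; the scalar reading is the
minimal one consistent with "four weights", and channel-wise modulation is
already provided by the attention stage that follows. The gated branch
outputs and the block input concatenate to 5C channels, pass through
squeeze-excitation channel attention (reduction 16, hidden width
`max(1, 5C // 16)`), and a 1×1 convolution restores C channels. The final
projection is this package's addition: some channel bookkeeping step is
required for the block to be shape-preserving inside S0/S1, and a learned
1×1 convolution is the lightest choice.

## Contrastive objective

Views are built by flips (p = 0.5 each axis), 90° rotations (p = 0.5,
k ∈ {1,2,3}), Gaussian blur (p = 0.5, σ ∈ [0.1, 2.0]), brightness/contrast
jitter ±0.2 (p = 0.2), and color jitter (p = 0.8; strengths 0.4 for
brightness/contrast/saturation, 0.1 for hue) — SimCLR-standard settings
for the parameters the protocol leaves open. The projection head is two
bias-free linear maps with a ReLU between (hidden width = encoder output
width, output 128). The head takes the globally average-pooled bottleneck
(the encoder must emit a vector and pooling is the standard reduction) and
is discarded after pretraining, per SimCLR convention.

NT-Xent uses cosine similarity and temperature 0.07; the denominator for
anchor i sums over every other view in the batch, including other images'
positives. The implementation computes one normalised similarity matrix
per batch and is verified in the tests against a literal double-loop
evaluation of the formula. The reference batch size of 2 gives only two
negatives per anchor; a warning is logged for batch sizes below 8.
Optimiser: SGD, momentum 0.9 (unstated; standard default), no weight
decay.

## Segmentation network

Decoder: five 4×4 stride-2 transposed convolutions (8→16→32→64→128→256
for a 256 input), BN + ReLU after each except the last, which maps to one
channel and a sigmoid. Decoder widths mirror the encoder stage channels.
The published wiring of skips was under-specified; the one implemented is
the only arrangement consistent with five decoder layers, attention on the
first four, and the stated spatial sizes: at decoder step k (k = 1..4),
the encoder skip s_{4−k} is attention-gated with the current decoder state
as gating signal, and concatenated with the step's upsampled output; the
concatenation feeds the next transposed convolution. The fifth layer has
no skip — no full-resolution encoder map exists. Attention gates are the
standard additive form: 1×1 maps on skip and (2× nearest-upsampled)
gating, ReLU, 1×1 to one channel, sigmoid, multiply into the skip; gate
inter-channel width defaults to half the skip width.

Loss: `γ·BCE + (1−γ)·Dice`, γ = 0.4. BCE is the pixel mean with
predictions clamped to [1e-7, 1 − 1e-7]; Dice is computed per image as
`1 − (2Σyt + s)/(Σy² + Σt² + s)` with smoothing s = 1e-6 (two empty masks
score a perfect 0) and averaged over the batch. Thresholding uses ≥ (the
boundary rule is unstated anywhere; one must be picked and documented).
Optimiser: Adam, lr 2e-4, β = (0.5, 0.999).

## Patch extraction

WSIs are resized to 1024×1024 (bilinear for images, nearest-neighbour for
masks so no labels are invented — mask handling is assumed to mirror the
image handling), tiled into non-overlapping 512×512 patches, and each tile
yields 200 random 256×256 crops with offsets uniform over valid positions,
for `W · 4 · 200` crops from W slides (23 slides → 18,400). Crops are
addressed by (source, tile, offset) in the index CSV and cut lazily from
cached resized sources by default; `materialize=True` writes every crop to
PNG. The lazy default keeps the pipeline I/O-light — the count law and
training both only need the index plus the 23 source images — and the
tests verify lazy and materialised crops agree to PNG quantisation.

## Evaluation metrics

Dice/precision/recall come from exact confusion counts; on empty
denominators Dice reports 1 when both masks are empty, and
precision/recall report 1 with a logged warning. AJI is the canonical
aggregated Jaccard index: ground-truth instances in ascending label order
greedily claim the unused predicted component with maximal pairwise
Jaccard (ties to the smaller predicted label, for determinism); matched
intersections/unions accumulate, unmatched ground truth adds its own
area, and leftover predicted components add theirs. The printed form of
the metric in the source literature has garbled indices; the
implementation follows the reference formulation the literature cites,
and the test suite pins it to an independent set-based re-derivation on
randomised small instance maps. Binary network output is turned into
instances by 8-connected component labelling (nuclei are blob-like;
4-connectivity is available). Summary statistics are mean and sample SD
(n−1).

## Training engine

All networks run on the package's own reverse-mode autodiff over numpy
(`stainseg.nn`): a tape-based `Tensor` with hand-written exact adjoints
for every operation used (im2col-based grouped/dilated convolutions,
transposed convolutions as the conv adjoint, max pooling, batch/layer
norm, attention primitives, the elementwise zoo), verified against central
finite differences in the tests. Float32 parameters; GELU is the exact
erf form. Checkpoints are single `.npz` files with a JSON config header,
versioned. Each module takes an explicit `numpy.random.Generator`, and
one global seed fans out to named substreams (data, patches, pretraining,
training, prediction), so runs are reproducible end-to-end.

## Synthetic data: what it does and does not show

Scenes are filled ellipses (random centre, semi-major axis from
`radius_range`, eccentricity from `eccentricity_range`, orientation
uniform in [0, π)) in a hematoxylin-like purple (base RGB (0.35, 0.22,
0.55)) on an eosin-like pink background (base (0.92, 0.78, 0.86)), with
per-image and per-nucleus color jitter, radial core shading, and smooth
background texture. Stain domains shift hue separately for
hematoxylin-dominant and eosin-dominant pixels (classified by an HSV hue
band), scale brightness/contrast, and add clipped Gaussian noise; the
identity domain is a bit-exact no-op. With `overlap_allowed=False`,
placement uses rejection sampling (100 attempts, then skip); labels are
compacted to consecutive 1..k either way.

This emulates the two axes the method targets — color variation across
laboratories and nuclear size/shape variation — but deliberately not:
Beer–Lambert stain physics, chromatin texture, realistic
touching-boundary geometry, tissue architecture, or scanner artefacts.
Passing tests therefore demonstrate that the pipeline learns
color-robust, scale-robust foreground segmentation and that every formula
matches its definition; they do not certify benchmark performance on real
WSIs.

## Scales used in the checks

The structural checks run the pipeline at the reference scale (23 slides,
1024/512/256/200 extraction; 256-input encoder geometry). The end-to-end
smoke run uses the package's chosen small-problem configuration: 32
synthetic 64×64 images across two stain domains, tiny preset, 2
pretraining epochs, 40 segmentation epochs at lr 2e-3 (the reference lr
2e-4 is tuned for 18k-crop epochs, far more steps than a 32-image corpus
provides), batch 4, flip/rotation augmentation. Held-out scenes from the
same generator score Dice ≈ 0.99 at these settings. Against a fixed
random initialisation this setting isolates what pretraining buys;
training from scratch is the `pretrained_checkpoint=None` arm.

## Known limitations

* Binary output: touching nuclei merge into one component, which Dice
  barely notices but AJI punishes (see the README example). No watershed
  or boundary-aware post-processing is included, by scope.
* The numpy engine is single-threaded BLAS-bound; the `full` preset is
  constructible and correct but not practical to train at benchmark scale.
* Batch statistics: batch norm with batch 2–4 is noisy; running estimates
  use momentum 0.1 and inference always uses them.
* The hue-band stain classifier in `apply_stain_domain` is a heuristic;
  extreme jitter can move pixels across the hematoxylin/eosin boundary.
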