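# Methods

## Model

`ASPNet` is a fully convolutional encoder–decoder for binary ridge
segmentation. Input is an RGB tile scaled to [0, 1]; output is a 2×H×W logit
map at full resolution. Any height/width divisible by 16 is accepted (four
2× downsamplings); other sizes raise a shape error rather than being
silently resized.

**Encoder.** Five blocks of (3×3 conv → batch norm → ReLU) × 2 with 2×2
max-pooling in front of blocks 2–5. The per-block output widths are the
`channel_schedule`, default (64, 128, 256, 512, 512), or (b, 2b, 4b, 8b, 8b)
derived from `base_channels`. The exact block design (two convolutions,
batch normalisation, ReLU) is this package's choice; the topology that
matters to the method — five blocks, four skip connections, deepest map into
the pyramid bottleneck — is fixed.

**ASPP bottleneck.** Four parallel padding-preserving branches on the
deepest map: one 1×1 convolution and three 3×3 convolutions with dilation
rates 6, 12, 18 (the canonical pyramid setting; configurable). Branch
outputs are concatenated and projected by a 1×1 convolution to
`aspp_out_channels` (default: the deepest encoder width). Oversized rates on
small maps are handled by zero padding, never an error. Each branch's
effective footprint is verifiable by a finite-difference probe
(`receptive_field_offsets`), which must return exactly
{−r, 0, +r}² for a rate-r branch.

**Decoder.** Four stages, deepest skip first. Each stage: 2× upsampling
(bilinear interpolation with half-pixel centres by default; a kernel-2
stride-2 transposed convolution as the `transposed` option), fusion with the
skip (channel concatenation followed by a 3×3 conv-BN-ReLU by default;
1×1-projected addition as the `add` option), a second 3×3 conv-BN-ReLU, and
a strip-pooling gate. Strip pooling is applied at **every** stage. A final
1×1 convolution emits the two class logits.

**Strip pooling.** For input x (C×H×W): row profile `mean over W` → H×1,
column profile `mean over H` → 1×W; each profile passes a length-3
channel-mixing 1-D convolution (padding 1); the two profiles are broadcast
back to H×W and summed; a 1×1 convolution plus sigmoid forms a gate in
(0, 1) multiplied element-wise with the input. Channel count is preserved
throughout. The vectorised implementation is tested against an explicit
per-pixel loop oracle to 1e-5.

**Inference.** `predict` takes the per-pixel argmax; exact ties go to
background (label 0) — the conservative choice for a detector that should
not hallucinate ridges.

**Initialisation.** Kaiming-normal (fan-in) for convolution weights, zero
biases, unit/zero batch-norm affine parameters; the random stream is fixed
by `ModelConfig.seed`, so a configuration reproduces its weights exactly.

## Autodiff backend

The network runs on a small reverse-mode automatic-differentiation engine
written on numpy (`ridgeseg.nn`): tensors form a DAG, gradients propagate in
reverse topological order. Convolutions are stride-1 and computed as a sum
over kernel taps (each tap one channel contraction on a shifted view), which
avoids im2col buffers and keeps peak memory low; downsampling is max-pooling
and upsampling is bilinear/transposed-conv, so stride-1 convolution is
sufficient. Every operation's gradient is verified against central finite
differences in the test suite (float64, tolerance 1e-6). Training arithmetic
is float32; batch-norm running statistics are kept in float64 (unbiased
variance, momentum 0.1, eps 1e-5).

## Loss and metrics

Per-pixel multinomial cross-entropy, `−x[c] + log Σⱼ exp(x[j])`, averaged
over all pixels of the batch and computed with the log-sum-exp shift. Labels
outside {0, …, K−1} raise a validation error.

Metrics derive from per-class confusion counts:
Acc = (TP+TN)/total, Pr = TP/(TP+FP), Re = TP/(TP+FN), IoU = TP/(TP+FP+FN),
all as percentages; mIoU averages IoU over the two classes. Dataset-level
scores average per-image metrics (`per_image_mean`, the default) or pool
pixel counts first (`pooled`). Degenerate denominators never raise: a class
with TP+FP+FN = 0 in an image is *perfectly absent* and scores 100% on
Pr/Re/IoU (this keeps per-image averaging well defined on background-only
tiles); a zero denominator with disagreement present scores 0%.

## Training protocol

SGD with learning rate 0.01, batch size 4, 100 epochs, 512×512 inputs by
default; momentum, weight decay, schedules and augmentation all default to
off and are exposed in `TrainConfig` — the protocol deliberately adds
nothing beyond plain SGD. Shuffling uses a generator seeded by
`TrainConfig.seed`, so runs are bit-reproducible. After each epoch the model
is scored on the validation split; `best.npz` tracks the highest validation
mIoU, `last.npz` the final state, and the history (mean training loss,
validation accuracy and mIoU per epoch) is written as CSV and plottable as
loss/accuracy curves. A non-finite loss aborts immediately, naming the
epoch and batch.

## Synthetic scenes

The generator emulates the gross statistics of drone imagery of ridged
fields: `n_ridges` roughly parallel full-length strips (horizontal,
vertical, or per-ridge mixed) of bare-soil colour over a green canopy,
integer widths drawn from `ridge_width_range`, boundary jitter from
smoothed Gaussian noise with standard deviation `edge_roughness`, low
frequency canopy brightness variation plus per-pixel Gaussian noise, and —
on the hard setting — small bright elliptical "vacancy" speckles covering an
expected `vacancy_density` fraction of the crop area. Vacancies are painted
only inside background regions and always labelled 0: they are distractors
that resemble ridge material, not ridges. Masks are paletted PNGs (index 0
black, index 1 yellow). Identical specs (including seed) produce
bit-identical scenes; per-tile seeds derive from the master seed via
`numpy.random.SeedSequence` spawning. When a dataset size is not divisible
by the split-ratio sum, the remainder goes to the training split, so the
validation fraction never exceeds its nominal share.

What the generator does **not** model: real canopy texture and row
structure, radiometric and atmospheric variation, perspective and
georeferencing, annotation noise, and ridge curvature (strips are
axis-aligned up to jitter). Passing the learning checks therefore shows the
architecture, loss, optimiser and pipeline are implemented coherently and
can fit strip-shaped structure under distractors — not that field-level
accuracies transfer to real imagery.

## Reduced study scale

The full configuration (base 64 channels, 512×512 tiles, 600 tiles, 100
epochs) is impractical for routine verification on one CPU core, so the
package fixes one reduced configuration in `ridgeseg.experiments` and uses
it for its own checks:

* 64×64 tiles with two ridges of width 5–12 px; 36 tiles split 5:1
  (30 train / 6 val) as the stand-in for the full 600 (500/100);
* base 16 channels (schedule 16/32/64/128/128);
* SGD lr 0.01, batch 4 — unchanged from the full protocol;
* easy-condition learning check: 20 epochs (reaches ≈99% validation mIoU);
* hard-condition robustness check: the full 100 epochs. Discriminating
  speckle distractors from ridges converges much more slowly than the clean
  stripe task (the vacancy mislabelling rate falls roughly 83% → 50% → 28%
  → 17% over the first 40 epochs and to ≈5% by 100), so this check keeps
  the standard epoch count;
* tiled inference on large scenes uses tiles of the network's training
  input size (64 px here, 512 in the full protocol). Strip pooling's
  whole-row/column averages and the ratio of ASPP rates to feature-map size
  make the features resolution-sensitive, so tiling at the training
  resolution is part of the method's contract, not an optimisation.

## Numerical and design notes

* Bilinear resizing uses the half-pixel-centre convention with edge
  clamping; forward and backward are exact transposes of each other.
* Max-pool ties route the gradient to the first (row-major) maximum.
* Tile grids are row-major and 0-based; rasters are zero-padded
  right/bottom to tile multiples and results cropped back, with no overlap
  or seam blending — plain splicing is accepted behaviour, and stitching
  audits tile order and shape, rejecting permuted inputs.
* Checkpoints are single `.npz` files with the full `ModelConfig` embedded,
  so a checkpoint is self-describing.
* Configuration precedence is defaults < YAML file < explicit flags, and a
  loaded configuration re-saves identically.

## Known limitations

Batch-norm statistics come from batches of 4 small tiles, so evaluation at
a very different tile size shifts feature statistics (see the tiling note
above). Training is single-device float32 with no mixed precision, no
augmentation and no learning-rate schedule. The CLI accepts PNG/JPEG/TIFF
but not georeferenced output; predictions carry no CRS. The synthetic
scenes are a stand-in, not a reproduction, of any real survey.
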