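# ridgeseg

Semantic segmentation of **farmland ridges** — the narrow raised soil strips
that separate crop plots — in low-altitude aerial (drone) imagery. Ridge maps
feed plot-layout analysis for wheat breeding trials and day-to-day farmland
management; the hard part is that ridges are long, thin, roughly axis-aligned
structures with irregular edges, easily confused with small bare "vacancy"
patches inside the crop canopy.

The package is aimed at agricultural remote-sensing practitioners who need a
self-contained, dependency-light tool: the network, its training loop and the
large-raster inference pipeline run on a plain numpy stack (a compact
reverse-mode autodiff engine ships inside the package), and a bundled
synthetic scene generator stands in for field imagery so everything is
testable offline.

## The model

`ASPNet` is an encoder–decoder convolutional network for two classes
(0 = crop/background, 1 = ridge):

* **Encoder** — five double-convolution blocks (3×3 conv → batch norm → ReLU,
  twice), channel schedule 64/128/256/512/512, with 2×2 max-pooling between
  blocks. The first four block outputs are kept as skip connections.
* **ASPP bottleneck** — atrous spatial pyramid pooling on the deepest map:
  a 1×1 branch plus three 3×3 branches dilated at rates 6/12/18, concatenated
  and projected 1×1. Dilation widens the receptive field without extra
  parameters, improving ridge connectivity across the scene.
* **Decoder with strip pooling** — four stages; each upsamples 2×, fuses with
  the matching skip (concatenation + 3×3 conv), refines, then applies a
  *strip pooling* gate. Strip pooling averages the feature map along whole
  rows (H×1) and whole columns (1×W), passes each profile through a length-3
  1-D convolution, broadcasts both back to H×W, sums them pixel-wise, and
  converts the sum through a 1×1 convolution and a sigmoid into a
  multiplicative gate on the input:

      g = σ( W₁ [ expand(conv₁ₓ₃(rowmean x)) + expand(conv₃ₓ₁(colmean x)) ] ),
      y = x ⊙ g

  This captures the long-range row/column dependencies of strip-shaped
  ridges and suppresses compact distractors such as vacancies.

Training minimises per-pixel cross-entropy,
`loss(x, c) = −x[c] + log Σⱼ exp(x[j])`, with plain SGD (lr 0.01, batch 4,
100 epochs by default). Quality is reported as pixel accuracy, precision,
recall and IoU (`TP/(TP+FP+FN)`), each ×100, with mIoU the mean IoU over the
two classes; dataset scores average per-image metrics. Rasters larger than
the network input are segmented by splitting into non-overlapping tiles,
predicting per tile, and stitching row-major.

## Worked example

Train the reduced network (base 16 channels) on a generated 64×64-tile
dataset and inspect the result — this is the package's desk-scale study
configuration from `ridgeseg.experiments` and takes a couple of minutes on
one CPU core:

```python
from pathlib import Path
from ridgeseg import experiments
from ridgeseg.metrics import evaluate_dataset

data = experiments.make_reduced_dataset(Path("data_easy"), "easy", seed=42)
model, history = experiments.train_reduced(data, seed=1,
                                           epochs=experiments.EASY_EPOCHS)
print(f"best epoch: {history.best_epoch}")
report = evaluate_dataset(model, data, split="val")
print(report.summary())
```

which prints

```
best epoch: 20
per_image_mean over 6 image(s)
  class 0 (background): Acc 99.7%  Pr 99.7%  Re 99.8%  IoU 99.5%
  class 1 (ridge): Acc 99.7%  Pr 99.6%  Re 99.2%  IoU 98.8%
  mIoU 99.2%
```

The validation mIoU of 99.2% says the clean synthetic stripe task is learned
essentially perfectly in 20 epochs; the per-class rows show the ridge class
(the rarer one) is recovered with both precision and recall above 98%.
Tiled inference on a 1024×1024 scene of the same family then reaches 97.6%
mIoU against the rendered ground truth
(`experiments.large_scene_miou(model, spec)`).

The same workflow is available from the shell:

```bash
ridgeseg generate --n-tiles 600 --tile-size 512 --difficulty hard --out data/
ridgeseg train --data data/ --checkpoint-dir ckpt/
ridgeseg eval --data data/ --checkpoint ckpt/best.npz
ridgeseg predict-large field.tif --checkpoint ckpt/best.npz --out ridges.png
```

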