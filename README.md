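# tganet — tongue feature recognition with an attention-gated CNN

Computer-aided tongue inspection for Traditional Chinese Medicine (TCM)
assigns diagnostic labels to tongue photographs along three axes: **tongue
color** (Pale Red / Red / Dark Red), **tongue body** (Swollen / Non-Swollen)
and **tongue coating** (White Greasy / Thin White / Thin Yellow / Yellow
Greasy). This package implements that pipeline end to end for researchers
who want a reproducible, CPU-scale reference:

1. **Segmentation** — a U-Net produces a binary tongue mask; the image is
   masked to black outside the tongue so lips/jaw/background cannot leak
   into classification.
2. **Augmentation** — random translation (±10 px), then rotation (±15°),
   then Gaussian noise (mean 0, variance 0.1 on the [0,1] scale); minority
   classes are upsampled with augmented copies to the largest class count.
3. **Classification** — *TGANet*: the first five convolutional blocks of
   VGG16 (fully connected layers removed) with sigmoid attention gates on
   the intermediate features from blocks B2 and B4:

   ```
   U  = W_F * F + UP(W_G * G)        # 1x1 projections to 256 channels,
                                     # UP = bilinear upsampling of G to F's size
   A  = sigmoid(Conv(ReLU(U)))       # single-channel attention map
   F' = A ⊙ proj(F)                  # pixel-wise gating
   ```

   The two gated features F′₂, F′₄ and the global feature G are global-
   average-pooled, concatenated (256+256+512 = 1024) and classified by a
   linear softmax head.
4. **Interpretability** — the learned maps A₂, A₄ are bilinearly upsampled,
   normalized, JET-colormapped and alpha-blended onto the input image.
5. **Evaluation** — stratified 5-fold cross-validation, cross-entropy +
   Adam (lr 1e-4, 20 epochs, batch 20), best-validation-epoch checkpoint
   selection; accuracy, macro precision/recall/F1 and one-vs-rest
   (Mann–Whitney) AUC reported as mean ± sd over folds.

All networks run on a small self-contained numpy layer toolkit
(`tganet.nn`: im2col convolution, max-pooling, exact bilinear resampling
adjoints, Adam) so the package has no deep-learning-framework dependency
and trains desk-scale models on one CPU.

Because clinical tongue images cannot be redistributed, the package ships a
**synthetic tongue-image generator** (`tganet.synthetic_data`) that renders
ellipse-like tongues with class-conditional color, contour scalloping and a
root-concentrated coating texture, together with exact ground-truth masks —
every stage of the pipeline is developed and tested against it.

## Worked example

```python
import numpy as np, tganet as tg
from tganet.pipeline import TrainConfig, run_cv
from tganet.segmentation import apply_mask

spec = tg.SyntheticSpec(image_size=(64, 64), n_per_class=30,
                        task="coating", seed=0)
items, table = tg.generate_dataset(spec)
items = [tg.LabeledImage(image=apply_mask(it.image, it.mask), mask=it.mask,
                         labels=it.labels, id=it.id) for it in items]
report = run_cv(items, TrainConfig(task="coating", k_folds=3, epochs=6,
                                   width_multiplier=0.25, input_size=64,
                                   batch_size=20, seed=1))
for metric, (mean, sd) in report.summary.items():
    print(f"{metric}: {mean:.3f} +/- {sd:.3f}")
```

prints (3-fold CV of a width-0.25 model on 120 synthetic coating images):

```
acc: 0.633 +/- 0.072
precision: 0.522 +/- 0.092
recall: 0.633 +/- 0.072
f1: 0.550 +/- 0.098
auc: 0.829 +/- 0.055
```

i.e. the scaled-down model already separates the four coating classes far
above the 0.25 chance rate after six epochs, with the usual fold-to-fold
spread of small validation sets (40 images per fold). Under the full
protocol (20 epochs) held-out accuracy on this generator reaches 1.0 (see
the acceptance script below).

The same run from the shell:

```bash
tganet simulate --task coating --n-per-class 30 --size 64 --seed 0 --out data/
tganet cv --images data/images --labels data/labels.csv --task coating \
          --masks data/masks --epochs 6 --k-folds 3 \
          --width-multiplier 0.25 --seed 1 --out results/
```

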