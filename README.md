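# ovoscope

Machine-vision candling for egg viability. During incubation, hatcheries
transilluminate ("candle") eggs around 12-day embryo age and remove the
non-viable ones. `ovoscope` implements that screen as a reproducible
pipeline for three classes of transmission image:

* **unfertilized** — pale amber-yellow interior, strong shell light leakage;
* **live** — dark red interior with black blood vessels;
* **abnormal** — a dead embryo (dark foci or a blackened mass on a
  tan-brown field) or a yolk-dispersed egg (uniform yellow).

Because candling datasets are rarely shareable, the package ships a seeded
synthetic generator that renders labelled candling images with the same
visual structure (dark box, elliptical egg, shell-glow rim, wall-reflection
patch at gray 180–200, leakage at gray 254–255, sensor noise), so every
stage is testable end to end without proprietary data.

## Method

**Egg localisation.** The photograph is converted to grayscale (BT.601),
median-filtered, and thresholded by Otsu's maximum between-class variance
principle,

    σ_B²(T) = ω₀(T) ω₁(T) [μ₀(T) − μ₁(T)]²,

where ω₀/ω₁ are the class proportions and μ₀/μ₁ the class mean gray levels
induced by threshold T. Because shell leakage saturates near 255 the
automatic threshold lands mid-range, so a manual offset of **+100** is
added; this keeps dark-box wall reflections (gray ≤ 200) below the
effective threshold. The largest 8-connected foreground region is selected,
its bounding box is scaled **1.1×** about its centre to avoid truncating
the egg, and the colour crop is resized to the model input.

**Classifier.** A 34-layer residual network of basic blocks
(y = F(x, {Wᵢ}) + W_s x, stages 3/4/6/3) with a pluggable attention module
inserted in every block after the convolution stack and before the shortcut
addition:

* **CBAM** — channel gate M_c(F) = σ(MLP(AvgPool F) + MLP(MaxPool F))
  followed by spatial gate M_s(F′) = σ(f⁷ˣ⁷[AvgPool F′; MaxPool F′]),
  both applied multiplicatively;
* **SE** (squeeze-and-excitation) and **CA** (coordinate attention) for
  comparison;
* **none** for the plain baseline.

**Protocol.** Stratified 6:2:2 train/validation/test split; random
horizontal flip, centre crop and per-channel normalisation (constants from
the training split); Adam at learning rate 0.001, batch size 16,
cross-entropy loss, 50 epochs by default. Stability of the per-epoch
validation accuracy is summarised by its mean and population variance,
overall and over the first/last 10 epochs; test metrics are accuracy,
macro precision/recall/F1, a confusion matrix, and the variance of accuracy
over 10 bootstrap evaluation rounds.

The network runs on a small numpy autodiff core (`ovoscope.nn`) with
gradient-checked convolution, batch-norm, pooling and attention ops — no
deep-learning framework required.

## Worked example

```sh
ovoscope generate  --out-dir data --n-per-class 100 --seed 7
ovoscope preprocess --manifest data/manifest.csv --out-dir prep
ovoscope train --audit prep/audit.csv --config config.yaml
```

with `config.yaml` selecting the desk-scale variant:

```yaml
seed: 7
preprocess: {input_size: 96}
model: {attention: cbam, base_width: 16}
training: {epochs: 10, early_stop_accuracy: 0.97}
```

Equivalently, in Python:

```python
from ovoscope.synthetic import GeneratorParams, generate_dataset
from ovoscope.preprocess import PreprocessConfig, preprocess_pipeline
from ovoscope.models import ModelSpec, build_classifier
from ovoscope.experiment import TrainConfig, stratified_split, train_model

samples, manifest = generate_dataset(
    {"unfertilized": 100, "live": 100, "abnormal": 100},
    GeneratorParams(), seed=42)
crops = [preprocess_pipeline(s.image, PreprocessConfig(input_size=96))
         for s in samples]
```

A run under those settings prints per-epoch records like

```
EpochRecord(epoch=1, train_loss=0.783, val_accuracy=0.917)
EpochRecord(epoch=2, train_loss=0.224, val_accuracy=0.967)
EpochRecord(epoch=3, train_loss=0.170, val_accuracy=1.000)
```

and a final report with test accuracy 1.000 and macro F1 1.000 on the
held-out 60 images — on clean synthetic data with well-separated class
palettes the three classes are fully recoverable within a few epochs. The
run directory contains `epochs.csv`, `stability.json`, `eval.json`, the
loss/accuracy curves, a confusion-matrix heatmap and a reloadable
checkpoint. Each preprocessed image's audit row records its Otsu threshold
`T_otsu`, the effective threshold after the +100 offset, and the crop box.

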