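# Methods

## Problem and scope

`ovoscope` classifies transmission (candling) photographs of incubated
eggs into unfertilized, live and abnormal, with abnormal subdivided into
early/late dead-embryo and yolk-dispersed subtypes. The package covers the
full chain — synthetic image generation, egg localisation, a residual
attention classifier, and a training-stability evaluation protocol — and is
deliberately self-contained: real candling datasets are rarely
distributable, so the synthetic generator is first-class, tested code, not
a fixture.

## Synthetic imaging model

Each image is a pure function of an integer seed. The renderer emulates a
dark-box candling rig at 480×270 (1/8 of a 3840×2160 capture; full
resolution is a config change):

* **Background** — uniform dark gray (8–22) plus sensor noise.
* **Egg** — one axis-aligned ellipse (semi-axes 78–96 × 56–70 px, centre
  jittered off the image centre). The interior takes a single base colour
  drawn from a class palette, mild per-pixel mottling, and a radial
  brightness falloff (0.92–1.0) mimicking the fall-off of transmitted
  light away from the source.
* **Class palettes** (RGB corners, chosen so the three top-level classes
  occupy disjoint mean-luminance intervals — the separability knob that
  `palettes_disjoint` asserts from parameters alone):
  * unfertilized (235,210,130)–(250,225,160): pale amber-yellow,
    luminance ≈ 192–225;
  * abnormal dead (190,150,100)–(215,175,125) with darker brown patches
    and either small dark foci (early) or a blackened central mass (late);
  * abnormal yolk-dispersed (200,160,80)–(220,180,100): uniform yellow;
  * live (120,30,25)–(150,55,45): dark red, luminance ≈ 52–82, with a
    branching random-walk vessel network grown from an embryo focus
    (the literature offers no vasculature model; a seeded momentum walk
    with occasional branching reads convincingly at this scale).
* **Shell glow** — an annulus at the egg rim (width 9 px; inner half ramps,
  outer half sits at gray 235–252) where light escapes around the shell.
  This is the physical feature that makes threshold-based localisation
  well-posed for dark (live) eggs: whatever the interior luminance, the
  rim is always bright, always connected, and spans the egg's full extent.
  The band is wide enough to survive 5×5 median filtering.
* **Light leakage** — unfertilized eggs additionally get 2–4 rim arcs at
  gray 254–255, the near-saturated leakage that pushes the automatic Otsu
  threshold toward mid-range on real rigs.
* **Wall reflection** — one elliptical patch (24×16 px ≈ 7% of the egg
  area, bounded at 25% by validation so largest-region selection stays
  meaningful) at gray 180–200, placed near the image border on the side
  opposite the egg so it never touches the egg region.
* **Noise, applied last** — Gaussian intensity noise (σ = 6) and
  salt-and-pepper impulses (fraction 0.002, capped at 0.05). The impulse
  noise exists specifically to exercise the median filter.

Geometry and palettes were fixed once from histogram arithmetic: with
these masses and intensities the Otsu threshold stays in roughly
[20, 130] for every class (measured [19, 116] over 300 renders), so the
effective threshold after the +100 offset always lies above the
reflection band (200) and below the glow (235). What passing tests show is
that the localisation chain and classifier behave correctly under this
imaging model; they say nothing about shell-texture variation, multi-egg
frames, motion blur or camera miscalibration, none of which are modelled.

## Localisation chain

Grayscale uses BT.601 weights (0.299/0.587/0.114). The median filter
defaults to 5×5 with reflect edge handling (scipy's convention, which
duplicates the edge sample). Otsu maximises
σ_B²(T) = ω₀ω₁(μ₀−μ₁)² by exhaustive scan over T ∈ [0, 255]; ties break
toward the smallest maximiser, and single-level images raise a
no-contrast error instead of returning an arbitrary threshold. The offset
is additive and capped at 255; foreground is strictly greater than the
effective threshold. Components are 8-connected (robust to 1-px diagonal
gaps from noise). The selected component's tight box is scaled 1.1× about
its centre with rounding to integers, then clamped. The crop is taken from
the original colour image at original resolution and resized bilinearly to
the model input — colour is the primary class cue and must survive
preprocessing. The conventional 224×224 input is the default; the
end-to-end tests use 96×96 with a width-reduced network (below).

## Network

Canonical 34-layer residual network: 7×7/2 stem, 3×3/2 max-pool, stages of
3/4/6/3 basic blocks at widths w/2w/4w/8w, global average pool, 3-way
linear head. `base_width` w defaults to 64; w = 16 gives the desk-scale
variant. Batch norm follows every convolution (the canonical recipe);
weight init is seeded Kaiming-normal (fan-out) for convolutions, zeros for
attention biases, and N(0, 0.01) for the head. Training is from scratch —
no pretrained weights.

Attention is inserted in **every** basic block, after the second
batch-norm and before the shortcut addition, so the gates rescale only the
residual branch. CBAM uses a shared two-layer MLP with reduction ratio 16
(the original convention; configurable) and a 7×7 spatial convolution with
padding 3 (same-size output). SE uses ratio 16; CA uses ratio 32 with a
minimum bottleneck of 4 channels and h-swish, following their original
publications. Since all gates are sigmoids, outputs satisfy
0 < gate < 1 and |F″| ≤ |F| elementwise; with all attention parameters
zero the gates are exactly 0.5 — both facts are exploited as analytic
test oracles.

The numerical core is a reverse-mode autodiff engine on float32 numpy
arrays (im2col convolution with a vectorised scatter-add backward, fused
max-pool and softmax–cross-entropy, composite batch-norm). All operations
are verified against central finite differences and, for convolution,
against scipy's direct correlation.

## Protocol

* **Split** — stratified 6:2:2 by class with a seeded per-class shuffle;
  per-class counts are exact to within one sample and the partition is
  disjoint and exhaustive.
* **Augmentation** — training: random horizontal flip, centre crop,
  per-channel normalisation; evaluation: the same minus the flip, hence
  fully deterministic. Normalisation constants come from the training
  split, never from external datasets. The input resize is already part
  of preprocessing, so no extra dimensionality reduction is applied.
* **Optimisation** — Adam (β = 0.9/0.999, ε = 1e−8) at learning rate
  0.001, batch 16, mean cross-entropy, 50 epochs by default. An optional
  `early_stop_accuracy` halts once validation accuracy reaches a target;
  the desk-scale runs use 10 epochs with early stop at 0.97.
* **Stability** — mean and population (divide-by-N) variance/std of the
  validation-accuracy sequence, plus the variances of the first and last
  10 epochs (window configurable; runs shorter than two windows skip the
  windowed statistics rather than extrapolate).
* **Test evaluation** — one deterministic pass gives the confusion
  matrix, accuracy and macro precision/recall/F1 (macro because the
  classes are moderately imbalanced in practice). Because the evaluation
  path is deterministic, the 10 repeated "rounds" are seeded bootstrap
  resamples of the prediction pairs, and reports carry
  `round_mode="bootstrap"` to say so; their population variance is the
  round-to-round variance statistic.
* **Variant comparison** — every attention variant shares the same split,
  seed and normalisation constants, so table rows differ only by
  architecture.

## Problem sizes

The standard desk-scale experiment, used by the end-to-end tests and the
acceptance script, is 300 synthetic images (100 per class) preprocessed to
96×96, a width-16 ResNet34+CBAM, and at most 10 training epochs — about
two minutes per seed on one CPU. The architecture, input size and epoch
count scale up by config without code changes.

## Known limitations

* The generator's classes are separable by design; real candling images
  have overlapping appearance distributions, shell-texture noise and
  pose variation, so accuracies here are upper bounds on realism.
* Egg localisation assumes exactly one egg and one reflection patch.
* The engine is CPU-only and single-threaded beyond BLAS; full-width
  224×224 training is possible but slow.
* Population vs sample variance is indistinguishable at the reported
  precisions but is fixed to population throughout for consistency.
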