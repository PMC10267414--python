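# octseg

Semantic segmentation of retinal layers in optical coherence tomography
(OCT) B-scans, for researchers who quantify layer thickness changes in
ophthalmic disease.  A B-scan shows the retina as a stack of thin,
ordered tissue bands (NFL, GCL+IPL, INL, OPL, ONL, ELM+IS, OS, RPE over a
dark background); the package assigns every pixel to one of these nine
classes, reports the standard segmentation statistics, and explains its
predictions with uncertainty and relevance maps.

## The model

The segmenter is a multi-scale encoder–decoder built on a ConvNeXt-style
convolutional backbone:

* **Encoder.** The stem is a stride-1 4×4 convolution — unlike the usual
  4× patchify stem it performs *no* spatial reduction — so the four stage
  outputs form a feature pyramid F₁′ ∈ ℝ^(C₁×H×W), F₂′ ∈ ℝ^(C₂×H/2×W/2),
  F₃′ ∈ ℝ^(C₃×H/4×W/4), F₄′ ∈ ℝ^(C₄×H/8×W/8).  Retinal bands are only a
  few pixels thick, so the full-resolution scale carries most of the
  boundary detail.
* **Decoder.** Starting from F₄′, three rounds of {bilinear upsample ×2 →
  concatenate with the next-shallower encoder map → attention block that
  halves the channel count}, then an output convolution producing the
  per-pixel class logits.
* **Attention.** Each decoder block applies CBAM — a channel gate
  Mc = σ(MLP(AvgPool F) + MLP(MaxPool F)) followed by a spatial gate
  Ms = σ(f⁷ˣ⁷[AvgPool_c F′; MaxPool_c F′]) — and, in the depth-efficient
  variant (DE-CBAM), two depthwise-separable convolutions that halve the
  channels while deepening the block at minimal parameter cost.  A plain
  CBAM + 1×1 projection variant is available as an ablation switch.

Training follows the usual protocol for this task: per-pixel
cross-entropy, Adam with a step learning-rate schedule
(lr·γ^⌊epoch/step⌋), flip/rotation/blur/contrast augmentation of the
training split, k-fold cross-validation, and best-on-validation
checkpoint selection.  Evaluation reports per-class Dice
(2TP/(2TP+FP+FN)), IoU (TP/(TP+FP+FN)), micro pixel accuracy, and mean
per-class pixel accuracy; per-image Dice scores of two models are
compared with a two-sided Wilcoxon rank-sum test (exact by enumeration
for small samples).  Interpretation tools compute per-pixel predictive
entropy H = −Σᵢ pᵢ log pᵢ of the normalised class scores and
Grad-CAM-style relevance heatmaps at chosen decoder layers.

Everything runs on CPU: the network, its training loop and the gradients
for Grad-CAM are implemented on a small reverse-mode autodiff engine over
numpy arrays (`octseg.autodiff` / `octseg.nn`) — no GPU framework is
required.

Because the annotated clinical datasets this task is usually trained on
are large and externally hosted, the package ships a synthetic phantom
generator (`octseg.phantom`) producing fovea-centred B-scan look-alikes —
ordered non-crossing bands, a Gaussian foveal pit, per-layer reflectance
contrast, multiplicative speckle — with pixel-exact masks, so the whole
pipeline is testable and demonstrable offline.

## Worked example

```python
import numpy as np
from octseg import RetinalLayerSegmenter, PhantomConfig, generate_dataset

cfg = PhantomConfig.desk_scale(64, 96, seed=0)        # small synthetic frames
samples, split = generate_dataset(cfg, 20, seed=0)
X = np.stack([s.image for s in samples])              # (20, 64, 96) in [0,1]
y = np.stack([s.mask for s in samples])               # integer masks, 0..8

est = RetinalLayerSegmenter(stage_widths=(8, 16, 32, 64),
                            stage_depths=(1, 1, 2, 1),
                            learning_rate=0.01, max_epochs=10,
                            batch_size=2, random_state=0)
est.fit(X[:16], y[:16])
print("held-out mean foreground Dice: %.3f" % est.score(X[16:], y[16:]))
```

Output:

```
held-out mean foreground Dice: 0.925
```

0.925 is the mean Dice overlap between predicted and true masks across
the eight retinal layer classes on the four held-out phantoms (1.0 would
be pixel-perfect agreement).  The same run reports mIoU 87.7 %, pixel
accuracy 96.3 % and mean per-class pixel accuracy 93.4 % through
`octseg.evaluation.compute_metrics`; the fitted model has 92 622
parameters.  The estimator follows scikit-learn conventions
(`get_params`/`set_params`, `predict`, `predict_proba`, `score`) and the
underlying library modules (`network`, `training`, `evaluation`,
`interpret`, `dataio`, `phantom`) are usable directly.

A command-line interface covers the same workflow on directories of
PNG images and palette masks:

```bash
octseg simulate --n 206 --height 500 --width 750 --seed 7 --out data/
octseg train    --data data/ --seed 0 --epochs 16 --out run/
octseg predict  --checkpoint run/checkpoint.npz --data data/ --out pred/
octseg evaluate --pred pred/ --truth data/ --out report.csv
octseg explain  --checkpoint run/checkpoint.npz --image data/images/phantom_0000.png \
                --layer de_cbam1 --cls 3 --uncertainty --out explain/
```

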