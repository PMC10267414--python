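# Methods

This note documents the models, procedures, numerical choices and known
limitations of `octseg`, in the spirit of a package methods appendix.  It
states no empirical number that the test suite or `scripts/acceptance.py`
does not itself compute.

## Segmentation model

The network is an encoder–decoder over NCHW float64 arrays.

**Encoder.**  A ConvNeXt-style backbone with four stages.  The stem is a
4×4 convolution with stride 1 and asymmetric 'same' padding (1,2,1,2) —
the conventional 4× patchify reduction is removed so that the first stage
operates at full resolution.  Stages are separated by LayerNorm + 2×2
stride-2 convolutions; each stage is a sequence of residual blocks
(depthwise 7×7 convolution → channel LayerNorm → 1×1 expansion ×4 → GELU
→ 1×1 projection, with a learned per-channel branch scale).  Stage widths
default to (16, 32, 64, 128) and depths to (3, 3, 9, 3); only the deepest
width (128) is treated as fixed by the architecture, the rest are
configuration.  `count_parameters` reports 901 643 trainable parameters
for this default — the same order as the ~1–2 M parameter budget this
family of segmenters targets.  A compact preset `TINY_CONFIG`
(widths 8/16/32/64, depths 1/1/2/1, 92 622 parameters) is used for
CPU-scale experiments.

**Decoder.**  Three rounds of upsample ×2 → channel concatenation with the
next-shallower encoder map → attention block halving the channel count,
followed by a 3×3 convolution + LayerNorm + GELU and a 1×1 head to the
class logits.  Upsampling is bilinear by default (parameter-free, no
checkerboard artifacts); a 2×2 stride-2 transposed convolution is
selectable.  Concatenated widths must be even; this is validated at
configuration time, not at run time.

**Attention blocks.**  CBAM is implemented exactly in its published form:
channel gate `Mc = σ(MLP(AvgPool F) + MLP(MaxPool F))` with a shared
one-hidden-layer MLP (reduction ratio 16, clamped to ≤ C/2 for narrow toy
widths so the hidden layer never vanishes), then spatial gate
`Ms = σ(f7×7([AvgPool_c; MaxPool_c]))`.  The depth-efficient block
(DE-CBAM) leaves CBAM untouched and appends two depthwise-separable
convolutions (depthwise 3×3 + pointwise 1×1, each followed by LayerNorm
and GELU); the first pointwise stage halves the channels, the second
preserves them.  The ablation variant replaces the two separable
convolutions with a single 1×1 projection; it touches nothing outside the
attention blocks, so variant comparisons isolate the block design.
Whether normalisation/activation follow each separable convolution is not
fixed by the architecture family; both are present here by default.

## Compute core

No GPU framework is used.  `octseg.autodiff` is a reverse-mode
define-by-run tape over numpy with exactly the primitives the model
needs; every primitive's backward pass is verified against central finite
differences in the test suite.  Arithmetic is float64 throughout, which
makes runs bit-reproducible on a given platform and lets oracle tests use
tight tolerances.  Depthwise convolutions dispatch between a
strided-view einsum (small maps, low call overhead) and a fused
shift-multiply-accumulate loop (large maps, better memory behaviour);
the crossover is a fixed element-count threshold and does not affect
results.

Initialisation: weights are fan-in-scaled truncated normals
(std = √(2/fan_in)); biases are uniform ±1/√fan_in.  Two degeneracies
motivated this over a fixed small std: (i) with zero biases, the stem
output on a locally constant image is exactly proportional to local
intensity and the following channel LayerNorm divides that scalar out,
leaving the features blind to absolute reflectance — fatal for a task
where intensity identifies the tissue class; (ii) a fixed std of 0.02
shrinks activations several-fold at every stage, collapsing the spatial
variance of deep features and stalling optimisation at the class-marginal
solution.  Both effects were observed directly at desk scale.

## Training protocol

Per-pixel cross-entropy (mean negative log-softmax of the true class),
Adam (β = 0.9/0.999, ε = 1e-8), step learning-rate decay
lr·γ^⌊epoch/step⌋.  Full-scale defaults follow the standard protocol for
this task: lr 0.002, 300 epochs, batch 4, 4-fold cross-validation,
augmentation (horizontal flip p = 0.5, rotation ±10°, Gaussian blur
σ ∈ [0, 1], contrast ×[0.8, 1.2]) applied to the training split only,
with geometric transforms shared between image and mask (mask
nearest-neighbour, exposed corners filled with background).  "Blur" is
implemented as Gaussian blur; additive-noise readings of that step are
not emulated.  There is no early stopping: training runs its epoch
budget and the checkpoint with the best validation score is kept.  The
selection metric is mean foreground Dice (background excluded).  One
master seed derives all RNG streams — weight init, fold assignment,
batch shuffling, augmentation — so a run is replayable end to end;
a NaN loss aborts with a diagnostic rather than training through it.

Desk-scale study conditions (used by the tests and the acceptance
script, chosen once): phantoms of 64×96 px, compact widths 8/16/32/64,
lr 0.01, batch 2, 16 epochs, StepLR(12, 0.5), no augmentation.  The
higher learning rate and smaller batch compensate for the tiny number of
optimisation steps (≈ 150) relative to the full 300-epoch protocol.

## Evaluation

Metrics come from per-class one-vs-rest confusion counts:
Dice = 2TP/(2TP+FP+FN), IoU = TP/(TP+FP+FN), micro accuracy
(TP+TN)/total ≡ Σ TP/total pixels, and mean per-class pixel accuracy
mPA = mean_c TP_c/(TP_c+FN_c).  A literal "averaged accuracy" variant
(mean_c TP_c/total) exists behind `literal_eq8=True` for auditability;
it is not the default because it approximates Acc/(k+1) and cannot match
the high-90s mPA values this metric is reported at.  Classes absent from
both prediction and truth are excluded from the mIoU/mPA means;
background is included in mIoU.  Percent rendering rounds half away from
zero to one decimal.

`compare_methods` is a two-sided Wilcoxon rank-sum (Mann–Whitney) test on
per-image scores.  For pooled sizes ≤ 20 the p-value is exact by
exhaustive enumeration of all C(n₁+n₂, n₁) assignments with
p = Pr(|W − μ| ≥ |w_obs − μ|), which remains valid under ties (average
ranks); larger samples use the normal approximation with tie-corrected
variance.  Identical pooled samples return p = 1 with a warning.  Since
the images being compared are paired across methods, a signed-rank test
would also be defensible; the unpaired rank-sum form is the one
implemented, matching common practice in the segmentation literature.

## Interpretation

**Uncertainty.**  Per-pixel Shannon entropy (natural log by default,
base 2 selectable) of normalised class scores.  Raw model outputs are
translated per pixel: if the minimum score is not already positive, all
scores are shifted by −min + ε·range (ε = 1e-6 of the per-pixel range),
then divided by their sum; a score vector that is already a probability
distribution is left unchanged.  Both this translation of raw logits and
plain softmax are supported input modes, since either reading of
"normalised output" is defensible.

**Heatmaps.**  Grad-CAM adapted to dense prediction: the class score is
the sum of the class's logits over the pixels *predicted* as that class;
channel weights are spatially averaged gradients of that score w.r.t. a
chosen decoder activation (one of the three attention-block outputs or
the pre-head features); the map is the rectified weighted activation sum,
bilinearly resized to image size and min–max scaled.  This is a standard
segmentation adaptation of Grad-CAM, documented as such — no claim is
made that it matches any particular published variant.  If the requested
class is absent from the prediction the map is zero and a warning is
raised.

## Phantom generator

The generator emulates what downstream code relies on: ordered
non-crossing bands (cumulative-thickness construction, shared
low-frequency sinusoidal undulation plus independent per-boundary wobble
of half amplitude, so consecutive gaps deviate from the mean thickness by
at most the configured amplitude), a centred Gaussian foveal pit applied
to the inner boundaries with linearly decaying weight, per-layer
reflectance values in [0, 1], and multiplicative speckle
I·(1 + s·N(0,1)) clipped to [0, 1].  Masks are rasterised from the same
analytic boundaries, so they are exact.  Default full-frame geometry
(500×750, mean thickness 9.9 px) targets ~14.8 % annotated-pixel
coverage after the foveal-pit deficit, matching the reported composition
of fovea-centred healthy-eye datasets.  The `desk_scale` preset (64×96)
uses ~50 % coverage instead: at 64 px height the full-frame proportion
would leave 1-px bands, which no segmenter could resolve meaningfully.
Split proportions default to the 126:40:40 train/val/test ratio.

What the phantom does *not* emulate: physically realistic OCT speckle
statistics (spatial correlation, Rayleigh amplitude), vessel shadows,
motion artifacts, pathology (drusen, fluid), or the optic disc.  A model
that segments phantoms well has demonstrated that the architecture,
optimisation and metrics work end to end — not that it segments clinical
OCT at any particular accuracy.

## Numerical choices and degenerate inputs

- Inputs must have height and width divisible by 8 (three 2× reductions);
  `crop_or_pad` exists for this and the error message says so.
- Bilinear ×2 upsampling uses half-pixel-centre interpolation matrices,
  cached per size.
- Max-pool gradients split ties evenly, keeping gradient checks exact.
- LayerNorm ε = 1e-6 over channels, per spatial site.
- Cross-entropy subtracts the per-pixel max logit before exponentiation.
- `decode_mask` matches palette colours exactly and raises on the first
  unknown colour with its coordinate — corrupt masks fail loudly rather
  than being snapped to the nearest class.
- All-equal score vectors normalise to the uniform distribution;
  0·log 0 := 0 in entropy.

## Known limitations

- The qualitative expectation that the first decoder block's relevance
  map shows more spatial variation ("edge-like" structure) than the
  output block's does not hold at desk scale with this implementation:
  the first block operates at 1/4 resolution, so its upsampled map is
  inherently smooth, while the output block is at full resolution.  The
  test suite checks the heatmaps are distinct and non-degenerate instead.
- Float64 CPU inference is seconds per full-frame 500×750 B-scan with the
  default widths; the package is built for methodological work, not
  clinical throughput.
- Checkpoints are numpy `.npz` archives with an embedded JSON config
  snapshot; there is no interoperability with GPU-framework checkpoint
  formats.
- The phantom's per-layer thickness distributions are synthetic
  conveniences; only the aggregate annotated fraction is calibrated to a
  published reference value.
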