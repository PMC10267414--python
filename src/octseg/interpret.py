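"""Model interpretation: entropy uncertainty maps and activation heatmaps.

Uncertainty: per-pixel Shannon entropy ``H = -sum_i p_i log p_i`` of the
normalised class scores.  Raw scores (logits or probabilities) are first
translated per pixel so the minimum is strictly positive and then divided
by their sum; this is the score-to-probability translation used for the
uncertainty maps.  With natural log, H ranges over [0, log m].

Heatmaps: a Grad-CAM adaptation for dense prediction.  The class score is
the sum of that class's logits over the pixels *predicted* as the class;
channel weights are the spatially averaged gradients of this score with
respect to a chosen layer's activations, and the heatmap is the rectified
weighted activation sum, upsampled to image size and min-max scaled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from . import autodiff as ad
from .network import MultiScaleSegNet

HEATMAP_LAYERS = ("de_cbam1", "de_cbam2", "de_cbam3", "output_conv")


@dataclass(frozen=True)
class UncertaintyMap:
    """Per-pixel entropy of the normalised class scores."""

    values: np.ndarray    # (H, W), in [0, log_base(m)]
    m: int                # number of categories
    base: float           # logarithm base (e or 2)

    @property
    def max_entropy(self) -> float:
        return float(np.log(self.m) / np.log(self.base))


@dataclass(frozen=True)
class Heatmap:
    """Min-max-scaled class relevance map at image resolution."""

    values: np.ndarray    # (H, W), in [0, 1]
    layer: str
    class_index: int


def normalize_scores(scores: np.ndarray, axis: int = 0,
                     eps: float = 1e-6) -> np.ndarray:
    """Translate raw per-pixel class scores into probabilities.

    Along ``axis``: where the per-pixel minimum is not already positive,
    shift by ``-min + eps * value range`` so it becomes strictly positive;
    already-positive pixels are left untouched (a probability vector is a
    fixed point).  Then divide by the sum.  Output entries are > 0 and sum
    to 1.  A pixel whose scores are all equal maps to the uniform
    distribution.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape[axis] < 2:
        raise ValueError("need at least 2 class scores per pixel")
    lo = scores.min(axis=axis, keepdims=True)
    rng = scores.max(axis=axis, keepdims=True) - lo
    shift = np.where(lo > 0, 0.0, -lo + np.where(rng > 0, rng, 1.0) * eps)
    shifted = scores + shift
    return shifted / shifted.sum(axis=axis, keepdims=True)


def entropy_map(probs: np.ndarray, axis: int = 0,
                base: float = np.e) -> UncertaintyMap:
    """Shannon entropy of per-pixel distributions (0 log 0 := 0)."""
    p = np.asarray(probs, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    h = -plogp.sum(axis=axis) / np.log(base)
    return UncertaintyMap(values=np.maximum(h, 0.0), m=p.shape[axis],
                          base=base)


def model_uncertainty(model: MultiScaleSegNet, image: np.ndarray,
                      mode: str = "translate", base: float = np.e
                      ) -> UncertaintyMap:
    """Uncertainty map of a model's output on one image.

    ``mode='translate'`` applies :func:`normalize_scores` to the raw logits
    (the shift-and-renormalise translation); ``mode='softmax'`` uses the
    softmax probabilities directly.
    """
    logits = model.predict_logits(image[None, None] if image.ndim == 2
                                  else image)[0]
    if mode == "translate":
        probs = normalize_scores(logits, axis=0)
    elif mode == "softmax":
        probs = ad.softmax(logits, axis=0)
    else:
        raise ValueError("mode must be 'translate' or 'softmax'")
    return entropy_map(probs, axis=0, base=base)


def activation_heatmap(model: MultiScaleSegNet, image: np.ndarray,
                       layer: str, class_index: int) -> Heatmap:
    """Grad-CAM-style relevance map for one class at one decoder layer."""
    if layer not in HEATMAP_LAYERS:
        raise ValueError(f"layer must be one of {HEATMAP_LAYERS}")
    if not 0 <= class_index < model.config.n_classes:
        raise ValueError("class_index out of range")
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, None]
    H, W = arr.shape[2], arr.shape[3]

    capture: dict = {}
    logits = model.forward(arr, capture=capture)
    act = capture[layer]
    act.requires_grad = True  # retain the intermediate gradient
    pred = logits.data.argmax(axis=1)
    sel = (pred == class_index)
    if not sel.any():
        warnings.warn(f"class {class_index} absent from the prediction; "
                      "returning a zero heatmap", stacklevel=2)
        return Heatmap(values=np.zeros((H, W)), layer=layer,
                       class_index=class_index)

    # masked class score: sum of the class logits over its predicted pixels
    grad_seed = np.zeros_like(logits.data)
    grad_seed[:, class_index][sel] = 1.0
    model.zero_grad()
    logits.backward(grad_seed)

    grads = act.grad[0]          # (K, h, w)
    acts = act.data[0]
    weights = grads.mean(axis=(1, 2))
    cam = np.maximum((weights[:, None, None] * acts).sum(axis=0), 0.0)
    cam = resize(cam, (H, W), order=1, mode="edge", anti_aliasing=False)
    peak = cam.max()
    if peak > 0:
        cam = cam / peak
    return Heatmap(values=cam, layer=layer, class_index=class_index)
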