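"""Segmentation metrics, method comparison, and error maps.

Metrics are computed from one-vs-rest confusion counts per class:
``Dice = 2TP / (2TP + FP + FN)``, ``IoU = TP / (TP + FP + FN)``,
micro accuracy ``Acc = (TP + TN) / total``, and mean pixel accuracy
``mPA = mean_c TP_c / (TP_c + FN_c)``.  Classes absent from both the
prediction and the ground truth are excluded from the mIoU/mPA means.

``compare_methods`` is a two-sided Wilcoxon rank-sum (Mann-Whitney) test on
per-image scores: exact by exhaustive enumeration for small pooled samples
(which stays valid under ties), normal approximation with tie correction
otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-class one-vs-rest pixel tallies."""

    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray

    def __post_init__(self):
        total = self.tp + self.tn + self.fp + self.fn
        if not np.all(total == total[0]):
            raise ValueError("per-class counts must each sum to the pixel total")

    @property
    def n_classes(self) -> int:
        return len(self.tp)

    @property
    def total_pixels(self) -> int:
        return int(self.tp[0] + self.tn[0] + self.fp[0] + self.fn[0])

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricReport:
    """Per-class Dice/IoU plus aggregate mIoU, Acc, mPA (all in [0, 1]).

    Per-class entries for classes absent from both masks are NaN and are
    excluded from the aggregate means.
    """

    dice: np.ndarray
    iou: np.ndarray
    miou: float
    acc: float
    mpa: float

    def as_frame(self, class_names=None) -> pd.DataFrame:
        n = len(self.dice)
        names = class_names or [f"class_{c}" for c in range(n)]
        return pd.DataFrame({"class": names, "dice": self.dice, "iou": self.iou})

    def percent(self, value: float) -> float:
        """Render a [0,1] metric as a percentage with 1 decimal,
        rounding half away from zero (table formatting)."""
        return np.floor(value * 1000.0 + 0.5) / 10.0


def confusion(pred: np.ndarray, true: np.ndarray, n_classes: int
              ) -> ConfusionCounts:
    """One-vs-rest TP/TN/FP/FN pixel counts for each class."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    for name, arr in (("pred", pred), ("true", true)):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{name} labels must lie in [0, {n_classes - 1}]")
    cm = np.bincount(true.ravel() * n_classes + pred.ravel(),
                     minlength=n_classes * n_classes
                     ).reshape(n_classes, n_classes)
    tp = np.diag(cm).astype(np.int64)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    tn = cm.sum() - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def compute_metrics(counts: ConfusionCounts,
                    literal_eq8: bool = False) -> MetricReport:
    """Dice/IoU per class and mIoU/Acc/mPA aggregates from counts.

    ``literal_eq8=True`` switches mPA to the (non-standard) form
    ``mean_c TP_c / total`` for auditability; the default is the
    conventional mean per-class pixel accuracy TP/(TP+FN).
    """
    tp = counts.tp.astype(float)
    fp = counts.fp.astype(float)
    fn = counts.fn.astype(float)
    tn = counts.tn.astype(float)
    present = (tp + fn + fp) > 0          # class appears in pred or truth
    if not present.any():
        raise ValueError("all classes empty: metrics are undefined")

    with np.errstate(divide="ignore", invalid="ignore"):
        dice = np.where(present, 2 * tp / np.maximum(2 * tp + fp + fn, 1e-300),
                        np.nan)
        iou = np.where(present, tp / np.maximum(tp + fp + fn, 1e-300), np.nan)
        if literal_eq8:
            pa = np.where(present, tp / (tp + tn + fp + fn), np.nan)
        else:
            pa = np.where(present & (tp + fn > 0),
                          tp / np.maximum(tp + fn, 1e-300), np.nan)

    total = counts.total_pixels
    acc = float(tp.sum() / total)
    return MetricReport(dice=dice, iou=iou,
                        miou=float(np.nanmean(iou)),
                        acc=acc,
                        mpa=float(np.nanmean(pa)))


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum comparison
# ---------------------------------------------------------------------------

_EXACT_MAX_POOLED = 20  # exhaustive enumeration up to C(20, 10) = 184 756 splits


def compare_methods(scores_a, scores_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value on two sets of per-image scores.

    The statistic is the rank sum of sample A over the pooled ranking
    (average ranks on ties).  For pooled sizes <= 20 the p-value is exact:
    all C(n1+n2, n1) label assignments are enumerated and
    ``p = Pr(|W - mu| >= |w_obs - mu|)`` under the permutation null, which
    remains correct in the presence of ties.  Larger samples use the normal
    approximation with the usual tie-corrected variance.

    Identical pooled values give p = 1 (with a warning): every assignment
    produces the same statistic.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    pooled = np.concatenate([a, b])
    n1, n2 = a.size, b.size
    N = n1 + n2
    if np.ptp(pooled) == 0:
        warnings.warn("all pooled values identical; rank-sum test degenerate, "
                      "returning p = 1", stacklevel=2)
        return 1.0
    ranks = stats.rankdata(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (N + 1) / 2.0

    if N <= _EXACT_MAX_POOLED:
        dev = abs(w_obs - mu) - 1e-9
        hits = 0
        for idx in combinations(range(N), n1):
            if abs(ranks[list(idx)].sum() - mu) >= dev:
                hits += 1
        return hits / comb(N, n1)

    # tie-corrected normal approximation
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (N * (N - 1))
    sigma2 = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    z = (w_obs - mu) / np.sqrt(sigma2)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def error_map(pred: np.ndarray, true: np.ndarray):
    """Binary disagreement map and the disagreement fraction (= 1 - Acc)."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    if pred.shape != true.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {true.shape}")
    emap = (pred != true).astype(np.uint8)
    return emap, float(emap.mean())
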