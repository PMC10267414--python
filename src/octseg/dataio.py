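"""Reading/writing image + palette-mask pairs, augmentation, crops, folds.

Annotation masks are colour-palette PNGs: each retinal layer class is one
exact RGB colour, background is black.  Decoding is exact-match — a pixel
whose colour is not in the palette raises, naming the colour and coordinate,
rather than being silently snapped to the nearest class.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image
from scipy import ndimage
from sklearn.model_selection import KFold

#: Class names of the 8-layer + background layout.
NR206_CLASS_NAMES = ("background", "NFL", "GCL+IPL", "INL", "OPL", "ONL",
                     "ELM+IS", "OS", "RPE")

#: Annotation colours: red, brown, yellow, dark green, light green,
#: light blue, dark blue, pink for NFL ... RPE; black background.
NR206_COLORS = (
    (0, 0, 0),        # background
    (255, 0, 0),      # NFL          red
    (139, 69, 19),    # GCL+IPL      brown
    (255, 255, 0),    # INL          yellow
    (0, 100, 0),      # OPL          dark green
    (144, 238, 144),  # ONL          light green
    (173, 216, 230),  # ELM+IS       light blue
    (0, 0, 139),      # OS           dark blue
    (255, 192, 203),  # RPE          pink
)


@dataclass(frozen=True)
class ClassPalette:
    """Ordered, injective mapping class index -> RGB triple; class 0 black."""

    colors: tuple = NR206_COLORS
    names: tuple | None = NR206_CLASS_NAMES

    def __post_init__(self):
        if len(set(self.colors)) != len(self.colors):
            raise ValueError("palette colors must be distinct")
        if tuple(self.colors[0]) != (0, 0, 0):
            raise ValueError("class 0 must be black background")
        if self.names is not None and len(self.names) != len(self.colors):
            raise ValueError("names/colors length mismatch")

    @property
    def n_classes(self) -> int:
        return len(self.colors)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.colors, dtype=np.uint8)


DEFAULT_PALETTE = ClassPalette()


def encode_mask(labels: np.ndarray, palette: ClassPalette = DEFAULT_PALETTE
                ) -> np.ndarray:
    """Integer label grid -> (H, W, 3) uint8 RGB image."""
    labels = np.asarray(labels)
    if labels.min() < 0 or labels.max() >= palette.n_classes:
        raise ValueError(f"labels must lie in [0, {palette.n_classes - 1}]")
    return palette.as_array()[labels]


def decode_mask(rgb_image: np.ndarray, palette: ClassPalette = DEFAULT_PALETTE
                ) -> np.ndarray:
    """(H, W, 3) RGB image -> integer label grid (exact colour match)."""
    rgb = np.asarray(rgb_image)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    rgb = rgb.astype(np.int64)
    key = (rgb[..., 0] << 16) | (rgb[..., 1] << 8) | rgb[..., 2]
    lut = {(c[0] << 16) | (c[1] << 8) | c[2]: i
           for i, c in enumerate(palette.colors)}
    labels = np.full(key.shape, -1, dtype=np.int64)
    for colour_key, idx in lut.items():
        labels[key == colour_key] = idx
    if (labels < 0).any():
        r, c = np.argwhere(labels < 0)[0]
        raise ValueError(
            f"unknown mask colour {tuple(int(v) for v in rgb[r, c])} "
            f"at pixel (row={r}, col={c})")
    return labels


def save_image_png(path: str | os.PathLike, image: np.ndarray) -> None:
    """Save a [0,1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.round(np.asarray(image) * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def load_image_png(path: str | os.PathLike) -> np.ndarray:
    """Load a grayscale PNG as a [0,1] float array."""
    return np.asarray(Image.open(path).convert("L"), dtype=float) / 255.0


def save_mask_png(path: str | os.PathLike, labels: np.ndarray,
                  palette: ClassPalette = DEFAULT_PALETTE) -> None:
    """Save a label grid as a palettised PNG using the class colours."""
    labels = np.asarray(labels)
    img = Image.fromarray(labels.astype(np.uint8), mode="P")
    flat = list(np.asarray(palette.colors, dtype=np.uint8).reshape(-1))
    img.putpalette(flat)
    img.save(path)


def load_mask_png(path: str | os.PathLike,
                  palette: ClassPalette = DEFAULT_PALETTE) -> np.ndarray:
    """Load a palette or RGB mask PNG back into an integer label grid."""
    rgb = np.asarray(Image.open(path).convert("RGB"))
    return decode_mask(rgb, palette)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentationConfig:
    """Stochastic augmentation: flip, rotation, blur, contrast.

    ``blur_sigma_range`` of (0, 0) disables blurring; ``contrast_range`` of
    (1, 1) leaves contrast untouched.  Rotation angles are degrees, drawn
    uniformly from ``[-rotation_range, rotation_range]``.
    """

    hflip_probability: float = 0.5
    rotation_range: float = 10.0
    blur_sigma_range: tuple = (0.0, 1.0)
    contrast_range: tuple = (0.8, 1.2)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.hflip_probability <= 1.0:
            raise ValueError("hflip_probability must lie in [0, 1]")
        if self.rotation_range < 0:
            raise ValueError("rotation_range must be >= 0")
        for name in ("blur_sigma_range", "contrast_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be well ordered")


def augment(sample, config: AugmentationConfig, rng_seed: int | None = None,
            force_hflip: bool | None = None):
    """Apply one random augmentation draw to an image/mask pair.

    Geometric transforms (flip, rotation) hit image and mask identically;
    the mask is interpolated nearest-neighbour and exposed rotation corners
    are filled with background.  Blur and contrast touch the image only.
    ``force_hflip`` overrides the coin flip (used for involution tests).
    """
    from .phantom import AnnotatedBScan  # local import to avoid a cycle

    rng = np.random.default_rng(config.seed if rng_seed is None else rng_seed)
    image = sample.image.astype(float).copy()
    mask = sample.mask.copy()

    do_flip = (rng.random() < config.hflip_probability
               if force_hflip is None else force_hflip)
    if do_flip:
        image = image[:, ::-1].copy()
        mask = mask[:, ::-1].copy()

    if config.rotation_range > 0:
        angle = rng.uniform(-config.rotation_range, config.rotation_range)
        if angle != 0.0:
            image = ndimage.rotate(image, angle, reshape=False, order=1,
                                   mode="constant", cval=0.0)
            mask = ndimage.rotate(mask, angle, reshape=False, order=0,
                                  mode="constant", cval=0)

    lo, hi = config.blur_sigma_range
    if hi > 0:
        sigma = rng.uniform(lo, hi)
        if sigma > 0:
            image = ndimage.gaussian_filter(image, sigma)

    lo, hi = config.contrast_range
    if (lo, hi) != (1.0, 1.0):
        factor = rng.uniform(lo, hi)
        mean = image.mean()
        image = (image - mean) * factor + mean

    image = np.clip(image, 0.0, 1.0)
    return AnnotatedBScan(image=image, mask=mask)


def crop_or_pad(sample, target: tuple):
    """Centre-crop (when larger) or zero-pad (when smaller) to target size.

    Padding uses background label 0 and image value 0; excess of one pixel
    goes to the bottom/right side.
    """
    from .phantom import AnnotatedBScan

    th, tw = target
    if th <= 0 or tw <= 0:
        raise ValueError("target dimensions must be positive")
    image, mask = sample.image, sample.mask

    def _fit(arr, size, axis, pad_value):
        n = arr.shape[axis]
        if n > size:
            start = (n - size) // 2
            sl = [slice(None)] * arr.ndim
            sl[axis] = slice(start, start + size)
            return arr[tuple(sl)]
        if n < size:
            before = (size - n) // 2
            after = size - n - before
            pads = [(0, 0)] * arr.ndim
            pads[axis] = (before, after)
            return np.pad(arr, pads, constant_values=pad_value)
        return arr

    for axis, size in ((0, th), (1, tw)):
        image = _fit(image, size, axis, 0.0)
        mask = _fit(mask, size, axis, 0)
    return AnnotatedBScan(image=image.copy(), mask=mask.copy())


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Disjoint train/val/test id lists (test may be empty for CV folds)."""

    train: tuple
    val: tuple
    test: tuple = ()
    fold_index: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "train", tuple(self.train))
        object.__setattr__(self, "val", tuple(self.val))
        object.__setattr__(self, "test", tuple(self.test))
        groups = (set(self.train), set(self.val), set(self.test))
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise ValueError("train/val/test lists must be pairwise disjoint")

    @property
    def all_ids(self) -> tuple:
        return self.train + self.val + self.test


def make_folds(sample_ids, k: int, seed: int = 0) -> list[SplitSpec]:
    """Shuffled k-fold split: each id lands in exactly one validation list.

    Validation sizes differ by at most one; fold assignment is a
    deterministic function of (sample_ids, k, seed).
    """
    sample_ids = list(sample_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(sample_ids):
        raise ValueError(f"cannot make {k} folds from {len(sample_ids)} ids")
    kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for i, (train_idx, val_idx) in enumerate(kf.split(sample_ids)):
        folds.append(SplitSpec(train=[sample_ids[j] for j in train_idx],
                               val=[sample_ids[j] for j in val_idx],
                               fold_index=i))
    return folds


# ---------------------------------------------------------------------------
# on-disk dataset layout
# ---------------------------------------------------------------------------

def write_dataset(out_dir: str | os.PathLike, samples, split: SplitSpec,
                  palette: ClassPalette = DEFAULT_PALETTE) -> None:
    """Write image/mask PNG pairs plus a plain-text split manifest.

    Layout: ``images/<id>.png``, ``masks/<id>.png``, and ``manifest.txt``
    with lines ``<split>\t<image path>\t<mask path>``.
    """
    out_dir = os.fspath(out_dir)
    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)
    ids = split.all_ids
    if len(ids) != len(samples):
        raise ValueError("split does not cover the sample collection")
    membership = {sid: name for name in ("train", "val", "test")
                  for sid in getattr(split, name)}
    lines = []
    for sid, sample in zip(ids, samples):
        img_rel = os.path.join("images", f"{sid}.png")
        msk_rel = os.path.join("masks", f"{sid}.png")
        save_image_png(os.path.join(out_dir, img_rel), sample.image)
        save_mask_png(os.path.join(out_dir, msk_rel), sample.mask, palette)
        lines.append(f"{membership[sid]}\t{img_rel}\t{msk_rel}")
    with open(os.path.join(out_dir, "manifest.txt"), "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_dataset(data_dir: str | os.PathLike,
                 palette: ClassPalette = DEFAULT_PALETTE):
    """Read a dataset written by :func:`write_dataset`.

    Returns (samples, split) with samples ordered train, val, test.
    """
    from .phantom import AnnotatedBScan

    data_dir = os.fspath(data_dir)
    groups: dict[str, list] = {"train": [], "val": [], "test": []}
    records: dict[str, AnnotatedBScan] = {}
    with open(os.path.join(data_dir, "manifest.txt")) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            part, img_rel, msk_rel = line.split("\t")
            sid = os.path.splitext(os.path.basename(img_rel))[0]
            groups[part].append(sid)
            records[sid] = AnnotatedBScan(
                image=load_image_png(os.path.join(data_dir, img_rel)),
                mask=load_mask_png(os.path.join(data_dir, msk_rel), palette))
    split = SplitSpec(train=groups["train"], val=groups["val"],
                      test=groups["test"])
    samples = [records[sid] for sid in split.all_ids]
    return samples, split
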