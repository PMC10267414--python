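"""Synthetic OCT B-scan phantoms with pixel-exact layer masks.

A phantom emulates the gross geometry of a fovea-centred retinal B-scan:
a stack of ordered, non-crossing layer bands (NFL ... RPE by default), a
central foveal pit where the inner layers thin out, per-layer reflectance
contrast, and multiplicative speckle noise.  Masks are generated from the
same analytic boundaries that render the image, so they are exact by
construction.  The generator exists so the whole pipeline — training,
evaluation, interpretation — is exercisable without any external dataset.

Geometry convention: row index increases downward; band j occupies the
half-open row interval [boundary_j(x), boundary_{j+1}(x)) in column x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import SplitSpec

#: Default per-class reflectance (index 0 = background/vitreous, then the
#: eight layers NFL, GCL+IPL, INL, OPL, ONL, ELM+IS, OS, RPE).  Values are
#: loosely modelled on typical B-scan contrast: bright NFL and RPE, dark
#: nuclear layers; what matters for the pipeline is that adjacent bands have
#: distinct reflectance.
DEFAULT_INTENSITIES = (0.06, 0.85, 0.30, 0.55, 0.70, 0.22, 0.62, 0.42, 0.92)


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the synthetic B-scan generator.

    Defaults emulate the 500x750, 8-layer-plus-background layout with the
    layer stack covering ~14.8% of the frame.
    """

    height: int = 500
    width: int = 750
    n_layers: int = 8
    mean_thickness: float = 9.9           # px per layer
    boundary_amplitude: float = 4.0       # px, peak undulation
    boundary_wavelength: float = 300.0    # px
    pit_depth: float = 25.0               # px, foveal pit
    pit_width: float = 60.0               # px, Gaussian sigma of the pit
    top_margin_frac: float = 0.35         # inner surface position / height
    layer_intensities: tuple = DEFAULT_INTENSITIES
    speckle_level: float = 0.10           # multiplicative noise scale
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return self.n_layers + 1

    @classmethod
    def for_frame(cls, height: int, width: int, seed: int = 0) -> "PhantomConfig":
        """Geometry scaled to an arbitrary frame size.

        Large frames keep the reference 500x750 proportions (~14.8% band
        coverage); small frames fall back to :meth:`desk_scale`, where bands
        are kept several pixels thick."""
        if height >= 320:
            sh, sw = height / 500.0, width / 750.0
            return cls(height=height, width=width,
                       mean_thickness=9.9 * sh, boundary_amplitude=4.0 * sh,
                       boundary_wavelength=300.0 * sw, pit_depth=25.0 * sh,
                       pit_width=60.0 * sw, seed=seed)
        return cls.desk_scale(height, width, seed=seed)

    @classmethod
    def desk_scale(cls, height: int = 64, width: int = 96,
                   seed: int = 0) -> "PhantomConfig":
        """A small-frame preset for CPU-scale experiments and tests.

        Band geometry is rescaled so eight layers remain several pixels
        thick (bands cover ~half the frame height rather than the full
        frame's ~15%, which at this size would leave 1-px bands)."""
        t = height * 0.5 / 8
        return cls(height=height, width=width, mean_thickness=t,
                   boundary_amplitude=min(2.0, t / 2), boundary_wavelength=width * 0.6,
                   pit_depth=height * 0.1, pit_width=width * 0.12,
                   top_margin_frac=0.25, seed=seed)

    def validate(self) -> None:
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        for name in ("mean_thickness", "boundary_amplitude", "pit_depth",
                     "pit_width", "speckle_level"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if len(self.layer_intensities) != self.n_layers + 1:
            raise ValueError("layer_intensities must have n_layers + 1 entries "
                             "(background first)")
        if not all(0.0 <= v <= 1.0 for v in self.layer_intensities):
            raise ValueError("layer intensities must lie in [0, 1]")
        stack = self.top_margin_frac * self.height \
            + self.n_layers * self.mean_thickness + self.boundary_amplitude
        if stack >= self.height:
            raise ValueError(
                f"band stack ({stack:.1f} px incl. top margin) does not fit "
                f"in a {self.height}-px frame")


@dataclass(frozen=True)
class LayerBoundarySet:
    """n_layers+1 ordered boundary curves, one real row value per column."""

    boundaries: np.ndarray  # (n_layers+1, width)
    height: int

    def __post_init__(self):
        b = self.boundaries
        if np.any(np.diff(b, axis=0) < 0):
            raise ValueError("boundaries must be non-crossing")
        if b.min() < 0 or b.max() > self.height:
            raise ValueError("boundaries must lie within [0, height]")

    @property
    def n_layers(self) -> int:
        return self.boundaries.shape[0] - 1


@dataclass(frozen=True)
class AnnotatedBScan:
    """A grayscale image with its integer label mask (0 = background)."""

    image: np.ndarray  # (H, W) float in [0, 1]
    mask: np.ndarray   # (H, W) int in [0, C-1]

    def __post_init__(self):
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")

    @property
    def shape(self):
        return self.image.shape


def _sinusoid_sum(rng: np.random.Generator, x: np.ndarray, wavelength: float,
                  amplitude: float) -> np.ndarray:
    """Sum of 3 random-phase sinusoids, rescaled to the requested peak."""
    if amplitude == 0:
        return np.zeros_like(x)
    out = np.zeros_like(x)
    for k in range(1, 4):
        lam = wavelength / k
        out += rng.uniform(0.3, 1.0) * np.sin(2 * np.pi * x / lam
                                              + rng.uniform(0, 2 * np.pi))
    peak = np.abs(out).max()
    if peak > 0:
        out *= amplitude / peak
    return out


def sample_boundaries(config: PhantomConfig,
                      rng_seed: int | None = None) -> LayerBoundarySet:
    """Draw a set of smooth, non-crossing layer boundary curves.

    The inner surface carries a shared low-frequency undulation plus the
    foveal pit; each boundary additionally gets an independent wobble of
    half the configured amplitude, so consecutive-boundary gaps deviate
    from the mean thickness by at most ``boundary_amplitude``.  Stacking
    cumulative thicknesses guarantees ordering; a final running maximum
    enforces it exactly even in extreme configurations.
    """
    config.validate()
    seed = config.seed if rng_seed is None else rng_seed
    rng = np.random.default_rng(seed)
    x = np.arange(config.width, dtype=float)

    shared = _sinusoid_sum(rng, x, config.boundary_wavelength,
                           config.boundary_amplitude)
    centre = (config.width - 1) / 2.0
    pit = config.pit_depth * np.exp(-0.5 * ((x - centre)
                                            / max(config.pit_width, 1e-9)) ** 2) \
        if config.pit_depth > 0 else np.zeros_like(x)

    top = config.top_margin_frac * config.height
    n_b = config.n_layers + 1
    # pit weight decays linearly over the inner half of the boundaries, so
    # the inner surface dips fully while the outer layers stay put
    n_pit = max(2, (n_b + 1) // 2)
    curves = np.empty((n_b, config.width))
    for j in range(n_b):
        wobble = _sinusoid_sum(rng, x, config.boundary_wavelength / 2.0,
                               config.boundary_amplitude / 2.0)
        pit_w = max(0.0, 1.0 - j / (n_pit - 1)) if config.pit_depth > 0 else 0.0
        curves[j] = (top + j * config.mean_thickness + shared
                     + (wobble if config.boundary_amplitude > 0 else 0.0)
                     + pit_w * pit)
    curves = np.maximum.accumulate(curves, axis=0)
    curves = np.clip(curves, 0.0, float(config.height))
    return LayerBoundarySet(boundaries=curves, height=config.height)


def render_bscan(boundaries: LayerBoundarySet, config: PhantomConfig,
                 rng_seed: int | None = None) -> AnnotatedBScan:
    """Rasterise boundary curves into an image + pixel-exact mask.

    Pixel (r, x) gets the label of the band whose interval
    [boundary_j(x), boundary_{j+1}(x)) contains the row index r; rows above
    the first or below the last boundary are background.  The image is the
    per-class reflectance composited with multiplicative speckle
    ``I * (1 + s * N(0,1))``, clipped to [0, 1].
    """
    config.validate()
    H, W = config.height, config.width
    rows = np.arange(H, dtype=float)[:, None]          # (H, 1)
    # count of boundaries at or above each pixel row
    idx = (rows >= boundaries.boundaries[:, None, :]).sum(axis=0)  # (H, W)
    mask = np.where((idx >= 1) & (idx <= config.n_layers), idx, 0).astype(np.int64)

    intensities = np.asarray(config.layer_intensities, dtype=float)
    image = intensities[mask]
    if config.speckle_level > 0:
        seed = config.seed + 1 if rng_seed is None else rng_seed
        rng = np.random.default_rng(seed)
        image = image * (1.0 + config.speckle_level * rng.standard_normal((H, W)))
    image = np.clip(image, 0.0, 1.0)
    return AnnotatedBScan(image=image, mask=mask)


def generate_phantom(config: PhantomConfig,
                     rng_seed: int | None = None) -> AnnotatedBScan:
    """Convenience: boundaries + rendering from one seed."""
    seed = config.seed if rng_seed is None else rng_seed
    bounds = sample_boundaries(config, rng_seed=seed)
    return render_bscan(bounds, config, rng_seed=seed + 1)


# train : val : test proportions of the reference 206-image layout
_SPLIT_PROPS = (126 / 206, 40 / 206, 40 / 206)


def default_split_sizes(n_images: int) -> tuple[int, int, int]:
    """Split ``n_images`` in ~126:40:40 proportions, each part non-empty."""
    if n_images < 3:
        raise ValueError("need at least 3 images to form three splits")
    n_val = max(1, round(n_images * _SPLIT_PROPS[1]))
    n_test = max(1, round(n_images * _SPLIT_PROPS[2]))
    n_train = n_images - n_val - n_test
    if n_train < 1:
        n_train, n_val, n_test = n_images - 2, 1, 1
    return n_train, n_val, n_test


def generate_dataset(config: PhantomConfig, n_images: int,
                     seed: int | None = None
                     ) -> tuple[list[AnnotatedBScan], SplitSpec]:
    """Generate ``n_images`` phantoms plus a train/val/test split.

    Per-image seeds are spawned from the master seed via
    ``numpy.random.SeedSequence`` so the collection is reproducible and
    images are mutually independent.
    """
    master = config.seed if seed is None else seed
    n_train, n_val, n_test = default_split_sizes(n_images)
    child_seeds = np.random.SeedSequence(master).generate_state(n_images)
    samples = [generate_phantom(config, rng_seed=int(s % (2 ** 30)) * 2)
               for s in child_seeds]
    ids = [f"phantom_{i:04d}" for i in range(n_images)]
    split = SplitSpec(train=ids[:n_train],
                      val=ids[n_train:n_train + n_val],
                      test=ids[n_train + n_val:])
    return samples, split
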