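"""Multi-scale encoder-decoder segmentation network with attention.

Architecture summary
--------------------
* **Encoder**: a ConvNeXt-style backbone whose stem performs *no* spatial
  reduction (stride-1 4x4 convolution), so the four stage outputs form a
  feature pyramid at scales 1, 1/2, 1/4 and 1/8 of the input:
  F1' (C1 x H x W) ... F4' (C4 x H/8 x W/8).  Keeping the full-resolution
  scale preserves the thin-band detail that retinal layers demand.
* **Decoder**: three iterations of {upsample x2 -> concatenate with the
  next-shallower encoder map -> attention block that halves the channel
  count}, then an output convolution to the class logits.  The attention
  block is either plain CBAM (channel + spatial gates) with a 1x1 halving
  projection, or the depth-efficient variant (DE-CBAM): CBAM followed by two
  depthwise-separable convolutions, the first of which halves the channels.

Channel attention: ``Mc = sigma(MLP(AvgPool(F)) + MLP(MaxPool(F)))`` with a
shared one-hidden-layer MLP; spatial attention:
``Ms = sigma(f7x7([AvgPool_c(F); MaxPool_c(F)]))``.  The refined map is
``F'' = Ms(F') * F'`` with ``F' = Mc(F) * F``.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from . import nn
from .autodiff import Tensor


@dataclass(frozen=True)
class NetworkConfig:
    in_channels: int = 1
    n_classes: int = 9
    stage_widths: tuple = (16, 32, 64, 128)
    stage_depths: tuple = (3, 3, 9, 3)
    depthwise_kernel: int = 7
    expansion_ratio: int = 4
    cam_reduction: int = 16
    sam_kernel: int = 7
    attention_variant: str = "de_cbam"   # or "cbam"
    upsample_mode: str = "bilinear"      # or "transposed"
    seed: int = 0

    def validate(self) -> None:
        if len(self.stage_widths) != 4 or len(self.stage_depths) != 4:
            raise ValueError("four encoder stages are required")
        if any(w <= 0 for w in self.stage_widths) or \
           any(d <= 0 for d in self.stage_depths):
            raise ValueError("stage widths and depths must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.sam_kernel % 2 == 0:
            raise ValueError("sam_kernel must be odd")
        if self.attention_variant not in ("cbam", "de_cbam"):
            raise ValueError("attention_variant must be 'cbam' or 'de_cbam'")
        if self.upsample_mode not in ("bilinear", "transposed"):
            raise ValueError("upsample_mode must be 'bilinear' or 'transposed'")
        for cin in self.decoder_in_channels():
            if cin % 2:
                raise ValueError(
                    f"decoder concat width {cin} is odd; choose stage widths "
                    "whose pairwise sums are even so channels can be halved")

    def decoder_in_channels(self) -> tuple:
        """Concatenated channel count entering each decoder attention block."""
        c1, c2, c3, c4 = self.stage_widths
        d1 = c3 + c4
        d2 = c2 + d1 // 2
        d3 = c1 + d2 // 2
        return (d1, d2, d3)


#: A compact configuration used for desk-scale experiments and tests.
TINY_CONFIG = NetworkConfig(stage_widths=(8, 16, 32, 64),
                            stage_depths=(1, 1, 2, 1))


@dataclass(frozen=True)
class FeaturePyramid:
    """Encoder outputs F1'..F4' at scales 1, 1/2, 1/4, 1/8."""

    f1: Tensor
    f2: Tensor
    f3: Tensor
    f4: Tensor

    def shapes(self):
        return tuple(t.shape for t in (self.f1, self.f2, self.f3, self.f4))


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class ConvNeXtBlock(nn.Module):
    """Depthwise 7x7 -> LN -> 1x1 expand -> GELU -> 1x1 project, residual,
    with a learned per-channel scale on the branch."""

    def __init__(self, channels, rng, kernel=7, expansion=4):
        super().__init__()
        hidden = channels * expansion
        self.dw = nn.DepthwiseConv2d(channels, kernel, rng)
        self.norm = nn.LayerNorm2d(channels)
        self.pw1 = nn.Conv2d(channels, hidden, 1, rng)
        self.act = nn.GELU()
        self.pw2 = nn.Conv2d(hidden, channels, 1, rng)
        self.scale = Tensor(np.full(channels, 1e-2), requires_grad=True)

    def forward(self, x):
        y = self.pw2(self.act(self.pw1(self.norm(self.dw(x)))))
        y = ad.mul(y, ad.reshape(self.scale, (1, -1, 1, 1)))
        return ad.add(x, y)


class ChannelAttention(nn.Module):
    """CBAM channel gate: shared MLP over global average and max pools."""

    def __init__(self, channels, rng, reduction=16):
        super().__init__()
        # clamp the bottleneck for narrow maps so hidden width stays >= 1
        r = min(reduction, max(1, channels // 2))
        hidden = max(1, channels // r)
        self.fc1 = nn.Linear(channels, hidden, rng)
        self.fc2 = nn.Linear(hidden, channels, rng)

    def _mlp(self, v):
        return self.fc2(ad.relu(self.fc1(v)))

    def forward(self, x) -> Tensor:
        """Return Mc with shape (N, C, 1, 1), values strictly in (0, 1)."""
        avg = ad.tmean(x, axis=(2, 3))               # (N, C)
        mx = ad.tmax(x, axis=(2, 3), keepdims=False)  # (N, C)
        mc = ad.sigmoid(ad.add(self._mlp(avg), self._mlp(mx)))
        n, c = mc.shape
        return ad.reshape(mc, (n, c, 1, 1))


class SpatialAttention(nn.Module):
    """CBAM spatial gate: 7x7 convolution over channelwise avg/max maps."""

    def __init__(self, rng, kernel=7):
        super().__init__()
        self.conv = nn.Conv2d(2, 1, kernel, rng, padding=kernel // 2)

    def forward(self, x) -> Tensor:
        """Return Ms with shape (N, 1, H, W), values strictly in (0, 1)."""
        avg = ad.tmean(x, axis=1, keepdims=True)
        mx = ad.tmax(x, axis=1, keepdims=True)
        return ad.sigmoid(self.conv(ad.concat([avg, mx], axis=1)))


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention refinement."""

    def __init__(self, channels, rng, reduction=16, sam_kernel=7):
        super().__init__()
        self.cam = ChannelAttention(channels, rng, reduction)
        self.sam = SpatialAttention(rng, sam_kernel)

    def forward(self, x):
        f1 = ad.mul(self.cam(x), x)     # F'  = Mc(F) * F
        return ad.mul(self.sam(f1), f1)  # F'' = Ms(F') * F'


class DepthwiseSeparableConv(nn.Module):
    """Depthwise kxk + pointwise 1x1, followed by LN and GELU."""

    def __init__(self, in_ch, out_ch, rng, kernel=3):
        super().__init__()
        self.dw = nn.DepthwiseConv2d(in_ch, kernel, rng)
        self.pw = nn.Conv2d(in_ch, out_ch, 1, rng)
        self.norm = nn.LayerNorm2d(out_ch)
        self.act = nn.GELU()

    def forward(self, x):
        return self.act(self.norm(self.pw(self.dw(x))))


class DECBAM(nn.Module):
    """Depth-efficient attention block: CBAM (unchanged) followed by two
    depthwise-separable convolutions; the first halves the channel count,
    the second preserves it.  Spatial size is preserved throughout."""

    def __init__(self, channels, rng, reduction=16, sam_kernel=7):
        super().__init__()
        if channels % 2:
            raise ValueError("DE-CBAM requires an even channel count")
        self.cbam = CBAM(channels, rng, reduction, sam_kernel)
        self.ds1 = DepthwiseSeparableConv(channels, channels // 2, rng)
        self.ds2 = DepthwiseSeparableConv(channels // 2, channels // 2, rng)

    def forward(self, x):
        return self.ds2(self.ds1(self.cbam(x)))


class CBAMProject(nn.Module):
    """Ablation variant: CBAM plus a plain 1x1 halving projection."""

    def __init__(self, channels, rng, reduction=16, sam_kernel=7):
        super().__init__()
        if channels % 2:
            raise ValueError("channel halving requires an even channel count")
        self.cbam = CBAM(channels, rng, reduction, sam_kernel)
        self.proj = nn.Conv2d(channels, channels // 2, 1, rng)
        self.norm = nn.LayerNorm2d(channels // 2)
        self.act = nn.GELU()

    def forward(self, x):
        return self.act(self.norm(self.proj(self.cbam(x))))


class Upsample2x(nn.Module):
    def __init__(self, channels, rng, mode="bilinear"):
        super().__init__()
        self.mode = mode
        if mode == "transposed":
            self.weight = Tensor(nn._he_normal(rng, (channels, channels, 2, 2), channels * 4),
                                 requires_grad=True)
            self.bias = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x):
        if self.mode == "bilinear":
            return ad.upsample_bilinear2x(x)
        return ad.conv_transpose2x(x, self.weight, self.bias)


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

class MultiScaleSegNet(nn.Module):
    """Encoder-decoder retinal layer segmentation network (see module docs)."""

    def __init__(self, config: NetworkConfig = NetworkConfig()):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        c1, c2, c3, c4 = config.stage_widths
        k, exp = config.depthwise_kernel, config.expansion_ratio

        # stem: 4x4 convolution, stride 1 (no spatial reduction), 'same' pad
        self.stem = nn.Conv2d(config.in_channels, c1, 4, rng,
                              stride=1, padding=(1, 2, 1, 2))
        self.stem_norm = nn.LayerNorm2d(c1)

        def stage(ch, depth):
            return nn.Sequential(*[ConvNeXtBlock(ch, rng, k, exp)
                                   for _ in range(depth)])

        self.stage1 = stage(c1, config.stage_depths[0])
        self.down2 = nn.Sequential(nn.LayerNorm2d(c1),
                                   nn.Conv2d(c1, c2, 2, rng, stride=2))
        self.stage2 = stage(c2, config.stage_depths[1])
        self.down3 = nn.Sequential(nn.LayerNorm2d(c2),
                                   nn.Conv2d(c2, c3, 2, rng, stride=2))
        self.stage3 = stage(c3, config.stage_depths[2])
        self.down4 = nn.Sequential(nn.LayerNorm2d(c3),
                                   nn.Conv2d(c3, c4, 2, rng, stride=2))
        self.stage4 = stage(c4, config.stage_depths[3])

        attn_cls = DECBAM if config.attention_variant == "de_cbam" else CBAMProject
        d1, d2, d3 = config.decoder_in_channels()
        self.up1 = Upsample2x(c4, rng, config.upsample_mode)
        self.dec1 = attn_cls(d1, rng, config.cam_reduction, config.sam_kernel)
        self.up2 = Upsample2x(d1 // 2, rng, config.upsample_mode)
        self.dec2 = attn_cls(d2, rng, config.cam_reduction, config.sam_kernel)
        self.up3 = Upsample2x(d2 // 2, rng, config.upsample_mode)
        self.dec3 = attn_cls(d3, rng, config.cam_reduction, config.sam_kernel)

        g = d3 // 2
        self.oc_conv = nn.Conv2d(g, g, 3, rng, padding=1)
        self.oc_norm = nn.LayerNorm2d(g)
        self.oc_act = nn.GELU()
        self.head = nn.Conv2d(g, config.n_classes, 1, rng)

    # -- pieces ------------------------------------------------------------
    def encode(self, x: Tensor) -> FeaturePyramid:
        """Image (N, in_ch, H, W) -> four-scale feature pyramid."""
        H, W = x.shape[2], x.shape[3]
        if H % 8 or W % 8:
            raise ValueError(
                f"input spatial size ({H}, {W}) must be divisible by 8; "
                "use dataio.crop_or_pad to adjust")
        f1 = self.stage1(self.stem_norm(self.stem(x)))
        f2 = self.stage2(self.down2(f1))
        f3 = self.stage3(self.down3(f2))
        f4 = self.stage4(self.down4(f3))
        return FeaturePyramid(f1, f2, f3, f4)

    def decode(self, pyr: FeaturePyramid, capture: dict | None = None) -> Tensor:
        """Pyramid -> class logits at input resolution."""
        g = self.dec1(ad.concat([self.up1(pyr.f4), pyr.f3], axis=1))
        if capture is not None:
            capture["de_cbam1"] = g
        g = self.dec2(ad.concat([self.up2(g), pyr.f2], axis=1))
        if capture is not None:
            capture["de_cbam2"] = g
        g = self.dec3(ad.concat([self.up3(g), pyr.f1], axis=1))
        if capture is not None:
            capture["de_cbam3"] = g
        feats = self.oc_act(self.oc_norm(self.oc_conv(g)))
        if capture is not None:
            capture["output_conv"] = feats
        logits = self.head(feats)
        if capture is not None:
            capture["logits"] = logits
        return logits

    def forward(self, x, capture: dict | None = None) -> Tensor:
        x = self._as_batch(x)
        return self.decode(self.encode(x), capture)

    # -- inference helpers -------------------------------------------------
    def _as_batch(self, x) -> Tensor:
        if isinstance(x, Tensor):
            return x
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 2:
            arr = arr[None, None]
        elif arr.ndim == 3:
            arr = arr[:, None]
        return Tensor(arr)

    def predict_logits(self, images: np.ndarray) -> np.ndarray:
        with ad.no_grad():
            return self.forward(images).data

    def predict_proba(self, images: np.ndarray) -> np.ndarray:
        """Per-pixel softmax class probabilities, summing to 1."""
        return ad.softmax(self.predict_logits(images), axis=1)

    def predict(self, images: np.ndarray) -> np.ndarray:
        """Argmax label masks, shape (N, H, W) (or (H, W) for one image)."""
        squeeze = np.asarray(images).ndim == 2
        masks = self.predict_logits(images).argmax(axis=1)
        return masks[0] if squeeze else masks


# ---------------------------------------------------------------------------
# module-level operation wrappers
# ---------------------------------------------------------------------------

def channel_attention(cam: ChannelAttention, F) -> Tensor:
    """Mc = sigma(MLP(AvgPool(F)) + MLP(MaxPool(F))), shape (N, C, 1, 1)."""
    return cam(F if isinstance(F, Tensor) else Tensor(F))


def spatial_attention(sam: SpatialAttention, F) -> Tensor:
    """Ms = sigma(f_kxk([AvgPool_c(F); MaxPool_c(F)])), shape (N, 1, H, W)."""
    return sam(F if isinstance(F, Tensor) else Tensor(F))


def cbam(block: CBAM, F) -> Tensor:
    """Refined feature map F'' (same shape as F)."""
    return block(F if isinstance(F, Tensor) else Tensor(F))


def de_cbam(block: DECBAM, F) -> Tensor:
    """CBAM + two depthwise-separable convs; output has C/2 channels."""
    return block(F if isinstance(F, Tensor) else Tensor(F))


def count_parameters(config: NetworkConfig) -> int:
    """Total trainable parameter count of the configured model."""
    return MultiScaleSegNet(config).n_parameters()


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: MultiScaleSegNet, path: str | os.PathLike) -> None:
    """Write parameters (.npz) with the config snapshot embedded as JSON."""
    state = model.state_dict()
    meta = json.dumps(asdict(model.config))
    np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **{k: v for k, v in state.items()})


def load_checkpoint(path: str | os.PathLike) -> MultiScaleSegNet:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__config__"]).decode())
        for key in ("stage_widths", "stage_depths", "layer_intensities"):
            if key in meta and isinstance(meta[key], list):
                meta[key] = tuple(meta[key])
        config = NetworkConfig(**meta)
        model = MultiScaleSegNet(config)
        model.load_state_dict({k: data[k] for k in data.files
                               if k != "__config__"})
    return model
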