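"""Neural-network layer library on top of :mod:`octseg.autodiff`.

Modules hold :class:`~octseg.autodiff.Tensor` parameters, expose
``parameters()`` / ``state_dict()`` in the usual way, and are callable on
tensors.  Initialisation draws from an explicit ``numpy.random.Generator`` so
that model construction is reproducible from a single seed.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    def __init__(self):
        self._params: "OrderedDict[str, Tensor]" = OrderedDict()
        self._modules: "OrderedDict[str, Module]" = OrderedDict()

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", OrderedDict())[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", OrderedDict())[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict((k, p.data.copy()) for k, p in self.named_parameters())

    def load_state_dict(self, state):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list: list[Module] = []
        for m in modules:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.layers = ModuleList(modules)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _trunc_normal(rng: np.random.Generator, shape, std=0.02):
    """Truncated normal in [-2 std, 2 std] (resampling)."""
    out = rng.normal(0.0, std, size=shape)
    bad = np.abs(out) > 2 * std
    while bad.any():
        out[bad] = rng.normal(0.0, std, size=int(bad.sum()))
        bad = np.abs(out) > 2 * std
    return out


def _he_normal(rng: np.random.Generator, shape, fan_in):
    """Fan-in-scaled truncated normal (std = sqrt(2 / fan_in)).

    Variance-preserving initialisation keeps the spatial structure of the
    input alive through the deep, normalisation-heavy stack; a fixed small
    std would shrink activations several-fold at every stage."""
    return _trunc_normal(rng, shape, std=np.sqrt(2.0 / max(fan_in, 1)))


def _fan_in_bias(rng: np.random.Generator, n_out, fan_in):
    """Uniform(-1/sqrt(fan_in), 1/sqrt(fan_in)) bias init.

    A non-zero bias matters here: with zero biases a conv of a locally
    constant image is exactly proportional to the local intensity, and the
    channel layer-norm that follows would divide that scalar out, leaving
    the features blind to absolute intensity."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=n_out)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, rng, stride=1, padding=0, bias=True):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.stride = stride
        self.padding = padding
        self.weight = Tensor(_he_normal(rng, (out_ch, in_ch, kh, kw),
                                        in_ch * kh * kw), requires_grad=True)
        self.bias = Tensor(_fan_in_bias(rng, out_ch, in_ch * kh * kw),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, channels, kernel, rng, bias=True):
        super().__init__()
        self.weight = Tensor(_he_normal(rng, (channels, kernel, kernel),
                                        kernel * kernel), requires_grad=True)
        self.bias = Tensor(_fan_in_bias(rng, channels, kernel * kernel),
                           requires_grad=True) if bias else None

    def forward(self, x):
        return ad.depthwise_conv2d(x, self.weight, self.bias)


class Linear(Module):
    def __init__(self, in_f, out_f, rng, bias=True):
        super().__init__()
        self.weight = Tensor(_he_normal(rng, (in_f, out_f), in_f),
                             requires_grad=True)
        self.bias = Tensor(_fan_in_bias(rng, out_f, in_f),
                           requires_grad=True) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out


class LayerNorm2d(Module):
    """Layer norm over channels of NCHW, applied per spatial location."""

    def __init__(self, channels, eps=1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)

    def forward(self, x):
        return ad.layer_norm_channels(x, self.gamma, self.beta, self.eps)


class GELU(Module):
    def forward(self, x):
        return ad.gelu(x)


class Identity(Module):
    def forward(self, x):
        return x


class Adam:
    """Adam optimiser (Kingma & Ba) with bias correction."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
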