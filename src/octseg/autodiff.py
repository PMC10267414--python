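"""Reverse-mode automatic differentiation on numpy arrays.

This is the package's compute core: a small define-by-run tape with exactly
the primitives the segmentation network needs (dense/depthwise/transposed
convolutions, channel-wise layer normalisation, pooling reductions, bilinear
upsampling, a fused softmax cross-entropy).  All arithmetic is float64 so that
results are bit-reproducible across runs on the same platform and so that
finite-difference gradient checks can be tight.

Layout convention is NCHW throughout (batch, channels, rows, cols); rows
increase downward, matching image coordinates.
"""

from __future__ import annotations

import math
from contextlib import contextmanager

import numpy as np

_GRAD_ENABLED = True

DTYPE = np.float64


@contextmanager
def no_grad():
    """Disable tape construction inside the block (inference mode)."""
    global _GRAD_ENABLED
    prev = _GRAD_ENABLED
    _GRAD_ENABLED = False
    try:
        yield
    finally:
        _GRAD_ENABLED = prev


def grad_enabled() -> bool:
    return _GRAD_ENABLED


class Tensor:
    """A numpy array plus (optionally) a node on the backward tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- bookkeeping -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad=None):
        """Backpropagate from this tensor (scalar unless ``grad`` given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without an explicit gradient "
                                 "requires a scalar tensor")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=DTYPE))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- operator sugar ----------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), Tensor(-1.0)))

    def __neg__(self):
        return mul(self, Tensor(-1.0))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _make(data, parents, backward_fn) -> Tensor:
    out = Tensor(data)
    if _GRAD_ENABLED and any(p.requires_grad or p._parents for p in parents):
        out.requires_grad = True
        out._parents = tuple(parents)
        out._backward = backward_fn
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nextra = grad.ndim - len(shape)
    if nextra:
        grad = grad.sum(axis=tuple(range(nextra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# ---------------------------------------------------------------------------
# elementwise / arithmetic
# ---------------------------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))
    return _make(a.data + b.data, (a, b), bw)


def mul(a: Tensor, b: Tensor) -> Tensor:
    def bw(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))
    return _make(a.data * b.data, (a, b), bw)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))

    def bw(g):
        x._accumulate(g * s * (1.0 - s))
    return _make(s, (x,), bw)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accumulate(g * mask)
    return _make(x.data * mask, (x,), bw)


_GELU_C = math.sqrt(2.0 / math.pi)


def gelu(x: Tensor) -> Tensor:
    """tanh-approximated GELU (in-place arithmetic to limit temporaries)."""
    d = x.data
    u = d * d
    x2 = u.copy()
    u *= 0.044715
    u *= d
    u += d
    u *= _GELU_C
    t = np.tanh(u)
    y = t + 1.0
    y *= d
    y *= 0.5

    def bw(g):
        # dy/dx = 0.5 (1 + t) + 0.5 x (1 - t^2) c (1 + 3*0.044715 x^2)
        du = x2
        du = du * (3 * 0.044715)
        du += 1.0
        du *= _GELU_C
        sech2 = t * t
        np.subtract(1.0, sech2, out=sech2)
        sech2 *= du
        sech2 *= d
        sech2 += t
        sech2 += 1.0
        sech2 *= 0.5
        sech2 *= g
        x._accumulate(sech2)
    return _make(y, (x,), bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """2-D (or batched trailing-2-D) matrix product."""
    def bw(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        a._accumulate(_unbroadcast(ga, a.data.shape))
        b._accumulate(_unbroadcast(gb, b.data.shape))
    return _make(np.matmul(a.data, b.data), (a, b), bw)


# ---------------------------------------------------------------------------
# reductions / shape
# ---------------------------------------------------------------------------

def tsum(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    def bw(g):
        if axis is None:
            x._accumulate(np.broadcast_to(g, x.data.shape).copy()
                          if np.ndim(g) else np.full_like(x.data, g))
            return
        gg = g
        if not keepdims:
            gg = np.expand_dims(gg, axis)
        x._accumulate(np.broadcast_to(gg, x.data.shape))
    return _make(x.data.sum(axis=axis, keepdims=keepdims), (x,), bw)


def tmean(x: Tensor, axis=None, keepdims: bool = False) -> Tensor:
    if axis is None:
        n = x.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([x.data.shape[a] for a in axes]))
    return mul(tsum(x, axis=axis, keepdims=keepdims), Tensor(1.0 / n))


def tmax(x: Tensor, axis, keepdims: bool = True) -> Tensor:
    """Max-reduction; gradient flows to the (first) argmax entries."""
    out = x.data.max(axis=axis, keepdims=True)
    mask = (x.data == out)
    # split ties evenly so the gradient check is well defined
    mask = mask / mask.sum(axis=axis, keepdims=True)
    res = out if keepdims else np.squeeze(out, axis=axis)

    def bw(g):
        gg = g if keepdims else np.expand_dims(g, axis)
        x._accumulate(mask * gg)
    return _make(res, (x,), bw)


def reshape(x: Tensor, shape) -> Tensor:
    orig = x.data.shape

    def bw(g):
        x._accumulate(g.reshape(orig))
    return _make(x.data.reshape(shape), (x,), bw)


def transpose(x: Tensor, axes) -> Tensor:
    inv = np.argsort(axes)

    def bw(g):
        x._accumulate(g.transpose(inv))
    return _make(x.data.transpose(axes), (x,), bw)


def concat(tensors, axis: int) -> Tensor:
    tensors = [_wrap(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)
    return _make(np.concatenate([t.data for t in tensors], axis=axis),
                 tuple(tensors), bw)


def pad2d(x: Tensor, pad) -> Tensor:
    """Zero-pad spatial dims of NCHW; pad = (top, bottom, left, right)."""
    top, bot, left, right = pad
    H, W = x.data.shape[2], x.data.shape[3]

    def bw(g):
        x._accumulate(g[:, :, top:top + H, left:left + W])
    padded = np.pad(x.data, ((0, 0), (0, 0), (top, bot), (left, right)))
    return _make(padded, (x,), bw)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, sh: int, sw: int) -> np.ndarray:
    """(N,C,H,W) -> (N, C*kh*kw, Ho*Wo) patch matrix (copies)."""
    N, C, H, W = x.shape
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    s = x.strides
    view = np.lib.stride_tricks.as_strided(
        x, (N, C, kh, kw, Ho, Wo),
        (s[0], s[1], s[2], s[3], s[2] * sh, s[3] * sw))
    return view.reshape(N, C * kh * kw, Ho * Wo), Ho, Wo


def _col2im(cols: np.ndarray, xshape, kh, kw, sh, sw) -> np.ndarray:
    N, C, H, W = xshape
    Ho = (H - kh) // sh + 1
    Wo = (W - kw) // sw + 1
    out = np.zeros(xshape, dtype=cols.dtype)
    cols = cols.reshape(N, C, kh, kw, Ho, Wo)
    for i in range(kh):
        for j in range(kw):
            out[:, :, i:i + sh * Ho:sh, j:j + sw * Wo:sw] += cols[:, :, i, j]
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor | None,
           stride: int | tuple = 1, padding: int | tuple = 0) -> Tensor:
    """Dense cross-correlation. w: (O, C, kh, kw); padding (top,bot,left,right)
    or a single symmetric int; stride (sh, sw) or int."""
    sh, sw = (stride, stride) if isinstance(stride, int) else stride
    if isinstance(padding, int):
        padding = (padding, padding, padding, padding)
    top, bot, left, right = padding
    O, C, kh, kw = w.data.shape

    if (kh, kw, sh, sw) == (1, 1, 1, 1) and not any(padding):
        # pointwise fast path: a channel-mixing matmul
        N, _, H, W = x.data.shape
        xm = x.data.reshape(N, C, H * W)
        w2 = w.data.reshape(O, C)
        out = np.matmul(w2, xm).reshape(N, O, H, W)
        if b is not None:
            out += b.data[None, :, None, None]

        def bw_pw(g):
            gm = g.reshape(N, O, H * W)
            w._accumulate(np.einsum("nop,ncp->oc", gm, xm,
                                    optimize=True).reshape(w.data.shape))
            if b is not None:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            x._accumulate(np.matmul(w2.T, gm).reshape(x.data.shape))
        parents = (x, w) if b is None else (x, w, b)
        return _make(out, parents, bw_pw)

    xp = np.pad(x.data, ((0, 0), (0, 0), (top, bot), (left, right)))
    cols, Ho, Wo = _im2col(xp, kh, kw, sh, sw)
    w2 = w.data.reshape(O, C * kh * kw)
    out = np.matmul(w2, cols).reshape(-1, O, Ho, Wo)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        gm = g.reshape(g.shape[0], O, Ho * Wo)
        gw = np.einsum("nop,nkp->ok", gm, cols).reshape(w.data.shape)
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        gcols = np.matmul(w2.T, gm)
        gxp = _col2im(gcols, xp.shape, kh, kw, sh, sw)
        H, W = x.data.shape[2], x.data.shape[3]
        x._accumulate(gxp[:, :, top:top + H, left:left + W])
    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


_DW_EINSUM_MAX = 1_500_000  # elements; crossover between einsum and tap loop


def depthwise_conv2d(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Depthwise (per-channel) k x k convolution, stride 1, 'same' output.

    w: (C, kh, kw).  Implemented as a sum of shifted scaled slices, which
    avoids materialising the im2col patch matrix for large feature maps.
    """
    C, kh, kw = w.data.shape
    top, left = (kh - 1) // 2, (kw - 1) // 2
    bot, right = kh - 1 - top, kw - 1 - left
    N, Cx, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (top, bot), (left, right)))

    def _taps(arr, h, w_):
        s = arr.strides
        return np.lib.stride_tricks.as_strided(
            arr, (arr.shape[0], arr.shape[1], kh, kw, h, w_),
            (s[0], s[1], s[2], s[3], s[2], s[3]))

    def _corr(src, kernel):
        """Per-channel correlation of padded ``src`` with (C, kh, kw) taps."""
        if src.size <= _DW_EINSUM_MAX:
            return np.einsum("ncijhw,cij->nchw", _taps(src, H, W), kernel,
                             optimize=True)
        # large maps: BLAS-free fused multiply-adds beat nditer here
        acc = np.zeros((src.shape[0], src.shape[1], H, W), dtype=src.dtype)
        tmp = np.empty_like(acc)
        for i in range(kh):
            for j in range(kw):
                np.multiply(src[:, :, i:i + H, j:j + W],
                            kernel[None, :, i, j, None, None], out=tmp)
                acc += tmp
        return acc

    out = _corr(xp, w.data)
    if b is not None:
        out += b.data[None, :, None, None]

    def bw(g):
        if xp.size <= _DW_EINSUM_MAX:
            gw = np.einsum("nchw,ncijhw->cij", g, _taps(xp, H, W),
                           optimize=True)
        else:
            gw = np.empty_like(w.data)
            for i in range(kh):
                for j in range(kw):
                    gw[:, i, j] = np.einsum(
                        "nchw,nchw->c", g, xp[:, :, i:i + H, j:j + W])
        w._accumulate(gw)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        # dx is the correlation of g with the spatially flipped kernel
        gp = np.pad(g, ((0, 0), (0, 0), (bot, top), (right, left)))
        x._accumulate(_corr(gp, np.ascontiguousarray(w.data[:, ::-1, ::-1])))
    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


def conv_transpose2x(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact x2 upsampling).

    w: (C_in, C_out, 2, 2)."""
    N, C, H, W = x.data.shape
    Cout = w.data.shape[1]
    # out[:, o, 2i+di, 2j+dj] = sum_c w[c, o, di, dj] * x[:, c, i, j]
    blocks = np.einsum("codk,nchw->nohwdk", w.data, x.data)
    out = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(N, Cout, 2 * H, 2 * W)
    if b is not None:
        out = out + b.data[None, :, None, None]

    def bw(g):
        gb = g.reshape(N, Cout, H, 2, W, 2).transpose(0, 1, 2, 4, 3, 5)
        w._accumulate(np.einsum("nohwdk,nchw->codk", gb, x.data))
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        x._accumulate(np.einsum("codk,nohwdk->nchw", w.data, gb))
    parents = (x, w) if b is None else (x, w, b)
    return _make(out, parents, bw)


_UPSAMPLE_CACHE: dict[int, np.ndarray] = {}


def _upsample_matrix(n: int) -> np.ndarray:
    """(2n, n) bilinear x2 interpolation matrix (half-pixel centres)."""
    mat = _UPSAMPLE_CACHE.get(n)
    if mat is None:
        mat = np.zeros((2 * n, n), dtype=DTYPE)
        for i in range(2 * n):
            src = (i + 0.5) / 2.0 - 0.5
            lo = int(np.floor(src))
            frac = src - lo
            lo_c = min(max(lo, 0), n - 1)
            hi_c = min(max(lo + 1, 0), n - 1)
            mat[i, lo_c] += 1.0 - frac
            mat[i, hi_c] += frac
        _UPSAMPLE_CACHE[n] = mat
    return mat


def upsample_bilinear2x(x: Tensor) -> Tensor:
    H, W = x.data.shape[2], x.data.shape[3]
    Bh = _upsample_matrix(H)
    Bw = _upsample_matrix(W)
    tmp = np.einsum("ph,nchw->ncpw", Bh, x.data, optimize=True)
    out = np.einsum("qw,ncpw->ncpq", Bw, tmp, optimize=True)

    def bw(g):
        t = np.einsum("qw,ncpq->ncpw", Bw, g, optimize=True)
        x._accumulate(np.einsum("ph,ncpw->nchw", Bh, t, optimize=True))
    return _make(out, (x,), bw)


# ---------------------------------------------------------------------------
# normalisation and loss
# ---------------------------------------------------------------------------

def layer_norm_channels(x: Tensor, gamma: Tensor, beta: Tensor,
                        eps: float = 1e-6) -> Tensor:
    """Layer normalisation over the channel axis of NCHW, per spatial site."""
    mu = x.data.mean(axis=1, keepdims=True)
    xc = x.data - mu
    var = (xc ** 2).mean(axis=1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    C = x.data.shape[1]

    def bw(g):
        gamma._accumulate(np.einsum("nchw,nchw->c", g, xhat))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gx = g * gamma.data[None, :, None, None]
        # standard layer-norm backward over the normalised axis
        m1 = gx.mean(axis=1, keepdims=True)
        m2 = (gx * xhat).mean(axis=1, keepdims=True)
        x._accumulate(inv * (gx - m1 - xhat * m2))
        _ = C
    return _make(out, (x, gamma, beta), bw)


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel negative log-softmax of the true class.

    logits: (N, C, H, W) tensor; target: (N, H, W) integer array."""
    target = np.asarray(target)
    N, C, H, W = logits.data.shape
    if target.min() < 0 or target.max() >= C:
        raise ValueError(f"target labels must lie in [0, {C - 1}]")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    ez = np.exp(z)
    sm = ez / ez.sum(axis=1, keepdims=True)
    n_px = N * H * W
    idx_n, idx_h, idx_w = np.meshgrid(np.arange(N), np.arange(H), np.arange(W),
                                      indexing="ij")
    logp = z - np.log(ez.sum(axis=1, keepdims=True))
    loss = -logp[idx_n, target, idx_h, idx_w].sum() / n_px

    def bw(g):
        grad = sm.copy()
        grad[idx_n, target, idx_h, idx_w] -= 1.0
        logits._accumulate(g * grad / n_px)
    return _make(loss, (logits,), bw)


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Plain numpy softmax (no tape)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=axis, keepdims=True)
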