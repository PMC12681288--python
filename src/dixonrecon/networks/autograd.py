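"""Minimal reverse-mode autodiff over numpy arrays.

Only the operations needed by the unrolled reconstruction networks are
implemented: 3D convolutions (via im2col), 2x2x2 transpose convolutions,
max pooling, instance normalization, leaky ReLU, dropout, trilinear
upsampling, channel concatenation, centered orthonormal FFTs on two-channel
(real/imag) tensors, and the whole-tensor normalization wrapper.

Tensors are channel-first without a batch axis: ``(C, X, Y, Z)``.  Every
backward pass was validated against central finite differences (see the
gradient-check tests).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..kspace import fft3c, ifft3c

__all__ = ["Tensor", "Parameter"]


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse-mode sweep from this node (scalar unless grad is given)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient needs a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def detach(self) -> "Tensor":
        return Tensor(self.data)


class Parameter(Tensor):
    """Learnable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data), requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _node(data, parents, backward) -> Tensor:
    if _needs(*parents):
        return Tensor(data, parents=parents, backward=backward)
    return Tensor(data)


# ---------------------------------------------------------------------------
# elementwise / structural ops
# ---------------------------------------------------------------------------


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch in add: {a.shape} vs {b.shape}")

    def bwd(g):
        a._accumulate(g)
        b._accumulate(g)

    return _node(a.data + b.data, (a, b), bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch in sub: {a.shape} vs {b.shape}")

    def bwd(g):
        a._accumulate(g)
        b._accumulate(-g)

    return _node(a.data - b.data, (a, b), bwd)


def add_n(tensors: list[Tensor]) -> Tensor:
    out = tensors[0].data.copy()
    for t in tensors[1:]:
        out += t.data

    def bwd(g):
        for t in tensors:
            t._accumulate(g)

    return _node(out, tuple(tensors), bwd)


def scale(x: Tensor, s: Tensor) -> Tensor:
    """Multiply tensor x by a scalar tensor s (a learned step size)."""
    if s.data.size != 1:
        raise ValueError("scale expects a scalar tensor")

    def bwd(g):
        x._accumulate(g * s.data)
        s._accumulate(np.sum(g * x.data).reshape(s.data.shape))

    return _node(x.data * s.data, (x, s), bwd)


def mul_const(x: Tensor, c) -> Tensor:
    c = np.asarray(c, dtype=x.data.dtype)

    def bwd(g):
        x._accumulate(g * c)

    return _node(x.data * c, (x,), bwd)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, gt in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(gt)

    return _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors), bwd)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    mask = x.data >= 0
    out = np.where(mask, x.data, slope * x.data)

    def bwd(g):
        x._accumulate(np.where(mask, g, slope * g))

    return _node(out, (x,), bwd)


def dropout(x: Tensor, p: float, rng: np.random.Generator, training: bool) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p).astype(x.data.dtype) / (1.0 - p)

    def bwd(g):
        x._accumulate(g * keep)

    return _node(x.data * keep, (x,), bwd)


def pad_spatial(x: Tensor, pads) -> Tensor:
    """Zero-pad the three spatial axes of a (C, X, Y, Z) tensor."""
    widths = ((0, 0), *pads)

    def bwd(g):
        sl = tuple(slice(lo, g.shape[i] - hi) for i, (lo, hi) in enumerate(widths))
        x._accumulate(g[sl])

    return _node(np.pad(x.data, widths), (x,), bwd)


def crop_spatial(x: Tensor, pads) -> Tensor:
    """Inverse of :func:`pad_spatial` for the same pad record."""
    widths = ((0, 0), *pads)
    sl = tuple(slice(lo, x.shape[i] - hi) for i, (lo, hi) in enumerate(widths))

    def bwd(g):
        x._accumulate(np.pad(g, widths))

    return _node(x.data[sl], (x,), bwd)


# ---------------------------------------------------------------------------
# convolutions
# ---------------------------------------------------------------------------


def conv3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """3D convolution, stride 1, 'same' padding, kernel from w's trailing dims.

    im2col layout is (cin*k^3, X*Y*Z), built and scattered back with 27
    contiguous slice copies to keep memory access cheap.
    """
    cout, cin, k, _, _ = w.shape
    if x.shape[0] != cin:
        raise ValueError(f"conv3d expects {cin} input channels, got {x.shape[0]}")
    p = k // 2
    sx, sy, sz = x.shape[1:]
    nvox = sx * sy * sz
    if p:
        xp = np.pad(x.data, ((0, 0), (p, p), (p, p), (p, p)))
        cols = np.empty((cin, k, k, k, sx, sy, sz), dtype=x.data.dtype)
        for a in range(k):
            for bb in range(k):
                for c in range(k):
                    cols[:, a, bb, c] = xp[:, a : a + sx, bb : bb + sy, c : c + sz]
        cols = cols.reshape(cin * k**3, nvox)
    else:
        cols = x.data.reshape(cin, nvox)
    wmat = w.data.reshape(cout, cin * k**3)
    out = (wmat @ cols + b.data[:, None]).reshape(cout, sx, sy, sz)

    def bwd(g):
        gmat = g.reshape(cout, nvox)
        w._accumulate((gmat @ cols.T).reshape(w.shape))
        b._accumulate(gmat.sum(axis=1))
        dcols = wmat.T @ gmat  # (cin*k^3, XYZ)
        if p:
            dcr = dcols.reshape(cin, k, k, k, sx, sy, sz)
            dxp = np.zeros((cin, sx + 2 * p, sy + 2 * p, sz + 2 * p), dtype=g.dtype)
            for a in range(k):
                for bb in range(k):
                    for c in range(k):
                        dxp[:, a : a + sx, bb : bb + sy, c : c + sz] += dcr[:, a, bb, c]
            x._accumulate(dxp[:, p : p + sx, p : p + sy, p : p + sz])
        else:
            x._accumulate(dcols.reshape(cin, sx, sy, sz))

    return _node(out, (x, w, b), bwd)


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Transpose convolution with kernel == stride == f (scales dims by f)."""
    cin, cout = w.shape[:2]
    f = w.shape[2]
    if x.shape[0] != cin:
        raise ValueError(f"conv_transpose3d expects {cin} input channels, got {x.shape[0]}")
    sx, sy, sz = x.shape[1:]
    out = np.einsum("cxyz,cdabe->dxaybze", x.data, w.data, optimize=True).reshape(
        cout, f * sx, f * sy, f * sz
    )
    out += b.data[:, None, None, None]

    def bwd(g):
        gb = g.reshape(cout, sx, f, sy, f, sz, f)
        w._accumulate(np.einsum("cxyz,dxaybze->cdabe", x.data, gb, optimize=True))
        b._accumulate(g.sum(axis=(1, 2, 3)))
        x._accumulate(np.einsum("dxaybze,cdabe->cxyz", gb, w.data, optimize=True))

    return _node(out, (x, w, b), bwd)


def maxpool2(x: Tensor) -> Tensor:
    """2x2x2 max pooling; spatial dims must be even."""
    c, sx, sy, sz = x.shape
    if sx % 2 or sy % 2 or sz % 2:
        raise ValueError(f"maxpool2 needs even spatial dims, got {x.shape}")
    blocks = (
        x.data.reshape(c, sx // 2, 2, sy // 2, 2, sz // 2, 2)
        .transpose(0, 1, 3, 5, 2, 4, 6)
        .reshape(c, sx // 2, sy // 2, sz // 2, 8)
    )
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gb = np.zeros_like(blocks)
        np.put_along_axis(gb, idx[..., None], g[..., None], axis=-1)
        x._accumulate(
            gb.reshape(c, sx // 2, sy // 2, sz // 2, 2, 2, 2)
            .transpose(0, 1, 4, 2, 5, 3, 6)
            .reshape(c, sx, sy, sz)
        )

    return _node(out, (x,), bwd)


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-channel normalization over the spatial axes (no learned affine)."""
    ax = (1, 2, 3)
    m = x.data.mean(axis=ax, keepdims=True)
    v = x.data.var(axis=ax, keepdims=True)
    inv = 1.0 / np.sqrt(v + eps)
    y = (x.data - m) * inv

    def bwd(g):
        gm = g.mean(axis=ax, keepdims=True)
        gy = (g * y).mean(axis=ax, keepdims=True)
        x._accumulate((g - gm - y * gy) * inv)

    return _node(y, (x,), bwd)


@lru_cache(maxsize=64)
def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """1D linear interpolation matrix, align_corners=False convention."""
    A = np.zeros((n_out, n_in))
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    src = np.clip(src, 0, n_in - 1)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    w = src - i0
    A[np.arange(n_out), i0] += 1.0 - w
    A[np.arange(n_out), i1] += w
    return A


def upsample_trilinear(x: Tensor, out_shape: tuple[int, int, int]) -> Tensor:
    """Trilinear interpolation of a (C, X, Y, Z) tensor to a target spatial shape."""
    mats = [
        _interp_matrix(n_in, n_out).astype(x.data.dtype)
        for n_in, n_out in zip(x.shape[1:], out_shape)
    ]

    def apply(t, ms):
        t = np.einsum("ai,cijk->cajk", ms[0], t, optimize=True)
        t = np.einsum("bj,cajk->cabk", ms[1], t, optimize=True)
        return np.einsum("pk,cabk->cabp", ms[2], t, optimize=True)

    def bwd(g):
        x._accumulate(apply(g, [m.T for m in mats]))

    return _node(apply(x.data, mats), (x,), bwd)


# ---------------------------------------------------------------------------
# FFT ops on two-channel tensors
# ---------------------------------------------------------------------------


def _as_complex(t: np.ndarray) -> np.ndarray:
    return t[0] + 1j * t[1]


def _as_channels(c: np.ndarray, dtype) -> np.ndarray:
    return np.stack([c.real, c.imag]).astype(dtype)


def fft2ch(x: Tensor) -> Tensor:
    """Centered orthonormal FFT of a (2, X, Y, Z) real/imag tensor."""

    def bwd(g):  # adjoint of a unitary map is its inverse
        x._accumulate(_as_channels(ifft3c(_as_complex(g)), g.dtype))

    return _node(_as_channels(fft3c(_as_complex(x.data)), x.data.dtype), (x,), bwd)


def ifft2ch(x: Tensor) -> Tensor:
    """Centered orthonormal inverse FFT of a (2, X, Y, Z) tensor."""

    def bwd(g):
        x._accumulate(_as_channels(fft3c(_as_complex(g)), g.dtype))

    return _node(_as_channels(ifft3c(_as_complex(x.data)), x.data.dtype), (x,), bwd)


# ---------------------------------------------------------------------------
# whole-tensor normalization wrapper
# ---------------------------------------------------------------------------


def normalize_whole(x: Tensor) -> tuple[Tensor, float, float]:
    """Normalize a tensor to zero mean, unit SD over all entries jointly.

    Returns (normalized tensor, mean, sd).  A constant input takes the
    sentinel path: the tensor is returned shifted by its mean (i.e. all
    zeros) with sd reported as 1.
    """
    m = float(x.data.mean())
    s = float(x.data.std())
    if s == 0.0:
        def bwd0(g):
            x._accumulate(g - g.mean())

        return _node(x.data - m, (x,), bwd0), m, 1.0
    y = (x.data - m) / s

    def bwd(g):
        x._accumulate((g - g.mean() - y * np.mean(g * y)) / s)

    return _node(y, (x,), bwd), m, s


def denormalize_scale(u: Tensor, x_ref: Tensor) -> Tensor:
    """Rescale a network output by the SD of the tensor that was normalized.

    The mean is deliberately not added back: the regularizer output is an
    additive update, so a zero network output must stay exactly zero.
    """
    m = float(x_ref.data.mean())
    s = float(x_ref.data.std())
    if s == 0.0:
        return u
    n = x_ref.data.size

    def bwd(g):
        u._accumulate(g * s)
        x_ref._accumulate(float(np.sum(g * u.data)) * (x_ref.data - m) / (n * s))

    return _node(u.data * s, (u, x_ref), bwd)


def mse(a: Tensor, b: Tensor) -> Tensor:
    """Mean squared difference, a scalar tensor."""
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch in mse: {a.shape} vs {b.shape}")
    diff = a.data - b.data
    n = diff.size

    def bwd(g):
        gg = 2.0 * float(g) / n * diff
        a._accumulate(gg)
        b._accumulate(-gg)

    return _node(np.asarray(np.mean(diff**2)), (a, b), bwd)
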