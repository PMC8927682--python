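"""Minimal reverse-mode automatic differentiation over numpy arrays.

The segmentation networks in this package are compact encoder/decoder CNNs
that train on a CPU in minutes, so the package carries its own tape-based
autograd engine instead of depending on a deep-learning framework.  The
engine supports exactly the operations the models need: broadcasted
arithmetic, (batched) matrix products, 2-D convolution via im2col, max/avg
pooling, bilinear resampling expressed as constant interpolation matrices,
softmax, and elementwise nonlinearities.

Conventions
-----------
* Image tensors are channels-first ``(N, C, H, W)``.
* A :class:`Tensor` wraps a numpy array; ``requires_grad`` marks leaves
  (parameters).  Interior nodes record their parents and a backward
  closure; :meth:`Tensor.backward` runs a topological sweep.
* Gradients accumulate into ``.grad`` as plain numpy arrays.
* dtype follows the inputs (float32 in training, float64 in gradient
  checks); no silent up-casting is performed.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor", "as_tensor", "add", "sub", "mul", "neg", "matmul", "relu",
    "sigmoid", "log", "clip", "softmax", "tsum", "tmean", "reshape",
    "transpose", "concat", "conv2d", "maxpool2x2", "avgpool", "bilinear_resize",
]


class Tensor:
    """A node in the autodiff graph holding a numpy array."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents: tuple = ()

    # -- array-like sugar -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):  # pragma: no cover - debugging aid
        flag = ", grad" if self.requires_grad else ""
        return f"Tensor(shape={self.data.shape}{flag})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def item(self) -> float:
        return float(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    # -- graph traversal --------------------------------------------------
    def backward(self, grad=None) -> None:
        """Back-propagate ``grad`` (default: ones) through the graph."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            for parent, pgrad in zip(node._parents, node._backward(node.grad)):
                if pgrad is None:
                    continue
                if not (parent.requires_grad or parent._parents):
                    continue
                if parent.grad is None:
                    parent.grad = pgrad
                else:
                    parent.grad = parent.grad + pgrad

    # -- operator sugar ---------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    def __radd__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __rsub__(self, other):
        return add(neg(self), other)

    def __mul__(self, other):
        return mul(self, other)

    def __rmul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return neg(self)

    def __matmul__(self, other):
        return matmul(self, other)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


# -- arithmetic -----------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.shape), _unbroadcast(g, b.shape)

    return _node(out, (a, b), backward)


def neg(a) -> Tensor:
    a = as_tensor(a)
    return _node(-a.data, (a,), lambda g: (-g,))


def sub(a, b) -> Tensor:
    return add(a, neg(b))


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out = a.data * b.data

    def backward(g):
        return (_unbroadcast(g * b.data, a.shape),
                _unbroadcast(g * a.data, b.shape))

    return _node(out, (a, b), backward)


def matmul(a, b) -> Tensor:
    """Batched matrix product with numpy broadcasting over leading axes."""
    a, b = as_tensor(a), as_tensor(b)
    out = np.matmul(a.data, b.data)

    def backward(g):
        ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
        gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
        return _unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape)

    return _node(out, (a, b), backward)


# -- nonlinearities -------------------------------------------------------

def relu(a) -> Tensor:
    a = as_tensor(a)
    mask = a.data > 0
    return _node(a.data * mask, (a,), lambda g: (g * mask,))


def leaky_relu(a, slope: float = 0.1) -> Tensor:
    a = as_tensor(a)
    factor = np.where(a.data > 0, 1.0, slope).astype(a.dtype)
    return _node(a.data * factor, (a,), lambda g: (g * factor,))


def sigmoid(a) -> Tensor:
    """Numerically stable logistic function, exact to |x| ~ 1e3 and beyond."""
    a = as_tensor(a)
    x = a.data
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)

    def backward(g):
        return (g * out * (1.0 - out),)

    return _node(out, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out = np.log(a.data)

    def backward(g):
        return (g / a.data,)

    return _node(out, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; the gradient passes only where the input is in range."""
    a = as_tensor(a)
    out = np.clip(a.data, lo, hi)
    inside = (a.data >= lo) & (a.data <= hi)

    def backward(g):
        return (g * inside,)

    return _node(out, (a,), backward)


def softmax(a) -> Tensor:
    """Softmax along the last axis."""
    a = as_tensor(a)
    shifted = a.data - a.data.max(axis=-1, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=-1, keepdims=True)

    def backward(g):
        inner = (g * out).sum(axis=-1, keepdims=True)
        return (out * (g - inner),)

    return _node(out, (a,), backward)


# -- reductions / reshaping ----------------------------------------------

def tsum(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    out = a.data.sum(axis=axis, keepdims=keepdims)
    in_shape = a.shape

    def backward(g):
        if axis is None:
            return (np.broadcast_to(g, in_shape).copy(),)
        axes = axis if isinstance(axis, tuple) else (axis,)
        if not keepdims:
            g = np.expand_dims(g, [ax % len(in_shape) for ax in axes])
        return (np.broadcast_to(g, in_shape).copy(),)

    return _node(out, (a,), backward)


def tmean(a, axis=None, keepdims: bool = False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    return mul(tsum(a, axis=axis, keepdims=keepdims), 1.0 / count)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    in_shape = a.shape
    return _node(a.data.reshape(shape), (a,), lambda g: (g.reshape(in_shape),))


def transpose(a, axes) -> Tensor:
    a = as_tensor(a)
    inv = np.argsort(axes)
    return _node(a.data.transpose(axes), (a,), lambda g: (g.transpose(inv),))


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.shape[axis] for t in ts]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _node(out, tuple(ts), backward)


# -- structured image ops -------------------------------------------------

def conv2d(x, w, b=None, padding: int | None = None) -> Tensor:
    """2-D convolution (stride 1) of ``x`` (N,C,H,W) with ``w`` (O,C,kh,kw).

    ``padding`` defaults to "same" for odd kernels.  Implemented with an
    explicit im2col buffer so both passes reduce to BLAS matmuls.
    """
    x, w = as_tensor(x), as_tensor(w)
    n, cin, h, ww = x.shape
    cout, cin_w, kh, kw = w.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, kernel expects {cin_w}")
    if padding is None:
        padding = kh // 2
    p = padding
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
    ho = h + 2 * p - kh + 1
    wo = ww + 2 * p - kw + 1
    cols6 = np.empty((n, cin, kh, kw, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            cols6[:, :, i, j] = xp[:, :, i:i + ho, j:j + wo]
    cols = cols6.reshape(n, cin * kh * kw, ho * wo)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols).reshape(n, cout, ho, wo)
    if b is not None:
        b = as_tensor(b)
        out = out + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        gmat = g.reshape(n, cout, ho * wo)
        gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0).reshape(w.shape)
        gcols = np.matmul(wmat.T, gmat).reshape(n, cin, kh, kw, ho, wo)
        gxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                gxp[:, :, i:i + ho, j:j + wo] += gcols[:, :, i, j]
        gx = gxp[:, :, p:p + h, p:p + ww] if p else gxp
        if b is None:
            return gx, gw
        return gx, gw, g.sum(axis=(0, 2, 3))

    parents = (x, w) if b is None else (x, w, b)
    return _node(out, parents, backward)


def maxpool2x2(x) -> Tensor:
    """2x2 max pooling with stride 2; ties go to the first maximum."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    h2, w2 = h // 2, w // 2
    windows = (x.data.reshape(n, c, h2, 2, w2, 2)
               .transpose(0, 1, 2, 4, 3, 5)
               .reshape(n, c, h2, w2, 4))
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gw = np.zeros((n, c, h2, w2, 4), dtype=g.dtype)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gx = (gw.reshape(n, c, h2, w2, 2, 2)
              .transpose(0, 1, 2, 4, 3, 5)
              .reshape(n, c, h, w))
        return (gx,)

    return _node(out, (x,), backward)


def avgpool(x, k: int) -> Tensor:
    """k x k average pooling with stride k (spatial dims must divide by k)."""
    x = as_tensor(x)
    n, c, h, w = x.shape
    if k == 1:
        return x
    if h % k or w % k:
        raise ValueError(f"avgpool: {h}x{w} not divisible by {k}")
    hk, wk = h // k, w // k
    out = x.data.reshape(n, c, hk, k, wk, k).mean(axis=(3, 5))

    def backward(g):
        gx = np.broadcast_to(
            g[:, :, :, None, :, None] / (k * k), (n, c, hk, k, wk, k)
        ).reshape(n, c, h, w)
        return (gx.copy(),)

    return _node(out, (x,), backward)


_INTERP_CACHE: dict[tuple[int, int, str], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int, dtype) -> np.ndarray:
    """1-D bilinear interpolation matrix (half-pixel centers, edge clamp)."""
    key = (n_in, n_out, np.dtype(dtype).str)
    mat = _INTERP_CACHE.get(key)
    if mat is None:
        src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n_in - 1)
        w1 = src - i0
        mat = np.zeros((n_out, n_in), dtype=dtype)
        rows = np.arange(n_out)
        np.add.at(mat, (rows, i0), 1.0 - w1)
        np.add.at(mat, (rows, i1), w1)
        _INTERP_CACHE[key] = mat
    return mat


def bilinear_resize(x, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of (N,C,H,W) to (N,C,out_h,out_w).

    Realized as two constant 1-D interpolation matmuls, so the adjoint in
    the backward pass is exact.
    """
    x = as_tensor(x)
    n, c, h, w = x.shape
    if (h, w) == (out_h, out_w):
        return x
    ah = _interp_matrix(h, out_h, x.dtype)
    aw = _interp_matrix(w, out_w, x.dtype)
    out = np.matmul(np.matmul(ah, x.data), aw.T)

    def backward(g):
        return (np.matmul(np.matmul(ah.T, g), aw),)

    return _node(out, (x,), backward)
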