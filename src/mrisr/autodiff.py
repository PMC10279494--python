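"""Minimal reverse-mode automatic differentiation over numpy arrays.

This module is the numerical core of the package: every layer of the
super-resolution network (convolutions, PReLU, LayerNorm, SimAM attention,
pixel shuffling) and every training loss is expressed through the small set
of differentiable primitives defined here, so a single backward pass yields
exact gradients for the Adam optimizer.

The public surface mirrors numpy closely.  Each dispatching helper
(:func:`sigmoid`, :func:`absolute`, :func:`where`, :func:`conv2d`, ...)
accepts either a plain ``numpy.ndarray`` (pure forward evaluation, used for
inference) or a :class:`Tensor` (graph-building evaluation, used for
training), which lets the scientific operators in the rest of the package be
written once and run in both modes.

Only what the network needs is implemented: elementwise arithmetic with
broadcasting, reductions over axes, shape manipulation (reshape / transpose /
basic slicing / concatenation), spatial padding, and stride-1 2-D
cross-correlation.  All data is kept in float64.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Tensor",
    "parameter",
    "as_array",
    "sigmoid",
    "absolute",
    "sqrt",
    "exp",
    "where",
    "relu",
    "mean",
    "concatenate",
    "pad2d",
    "conv2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum away leading axes introduced by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum axes that were broadcast from length 1
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray.

    Leaf tensors created with ``requires_grad=True`` (see :func:`parameter`)
    accumulate gradients in ``.grad`` after :meth:`backward` is called on a
    scalar downstream result.
    """

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_vjp")

    def __init__(self, data, requires_grad: bool = False, _parents=(), _vjp=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad = None
        self._parents = _parents
        self._vjp = _vjp

    # -- construction helpers ------------------------------------------------

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    @staticmethod
    def _make(data, parents, vjp) -> "Tensor":
        if any(p.requires_grad for p in parents):
            return Tensor(data, requires_grad=True, _parents=tuple(parents), _vjp=vjp)
        return Tensor(data)

    # -- basic properties ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        other = self._lift(other)
        out = self.data + other.data
        return self._make(
            out,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)),
        )

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = self.data * other.data
        return self._make(
            out,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __sub__(self, other):
        other = self._lift(other)
        out = self.data - other.data
        return self._make(
            out,
            (self, other),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(-g, other.data.shape)),
        )

    def __rsub__(self, other):
        return self._lift(other).__sub__(self)

    def __truediv__(self, other):
        other = self._lift(other)
        out = self.data / other.data
        return self._make(
            out,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._lift(other).__truediv__(self)

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __pow__(self, n):
        if not np.isscalar(n):
            raise TypeError("Tensor ** only supports scalar exponents")
        out = self.data ** n
        return self._make(out, (self,), lambda g: (g * n * self.data ** (n - 1),))

    # -- reductions ----------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def vjp(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            if not keepdims:
                g = np.expand_dims(g, axes)
            return (np.broadcast_to(g, self.data.shape).copy(),)

        return self._make(out, (self,), vjp)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            count = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape manipulation --------------------------------------------------

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return self._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(old),)
        )

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, key):
        out = self.data[key]

        def vjp(g):
            full = np.zeros_like(self.data)
            full[key] += g
            return (full,)

        return self._make(out, (self,), vjp)

    # -- autodiff driver -----------------------------------------------------

    def backward(self):
        """Backpropagate from this (scalar) tensor to all leaf parameters."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))

        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._vjp is None:
                continue
            grads = node._vjp(node.grad)
            for p, g in zip(node._parents, grads):
                if not p.requires_grad or g is None:
                    continue
                p.grad = g if p.grad is None else p.grad + g


def parameter(data) -> Tensor:
    """Create a learnable leaf tensor (gradients accumulate in ``.grad``)."""
    return Tensor(np.array(data, dtype=np.float64), requires_grad=True)


def as_array(x) -> np.ndarray:
    """Underlying ndarray of a Tensor, or the array itself."""
    return x.data if isinstance(x, Tensor) else np.asarray(x)


# ---------------------------------------------------------------------------
# dispatching elementwise / structural helpers
# ---------------------------------------------------------------------------


def sigmoid(x):
    if isinstance(x, Tensor):
        out = expit(x.data)
        return Tensor._make(out, (x,), lambda g: (g * out * (1.0 - out),))
    return expit(x)


def absolute(x):
    if isinstance(x, Tensor):
        return Tensor._make(np.abs(x.data), (x,), lambda g: (g * np.sign(x.data),))
    return np.abs(x)


def sqrt(x):
    if isinstance(x, Tensor):
        out = np.sqrt(x.data)
        return Tensor._make(out, (x,), lambda g: (g * 0.5 / out,))
    return np.sqrt(x)


def exp(x):
    if isinstance(x, Tensor):
        out = np.exp(x.data)
        return Tensor._make(out, (x,), lambda g: (g * out,))
    return np.exp(x)


def where(cond, a, b):
    """Elementwise select; ``cond`` is a plain boolean array (not differentiated)."""
    cond = np.asarray(cond)
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        a = Tensor._lift(a)
        b = Tensor._lift(b)
        out = np.where(cond, a.data, b.data)
        return Tensor._make(
            out,
            (a, b),
            lambda g: (
                _unbroadcast(np.where(cond, g, 0.0), a.data.shape),
                _unbroadcast(np.where(cond, 0.0, g), b.data.shape),
            ),
        )
    return np.where(cond, a, b)


def relu(x):
    return where(as_array(x) > 0, x, 0.0)


def mean(x, axis=None, keepdims: bool = False):
    if isinstance(x, Tensor):
        return x.mean(axis=axis, keepdims=keepdims)
    return np.mean(x, axis=axis, keepdims=keepdims)


def concatenate(parts: Sequence, axis: int = 0):
    if any(isinstance(p, Tensor) for p in parts):
        parts = [Tensor._lift(p) for p in parts]
        sizes = [p.data.shape[axis] for p in parts]
        out = np.concatenate([p.data for p in parts], axis=axis)
        bounds = np.cumsum([0] + sizes)

        def vjp(g):
            sl = [slice(None)] * g.ndim
            outs = []
            for i in range(len(parts)):
                sl[axis] = slice(bounds[i], bounds[i + 1])
                outs.append(g[tuple(sl)])
            return tuple(outs)

        return Tensor._make(out, tuple(parts), vjp)
    return np.concatenate(parts, axis=axis)


def pad2d(x, pad: int, mode: str = "constant"):
    """Pad the two trailing (spatial) axes by ``pad`` pixels.

    ``mode='constant'`` zero-pads; ``mode='edge'`` replicates the border.  The
    adjoint of replicate padding folds border gradients back onto the edge
    pixels, which is implemented generically by padding an index grid.
    """
    if pad == 0:
        return x
    if mode not in ("constant", "edge"):
        raise ValueError(f"unsupported pad mode: {mode!r}")
    data = as_array(x)
    widths = [(0, 0)] * (data.ndim - 2) + [(pad, pad)] * 2
    if not isinstance(x, Tensor):
        return np.pad(data, widths, mode=mode)

    out = np.pad(data, widths, mode=mode)
    H, W = data.shape[-2:]

    if mode == "constant":
        def vjp(g):
            return (g[..., pad:-pad, pad:-pad],)
    else:
        idx = np.arange(H * W).reshape(H, W)
        pidx = np.pad(idx, pad, mode="edge").ravel()

        def vjp(g):
            lead = g.shape[:-2]
            flat = g.reshape(*lead, -1)
            acc = np.zeros(lead + (H * W,))
            np.add.at(acc, (..., pidx), flat)
            return (acc.reshape(*lead, H, W),)

    return Tensor._make(out, (x,), vjp)


def _im2col(x: np.ndarray, kh: int, kw: int):
    """Contiguous (B*Ho*Wo, Cin*kh*kw) patch matrix of a padded NCHW input."""
    v = sliding_window_view(x, (kh, kw), axis=(2, 3))  # (B, C, Ho, Wo, kh, kw)
    B, C, Ho, Wo = v.shape[:4]
    cols = np.ascontiguousarray(v.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(B * Ho * Wo, C * kh * kw), (B, C, Ho, Wo)


def conv2d(x, w, b=None, padding: int = 0):
    """Stride-1 2-D cross-correlation, NCHW layout, optional zero padding.

    ``x``: (B, Cin, H, W); ``w``: (Cout, Cin, kh, kw); ``b``: (Cout,) or None.
    Any of the three may be a Tensor, in which case gradients flow to it.
    Implemented as im2col + matrix multiply; the backward pass scatters the
    column gradient back with one strided add per kernel tap.
    """
    tensors = [t for t in (x, w, b) if isinstance(t, Tensor)]
    xd, wd = as_array(x), as_array(w)
    bd = None if b is None else as_array(b)

    cout, cin, kh, kw = wd.shape
    xpad = (
        np.pad(xd, [(0, 0), (0, 0), (padding, padding), (padding, padding)])
        if padding
        else xd
    )
    cols, (B, _, Ho, Wo) = _im2col(xpad, kh, kw)
    wmat = wd.reshape(cout, cin * kh * kw)
    y2 = cols @ wmat.T  # (B*Ho*Wo, Cout)
    if bd is not None:
        y2 += bd
    y = np.ascontiguousarray(y2.reshape(B, Ho, Wo, cout).transpose(0, 3, 1, 2))
    if not tensors:
        return y

    parents = [Tensor._lift(x), Tensor._lift(w)]
    if b is not None:
        parents.append(Tensor._lift(b))
    Hp, Wp = xpad.shape[2], xpad.shape[3]

    def vjp(g):
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, cout)
        grad_w = (g2.T @ cols).reshape(cout, cin, kh, kw)
        grad_cols = (g2 @ wmat).reshape(B, Ho, Wo, cin, kh, kw)
        # col2im in BHWC layout (no per-tap transpose), one final transpose
        acc = np.zeros((B, Hp, Wp, cin))
        for i in range(kh):
            for j in range(kw):
                acc[:, i : i + Ho, j : j + Wo, :] += grad_cols[:, :, :, :, i, j]
        if padding:
            acc = acc[:, padding:-padding, padding:-padding, :]
        grads = [np.ascontiguousarray(acc.transpose(0, 3, 1, 2)), grad_w]
        if b is not None:
            grads.append(g2.sum(axis=0))
        return tuple(grads)

    return Tensor._make(y, tuple(parents), vjp)
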