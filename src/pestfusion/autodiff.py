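"""Reverse-mode automatic differentiation over numpy arrays.

A deliberately small engine: a :class:`Tensor` wraps an ``ndarray`` and
records the operations applied to it; :meth:`Tensor.backward` walks the
recorded graph in reverse topological order and accumulates gradients.
Only the primitives the recognition pipeline needs are provided
(broadcast arithmetic, matmul, 2-D convolution via im2col, separable
bilinear interpolation, reductions, concat/slice, the usual pointwise
nonlinearities).  Gradients flow through every primitive except where a
value is explicitly ``detach``-ed.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "conv2d", "interp2d", "no_grad"]


class _GradMode:
    enabled = True


class no_grad:
    """Context manager disabling graph recording (inference paths)."""

    def __enter__(self):
        self._prev = _GradMode.enabled
        _GradMode.enabled = False
        return self

    def __exit__(self, *exc):
        _GradMode.enabled = self._prev
        return False


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad: bool = False, name: str | None = None):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = bool(requires_grad) and _GradMode.enabled
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], None] | None = None
        self.name = name

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[[np.ndarray], None]) -> "Tensor":
        req = _GradMode.enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=False)
        out.requires_grad = req
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be supplied for non-scalar output")
            grad = np.ones_like(self.data)
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
        self._accum(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bw(g):
            a._accum(-g)

        return Tensor._make(-a.data, (a,), bw)

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / (b.data ** 2), b.shape))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent: float):
        a = self

        def bw(g):
            a._accum(g * exponent * a.data ** (exponent - 1))

        return Tensor._make(a.data ** exponent, (a,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return Tensor._make(a.data @ b.data, (a, b), bw)

    # -- pointwise ------------------------------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bw(g):
            a._accum(g * out_data)

        return Tensor._make(out_data, (a,), bw)

    def log(self):
        a = self

        def bw(g):
            a._accum(g / a.data)

        return Tensor._make(np.log(a.data), (a,), bw)

    def relu(self):
        a = self
        keep = a.data > 0

        def bw(g):
            a._accum(g * keep)

        return Tensor._make(a.data * keep, (a,), bw)

    def sigmoid(self):
        a = self
        s = 1.0 / (1.0 + np.exp(-a.data))

        def bw(g):
            a._accum(g * s * (1.0 - s))

        return Tensor._make(s, (a,), bw)

    def sqrt(self):
        return self ** 0.5

    # -- reductions / shape ---------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def bw(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.shape).copy())
                return
            gg = g
            if not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.shape).copy())

        return Tensor._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            count = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            count = int(np.prod([self.data.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bw(g):
            a._accum(g.reshape(old))

        return Tensor._make(a.data.reshape(shape), (a,), bw)

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(reversed(range(a.ndim)))
        inv = np.argsort(axes)

        def bw(g):
            a._accum(g.transpose(inv))

        return Tensor._make(a.data.transpose(axes), (a,), bw)

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._make(a.data[idx], (a,), bw)

    def max_detached(self, axis=None, keepdims: bool = False) -> np.ndarray:
        """Max as a constant (used for numerically stable softmax shifts)."""
        return self.data.max(axis=axis, keepdims=keepdims)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors: Iterable[Tensor], axis: int = -1) -> Tensor:
    ts = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    return Tensor._make(np.concatenate([t.data for t in ts], axis=axis), ts, bw)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    x, weight = as_tensor(x), as_tensor(weight)
    n, c, h, w = x.shape
    o, c2, kh, kw = weight.shape
    if c != c2:
        raise ValueError(f"conv2d channel mismatch: input {c}, weight {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    ho = (h + 2 * padding - kh) // stride + 1
    wo = (w + 2 * padding - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                  # n,c,ho,wo,kh,kw
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * ho * wo, c * kh * kw)
    wmat = weight.data.reshape(o, c * kh * kw)
    out = cols @ wmat.T
    if bias is not None:
        out = out + bias.data
    out = out.reshape(n, ho, wo, o).transpose(0, 3, 1, 2)
    parents = [x, weight] + ([bias] if bias is not None else [])

    def bw(g):
        gcols = g.transpose(0, 2, 3, 1).reshape(n * ho * wo, o)
        if weight.requires_grad:
            weight._accum((gcols.T @ cols).reshape(weight.shape))
        if bias is not None and bias.requires_grad:
            bias._accum(gcols.sum(axis=0))
        if x.requires_grad:
            gx_cols = (gcols @ wmat).reshape(n, ho, wo, c, kh, kw)
            gx_pad = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gx_pad[:, :, i:i + stride * ho:stride,
                           j:j + stride * wo:stride] += \
                        gx_cols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            if padding:
                gx_pad = gx_pad[:, :, padding:-padding, padding:-padding]
            x._accum(gx_pad)

    return Tensor._make(out, parents, bw)


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Corner-anchored bilinear weights mapping n_in samples to n_out.

    Output position i samples the source at i*(n_in-1)/(n_out-1), so an
    identity-size resize is exactly the identity matrix.
    """
    m = np.zeros((n_out, n_in))
    if n_in == 1:
        m[:, 0] = 1.0
        return m
    if n_out == 1:
        # single output row anchored at the first sample
        m[0, 0] = 1.0
        return m
    pos = np.arange(n_out) * (n_in - 1) / (n_out - 1)
    lo = np.floor(pos).astype(int)
    lo = np.minimum(lo, n_in - 2)
    frac = pos - lo
    m[np.arange(n_out), lo] = 1.0 - frac
    m[np.arange(n_out), lo + 1] = frac
    return m


def interp2d(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize of the trailing two axes of an NCHW (or CHW) tensor."""
    x = as_tensor(x)
    h, w = x.shape[-2], x.shape[-1]
    rr = _interp_matrix(out_h, h)
    rc = _interp_matrix(out_w, w)
    out = np.einsum("ij,...jk,lk->...il", rr, x.data, rc, optimize=True)

    def bw(g):
        x._accum(np.einsum("ij,...jk,lk->...il", rr.T, g, rc.T, optimize=True))

    return Tensor._make(out, (x,), bw)
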