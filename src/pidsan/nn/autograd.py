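"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order and
accumulates gradients.  The op set is exactly what the networks in this
package need: broadcasting arithmetic, (batched) matmul, reductions, shape
ops, stable softmax, 2-D convolution with channel groups, and 2x2 max
pooling.  Everything is dense NumPy; there is no lazy evaluation.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "no_grad"]


class _NoGrad:
    """Context manager that disables tape recording (used at eval time)."""

    _active = False

    def __enter__(self):
        self._prev = _NoGrad._active
        _NoGrad._active = True
        return self

    def __exit__(self, *exc):
        _NoGrad._active = self._prev
        return False


def no_grad() -> _NoGrad:
    return _NoGrad()


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and not _NoGrad._active
        self._backward = None
        self._parents = ()

    # -- construction helper for op results ---------------------------------
    @staticmethod
    def _result(data, parents, backward):
        out = Tensor(data)
        if not _NoGrad._active and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def _accum(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data, dtype=g.dtype if self.data.dtype.kind != "f" else self.data.dtype)
        self.grad = self.grad + g

    # -- autodiff ------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad))
        for t in reversed(topo):
            if t._backward is not None:
                t._backward(t.grad)

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x):
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)
        out_data = a.data + b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.shape))

        return Tensor._result(out_data, (a, b), bwd)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def bwd(g):
            a._accum(-g)

        return Tensor._result(-a.data, (a,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)
        out_data = a.data * b.data

        def bwd(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.shape))

        return Tensor._result(out_data, (a, b), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        b = Tensor._coerce(other)
        return self * b._reciprocal()

    def __rtruediv__(self, other):
        return Tensor._coerce(other) * self._reciprocal()

    def _reciprocal(self):
        a = self
        out_data = 1.0 / a.data

        def bwd(g):
            a._accum(-g * out_data * out_data)

        return Tensor._result(out_data, (a,), bwd)

    def __pow__(self, exponent: float):
        a = self
        out_data = a.data ** exponent

        def bwd(g):
            a._accum(g * exponent * a.data ** (exponent - 1))

        return Tensor._result(out_data, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._coerce(other)
        out_data = a.data @ b.data

        def bwd(g):
            if a.requires_grad:
                ga = g @ np.swapaxes(b.data, -1, -2)
                a._accum(_unbroadcast(ga, a.shape))
            if b.requires_grad:
                gb = np.swapaxes(a.data, -1, -2) @ g
                b._accum(_unbroadcast(gb, b.shape))

        return Tensor._result(out_data, (a, b), bwd)

    # -- elementwise nonlinearities -----------------------------------------
    def exp(self):
        a = self
        out_data = np.exp(a.data)

        def bwd(g):
            a._accum(g * out_data)

        return Tensor._result(out_data, (a,), bwd)

    def log(self):
        a = self

        def bwd(g):
            a._accum(g / a.data)

        return Tensor._result(np.log(a.data), (a,), bwd)

    def sigmoid(self):
        from scipy.special import expit

        a = self
        out_data = expit(a.data)

        def bwd(g):
            a._accum(g * out_data * (1.0 - out_data))

        return Tensor._result(out_data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0

        def bwd(g):
            a._accum(g * mask)

        return Tensor._result(a.data * mask, (a,), bwd)

    def clip_min(self, lo: float):
        """max(x, lo); gradient flows only where x > lo."""
        a = self
        mask = a.data > lo

        def bwd(g):
            a._accum(g * mask)

        return Tensor._result(np.maximum(a.data, lo), (a,), bwd)

    def clip_max(self, hi: float):
        a = self
        mask = a.data < hi

        def bwd(g):
            a._accum(g * mask)

        return Tensor._result(np.minimum(a.data, hi), (a,), bwd)

    def tanh(self):
        a = self
        out_data = np.tanh(a.data)

        def bwd(g):
            a._accum(g * (1.0 - out_data * out_data))

        return Tensor._result(out_data, (a,), bwd)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out_data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(ax % a.ndim for ax in axes):
                    g = np.expand_dims(g, ax)
            a._accum(np.broadcast_to(g, a.shape).copy())

        return Tensor._result(out_data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[ax] for ax in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        a = self
        old = a.shape

        def bwd(g):
            a._accum(g.reshape(old))

        return Tensor._result(a.data.reshape(shape), (a,), bwd)

    def transpose(self, axes):
        a = self
        inv = np.argsort(axes)

        def bwd(g):
            a._accum(g.transpose(inv))

        return Tensor._result(a.data.transpose(axes), (a,), bwd)

    def swapaxes(self, ax1: int, ax2: int):
        axes = list(range(self.ndim))
        axes[ax1], axes[ax2] = axes[ax2], axes[ax1]
        return self.transpose(tuple(axes))

    def __getitem__(self, idx):
        a = self

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return Tensor._result(a.data[idx], (a,), bwd)

    # -- fused numerically-stable ops -----------------------------------------
    def softmax(self, axis: int = -1):
        a = self
        z = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        s = e / e.sum(axis=axis, keepdims=True)

        def bwd(g):
            inner = (g * s).sum(axis=axis, keepdims=True)
            a._accum(s * (g - inner))

        return Tensor._result(s, (a,), bwd)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    return Tensor._result(out_data, tuple(tensors), bwd)


# ---------------------------------------------------------------------------
# Convolution and pooling (NCHW layout)
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D convolution (cross-correlation) on (B, C, H, W) input.

    ``w`` has shape (C_out, C_in // groups, kh, kw).  Depthwise convolution is
    ``groups == C_in`` with one filter per channel.
    """
    x = Tensor._coerce(x)
    w = Tensor._coerce(w)
    B, C, H, W = x.shape
    Cout, Cg, kh, kw = w.shape
    if C % groups or Cout % groups or Cg != C // groups:
        raise ValueError(
            f"channel/group mismatch: input {C} channels, weight {w.shape}, groups={groups}")
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    Hp, Wp = xp.shape[2], xp.shape[3]
    Ho = (Hp - kh) // s + 1
    Wo = (Wp - kw) // s + 1
    if Ho < 1 or Wo < 1:
        raise ValueError("convolution output would be empty")
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    win = win[:, :, ::s, ::s]                       # (B, C, Ho, Wo, kh, kw)
    cols = win.reshape(B, groups, Cg, Ho, Wo, kh, kw)
    wg = w.data.reshape(groups, Cout // groups, Cg, kh, kw)
    # (B, g, og, Ho, Wo)
    out = np.einsum("bgchwij,gocij->bgohw", cols, wg, optimize=True)
    out = out.reshape(B, Cout, Ho, Wo)
    if b is not None:
        out = out + b.data.reshape(1, Cout, 1, 1)

    def bwd(g):
        gg = g.reshape(B, groups, Cout // groups, Ho, Wo)
        if w.requires_grad:
            gw = np.einsum("bgohw,bgchwij->gocij", gg, cols, optimize=True)
            w._accum(gw.reshape(w.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)).reshape(b.shape))
        if x.requires_grad:
            # gradient w.r.t. the im2col windows, scattered back to the input
            gcols = np.einsum("bgohw,gocij->bgchwij", gg, wg, optimize=True)
            gcols = gcols.reshape(B, C, Ho, Wo, kh, kw)
            gxp = np.zeros((B, C, Hp, Wp), dtype=g.dtype)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += gcols[:, :, :, :, i, j]
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding]
            x._accum(gxp)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._result(out, parents, bwd)


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; odd trailing rows/columns are dropped."""
    x = Tensor._coerce(x)
    B, C, H, W = x.shape
    if H < 2 or W < 2:
        raise ValueError(f"cannot 2x2-pool a {H}x{W} map")
    H2, W2 = H // 2, W // 2
    xv = x.data[:, :, :2 * H2, :2 * W2].reshape(B, C, H2, 2, W2, 2)
    xv = xv.transpose(0, 1, 2, 4, 3, 5).reshape(B, C, H2, W2, 4)
    idx = xv.argmax(axis=-1)
    out = np.take_along_axis(xv, idx[..., None], axis=-1)[..., 0]

    def bwd(g):
        gx4 = np.zeros_like(xv)
        np.put_along_axis(gx4, idx[..., None], g[..., None], axis=-1)
        gx = gx4.reshape(B, C, H2, W2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        gx = gx.reshape(B, C, 2 * H2, 2 * W2)
        if gx.shape[2:] != (H, W):
            full = np.zeros_like(x.data)
            full[:, :, :2 * H2, :2 * W2] = gx
            gx = full
        x._accum(gx)

    return Tensor._result(out, (x,), bwd)
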