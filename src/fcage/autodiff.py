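"""Minimal reverse-mode automatic differentiation over numpy arrays.

The package trains small convolutional networks on p x p connectivity
matrices and differentiates their outputs with respect to the *input*
(for integrated gradients), so it needs a tape-based autodiff engine
rather than hand-derived layer backward passes.  This module provides a
``Tensor`` wrapping an ``ndarray`` plus the primitive operations the
models require: broadcast arithmetic, matmul, relu, softmax/logsumexp,
2-D convolution (3x3, arbitrary stride, zero padding 1), 2x2 max
pooling, reshape/transpose/concat and reductions.

Gradients are accumulated by topological-sort backward traversal; every
primitive's vector-Jacobian product is covered by finite-difference
checks in the test suite.  All data is float64.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2x2", "softmax", "logsumexp", "gather_rows"]


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=np.float64)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph: value, gradient, backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev: tuple = ()):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)
        self._backward = None
        self._prev = _prev

    # -- graph plumbing ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=np.float64, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None) -> None:
        """Reverse-accumulate gradients from this node to all ancestors."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; graphs can be deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        self._accum(_as_array(grad))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = _bwd
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def _bwd(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = _bwd
        return out

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    __radd__ = __add__
    __rmul__ = __mul__

    def __truediv__(self, other):
        if isinstance(other, Tensor):
            return self * other ** -1.0
        return self * (1.0 / float(other))

    def __pow__(self, exponent: float):
        out = Tensor(self.data ** exponent, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accum(g * exponent * self.data ** (exponent - 1.0))

        out._backward = _bwd
        return out

    def __matmul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def _bwd(g):
            # batched matmul may broadcast either operand over leading dims
            if self.requires_grad:
                self._accum(_unbroadcast(g @ other.data.swapaxes(-1, -2), self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(self.data.swapaxes(-1, -2) @ g, other.data.shape))

        out._backward = _bwd
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor(self.data.reshape(shape), _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        out._backward = _bwd
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(axes), _prev=(self,))
        inv = np.argsort(axes)

        def _bwd(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        out._backward = _bwd
        return out

    # -- nonlinearities / reductions ------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accum(g * mask)

        out._backward = _bwd
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accum(g * val)

        out._backward = _bwd
        return out

    def log(self):
        out = Tensor(np.log(self.data), _prev=(self,))

        def _bwd(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = _bwd
        return out

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        shape = self.data.shape

        def _bwd(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, shape))
            else:
                axes = (axis,) if isinstance(axis, int) else tuple(axis)
                if not keepdims:
                    g = np.expand_dims(g, tuple(a % len(shape) for a in axes))
                self._accum(np.broadcast_to(g, shape))

        out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in ((axis,) if isinstance(axis, int) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


# -- free-function primitives -------------------------------------------


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def _bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accum(piece)

    out._backward = _bwd
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    val = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(val, _prev=(x,))

    def _bwd(g):
        if x.requires_grad:
            inner = (g * val).sum(axis=axis, keepdims=True)
            x._accum(val * (g - inner))

    out._backward = _bwd
    return out


def logsumexp(x: Tensor, axis: int = -1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = np.exp(x.data - m)
    s = e.sum(axis=axis, keepdims=True)
    val = (np.log(s) + m).squeeze(axis)
    out = Tensor(val, _prev=(x,))
    soft = e / s

    def _bwd(g):
        if x.requires_grad:
            x._accum(np.expand_dims(g, axis) * soft)

    out._backward = _bwd
    return out


def gather_rows(x: Tensor, idx: np.ndarray) -> Tensor:
    """Pick ``x[i, idx[i]]`` per row of a 2-D tensor."""
    idx = np.asarray(idx, dtype=np.intp)
    rows = np.arange(x.data.shape[0])
    out = Tensor(x.data[rows, idx], _prev=(x,))

    def _bwd(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            np.add.at(full, (rows, idx), g)
            x._accum(full)

    out._backward = _bwd
    return out


def _im2col(xp: np.ndarray, stride: int, h_out: int, w_out: int) -> np.ndarray:
    """(B, C, Hp, Wp) zero-padded input -> (B*h_out*w_out, C*9) patch matrix."""
    b, c = xp.shape[:2]
    patches = np.empty((3, 3, b, c, h_out, w_out), dtype=np.float64)
    for ki in range(3):
        for kj in range(3):
            patches[ki, kj] = xp[
                :, :, ki : ki + stride * (h_out - 1) + 1 : stride,
                kj : kj + stride * (w_out - 1) + 1 : stride,
            ]
    # (B, h, w, C, 3, 3) -> rows are patches, columns match w.reshape(O, C*9)
    return patches.transpose(2, 4, 5, 3, 0, 1).reshape(b * h_out * w_out, c * 9)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """3x3 convolution with zero padding 1.

    x: (B, C, H, W); w: (O, C, 3, 3); b: (O,).  Output spatial size is
    ceil(H / stride).
    """
    bs, c, h, wd = x.data.shape
    o = w.data.shape[0]
    h_out = (h + 2 - 3) // stride + 1
    w_out = (wd + 2 - 3) // stride + 1
    xp = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)))
    cols = _im2col(xp, stride, h_out, w_out)
    w_flat = w.data.reshape(o, c * 9)
    out_val = (cols @ w_flat.T).reshape(bs, h_out, w_out, o).transpose(0, 3, 1, 2)
    out_val += b.data.reshape(1, o, 1, 1)
    out = Tensor(out_val, _prev=(x, w, b))

    def _bwd(g):
        g_rows = g.transpose(0, 2, 3, 1).reshape(bs * h_out * w_out, o)
        if w.requires_grad:
            w._accum((g_rows.T @ cols).reshape(o, c, 3, 3))
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = g_rows @ w_flat  # (B*h*w, C*9)
            dpatch = dcols.reshape(bs, h_out, w_out, c, 3, 3).transpose(4, 5, 0, 3, 1, 2)
            dxp = np.zeros_like(xp)
            for ki in range(3):
                for kj in range(3):
                    dxp[
                        :, :, ki : ki + stride * (h_out - 1) + 1 : stride,
                        kj : kj + stride * (w_out - 1) + 1 : stride,
                    ] += dpatch[ki, kj]
            x._accum(dxp[:, :, 1 : 1 + h, 1 : 1 + wd])

    out._backward = _bwd
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2; spatial dims must be even."""
    b, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    windows = x.data.reshape(b, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, ho, wo, 4)
    idx = windows.argmax(axis=-1)
    out = Tensor(np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def _bwd(g):
        if not x.requires_grad:
            return
        dwin = np.zeros((b, c, ho, wo, 4), dtype=np.float64)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        x._accum(dwin.reshape(b, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h, w))

    out._backward = _bwd
    return out
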