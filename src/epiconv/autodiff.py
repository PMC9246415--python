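"""Reverse-mode automatic differentiation on NumPy arrays.

A deliberately small tape-based engine: :class:`Tensor` wraps an
``ndarray`` and records enough of the computation graph to back-propagate
exact gradients.  Only the operations the epitope networks need are
implemented (elementwise arithmetic, matmul, gather, slicing,
concatenation, reductions, ReLU/sigmoid, windowed max/mean pooling).
Every gradient is validated against finite differences in the test suite.

All tensors are float64; problem sizes here are small enough that
precision is worth more than speed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "embedding_lookup", "conv1d_same", "pool1d", "Adam", "SGD"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing NumPy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # make ndarray defer to Tensor in mixed ops

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g):
            self._accum(-g)

        return self._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __mul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / other.data**2, other.data.shape)
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return Tensor._lift(other) / self

    def __pow__(self, p: float):
        assert np.isscalar(p)

        def backward(g):
            self._accum(g * p * self.data ** (p - 1))

        return self._make(self.data**p, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._lift(other)

        def backward(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        return self._make(np.matmul(self.data, other.data), (self, other), backward)

    # -- nonlinearities -------------------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g):
            self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        out_data = np.where(
            self.data >= 0,
            1.0 / (1.0 + np.exp(-np.clip(self.data, -500, None))),
            np.exp(np.clip(self.data, None, 500))
            / (1.0 + np.exp(np.clip(self.data, None, 500))),
        )

        def backward(g):
            self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def log(self):
        def backward(g):
            self._accum(g / self.data)

        return self._make(np.log(self.data), (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self**0.5

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        return self._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.max(self.data, axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accum(full)

        return self._make(out_data, (self,), backward)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape

        def backward(g):
            self._accum(g.reshape(orig))

        return self._make(self.data.reshape(*shape), (self,), backward)

    def __getitem__(self, key):
        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            self._accum(full)

        return self._make(self.data[key], (self,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad only on scalars")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._lift(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(lo, hi)
            t._accum(g[tuple(sl)])

    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


def embedding_lookup(table: Tensor, idx: np.ndarray) -> Tensor:
    """Gather rows of `table` (V, D) by integer index array `idx` (...,)."""
    idx = np.asarray(idx)
    if idx.size and (idx.min() < 0 or idx.max() >= table.data.shape[0]):
        raise IndexError(
            f"token index out of range [0, {table.data.shape[0] - 1}]"
        )

    def backward(g):
        full = np.zeros_like(table.data)
        np.add.at(full, idx.reshape(-1), g.reshape(-1, table.data.shape[1]))
        table._accum(full)

    return table._make(table.data[idx], (table,), backward)


def conv1d_same(x: Tensor, kernel: Tensor, bias: Tensor | None = None) -> Tensor:
    """Fused same-padded 1-D convolution along axis 1 of (B, L, C_in).

    kernel: (K, C_in, C_out).  A single graph node: forward via a strided
    window view + einsum, backward in closed form — equivalent to the
    pad/slice/matmul composition but far fewer tape entries.
    """
    kernel = Tensor._lift(kernel)
    B, L, C = x.data.shape
    K, c_in, c_out = kernel.data.shape
    if C != c_in:
        raise ValueError(f"input channels {C} != kernel channels {c_in}")
    half = K // 2
    xp = np.pad(x.data, ((0, 0), (half, half), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=1)
    # win: (B, L, C, K)
    out_data = np.einsum("blck,kco->blo", win, kernel.data, optimize=True)
    parents = [x, kernel]
    if bias is not None:
        bias = Tensor._lift(bias)
        out_data = out_data + bias.data
        parents.append(bias)

    def backward(g):
        kernel._accum(np.einsum("blck,blo->kco", win, g, optimize=True))
        if bias is not None:
            bias._accum(g.sum(axis=(0, 1)))
        if x.requires_grad:
            gx_tap = np.einsum("blo,kco->blkc", g, kernel.data, optimize=True)
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, k : k + L, :] += gx_tap[:, :, k, :]
            x._accum(gxp[:, half : half + L, :])

    return x._make(out_data, parents, backward)


def pool1d(x: Tensor, width: int, stride: int, kind: str = "max") -> Tensor:
    """Fused windowed pooling over axis 1 of (B, L, C); ragged tail kept.

    kind is "max" or "average".  Single graph node with scatter backward.
    """
    if kind not in ("max", "average"):
        raise ValueError(f"unknown pooling kind {kind!r}")
    B, L, C = x.data.shape
    starts = np.arange(0, L, stride)
    n = len(starts)
    # gather window member indices, padding the ragged tail with -1
    idx = starts[:, None] + np.arange(width)[None, :]  # (n, width)
    valid = idx < L
    idx_c = np.where(valid, idx, 0)
    win = x.data[:, idx_c, :]  # (B, n, width, C)
    if kind == "max":
        win = np.where(valid[None, :, :, None], win, -np.inf)
        arg = np.argmax(win, axis=2)  # (B, n, C)
        out_data = np.take_along_axis(win, arg[:, :, None, :], axis=2)[:, :, 0, :]

        def backward(g):
            rows = np.take_along_axis(
                np.broadcast_to(idx[None, :, :, None], win.shape),
                arg[:, :, None, :], axis=2,
            )[:, :, 0, :]  # (B, n, C) source row per output
            full = np.zeros_like(x.data)
            b_i = np.arange(B)[:, None, None]
            c_i = np.arange(C)[None, None, :]
            np.add.at(full, (b_i, rows, c_i), g)
            x._accum(full)

    else:
        counts = valid.sum(axis=1)  # (n,)
        win = np.where(valid[None, :, :, None], win, 0.0)
        out_data = win.sum(axis=2) / counts[None, :, None]

        def backward(g):
            full = np.zeros_like(x.data)
            share = g / counts[None, :, None]  # (B, n, C)
            for j in range(n):
                full[:, idx[j][valid[j]], :] += share[:, j : j + 1, :]
            x._accum(full)

    return x._make(out_data, (x,), backward)


class SGD:
    def __init__(self, params: list[Tensor], lr: float = 1e-2):
        self.params = params
        self.lr = lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class Adam:
    """Adaptive-moment estimation, standard bias-corrected form."""

    def __init__(
        self,
        params: list[Tensor],
        lr: float = 1e-3,
        betas=(0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
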