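"""Minimal reverse-mode automatic differentiation on NumPy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to it;
:meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  Only the primitives the blood-pressure
network needs are provided: elementwise arithmetic with broadcasting,
matmul, the sigmoid/tanh/ReLU nonlinearities, reductions, slicing/concat,
1-D convolution and transposed convolution, 2:1 max-pooling, batch
normalization and linear re-interpolation.  Everything runs in float64.

Gradient recording can be suspended with the :func:`no_grad` context
manager (used for validation/prediction passes).
"""

from __future__ import annotations

import contextlib
from typing import Callable, Sequence

import numpy as np

__all__ = ["Tensor", "no_grad", "concat"]

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Context manager that disables graph recording."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the original operand shape."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"

    def _accum(self, grad: np.ndarray, own: bool = False) -> None:
        # own=True promises grad is a freshly allocated array no one else
        # aliases, so it can be adopted without a defensive copy
        if self.grad is None:
            self.grad = grad if own else np.array(grad, dtype=np.float64)
        else:
            self.grad += grad

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones)."""
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = (
            np.ones_like(self.data) if grad is None else np.asarray(grad, dtype=np.float64)
        )
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward()

    # -- construction helper ---------------------------------------------

    @staticmethod
    def _make(data, parents: tuple["Tensor", ...], backward_factory) -> "Tensor":
        req = _grad_enabled and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward_factory(out)
        return out

    # -- elementwise arithmetic ------------------------------------------

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def factory(out):
            def bw():
                if a.requires_grad:
                    a._accum(_unbroadcast(out.grad, a.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(out.grad, b.shape))
            return bw

        return Tensor._make(a.data + b.data, (a, b), factory)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def factory(out):
            def bw():
                a._accum(-out.grad)
            return bw

        return Tensor._make(-a.data, (a,), factory)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def factory(out):
            def bw():
                if a.requires_grad:
                    a._accum(_unbroadcast(out.grad * b.data, a.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(out.grad * a.data, b.shape))
            return bw

        return Tensor._make(a.data * b.data, (a, b), factory)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other

        def factory(out):
            def bw():
                if a.requires_grad:
                    a._accum(_unbroadcast(out.grad / b.data, a.shape))
                if b.requires_grad:
                    b._accum(_unbroadcast(-out.grad * a.data / b.data**2, b.shape))
            return bw

        return Tensor._make(a.data / b.data, (a, b), factory)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        a, b = self, other
        if a.ndim != 2 or b.ndim != 2:
            raise ValueError("matmul supports 2-D operands only")

        def factory(out):
            def bw():
                if a.requires_grad:
                    a._accum(out.grad @ b.data.T)
                if b.requires_grad:
                    b._accum(a.data.T @ out.grad)
            return bw

        return Tensor._make(a.data @ b.data, (a, b), factory)

    def __pow__(self, p: float):
        a = self

        def factory(out):
            def bw():
                a._accum(out.grad * p * a.data ** (p - 1))
            return bw

        return Tensor._make(a.data**p, (a,), factory)

    # -- nonlinearities ---------------------------------------------------

    def sigmoid(self):
        a = self
        y = 1.0 / (1.0 + np.exp(-a.data))

        def factory(out):
            def bw():
                a._accum(out.grad * y * (1.0 - y), own=True)
            return bw

        return Tensor._make(y, (a,), factory)

    def tanh(self):
        a = self
        y = np.tanh(a.data)

        def factory(out):
            def bw():
                a._accum(out.grad * (1.0 - y**2), own=True)
            return bw

        return Tensor._make(y, (a,), factory)

    def relu(self):
        a = self
        mask = a.data > 0

        def factory(out):
            def bw():
                a._accum(out.grad * mask, own=True)
            return bw

        return Tensor._make(a.data * mask, (a,), factory)

    def abs(self):
        a = self
        sign = np.sign(a.data)

        def factory(out):
            def bw():
                a._accum(out.grad * sign, own=True)
            return bw

        return Tensor._make(np.abs(a.data), (a,), factory)

    # -- reductions / shape ----------------------------------------------

    def mean(self, axis=None, keepdims: bool = False):
        a = self
        y = a.data.mean(axis=axis, keepdims=keepdims)
        count = a.data.size if axis is None else np.prod(
            [a.shape[ax] for ax in (axis if isinstance(axis, tuple) else (axis,))]
        )

        def factory(out):
            def bw():
                g = out.grad
                if not keepdims and axis is not None:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.shape) / count, own=True)
            return bw

        return Tensor._make(y, (a,), factory)

    def sum(self, axis=None, keepdims: bool = False):
        a = self
        y = a.data.sum(axis=axis, keepdims=keepdims)

        def factory(out):
            def bw():
                g = out.grad
                if not keepdims and axis is not None:
                    g = np.expand_dims(g, axis)
                a._accum(np.broadcast_to(g, a.shape).copy(), own=True)
            return bw

        return Tensor._make(y, (a,), factory)

    def reshape(self, shape):
        a = self

        def factory(out):
            def bw():
                a._accum(out.grad.reshape(a.shape))
            return bw

        return Tensor._make(a.data.reshape(shape), (a,), factory)

    def __getitem__(self, key):
        a = self

        def factory(out):
            def bw():
                g = np.zeros_like(a.data)
                np.add.at(g, key, out.grad)
                a._accum(g)
            return bw

        return Tensor._make(a.data[key], (a,), factory)

    # -- structured primitives -------------------------------------------

    def conv1d(self, weight: "Tensor", bias: "Tensor" | None = None, pad: int = 0):
        """1-D cross-correlation, stride 1.  self: [B,C,L], weight: [O,C,K].

        Implemented as im2col + matmul; the column matrix is cached for the
        backward pass.
        """
        a, w = self, weight
        B, C, L = a.shape
        O, Cw, K = w.shape
        if Cw != C:
            raise ValueError(f"conv1d channel mismatch: input {C}, weight {Cw}")
        if pad > 0:
            xp = np.zeros((B, C, L + 2 * pad))
            xp[:, :, pad:pad + L] = a.data
        else:
            xp = a.data
        Lout = L + 2 * pad - K + 1
        # one batched GEMM per kernel tap: w[:,:,k] [O,C] @ xp slice [B,C,Lout]
        y = np.zeros((B, O, Lout))
        for k in range(K):
            y += np.matmul(w.data[:, :, k], xp[:, :, k:k + Lout])
        if bias is not None:
            y += bias.data[None, :, None]
        parents = (a, w) if bias is None else (a, w, bias)

        def factory(out):
            def bw():
                go = out.grad  # [B,O,Lout]
                if w.requires_grad:
                    gw = np.empty((O, C, K))
                    for k in range(K):
                        gw[:, :, k] = np.matmul(
                            go, xp[:, :, k:k + Lout].transpose(0, 2, 1)
                        ).sum(axis=0)
                    w._accum(gw)
                if bias is not None and bias.requires_grad:
                    bias._accum(go.sum(axis=(0, 2)))
                if a.requires_grad:
                    dxp = np.zeros((B, C, L + 2 * pad))
                    for k in range(K):
                        dxp[:, :, k:k + Lout] += np.matmul(w.data[:, :, k].T, go)
                    a._accum(dxp[:, :, pad:pad + L] if pad > 0 else dxp, own=True)
            return bw

        return Tensor._make(y, parents, factory)

    def conv_transpose1d(self, weight: "Tensor", bias: "Tensor" | None = None):
        """Stride-2, kernel-2 transposed convolution (length doubles).

        self: [B,C,L], weight: [C,O,2] -> [B,O,2L].
        """
        a, w = self, weight
        B, C, L = a.shape
        Cw, O, K = w.shape
        if Cw != C or K != 2:
            raise ValueError("conv_transpose1d expects weight [C,O,2] matching input channels")
        y = np.empty((B, O, 2 * L))
        y[:, :, 0::2] = np.matmul(w.data[:, :, 0].T, a.data)
        y[:, :, 1::2] = np.matmul(w.data[:, :, 1].T, a.data)
        if bias is not None:
            y += bias.data[None, :, None]
        parents = (a, w) if bias is None else (a, w, bias)

        def factory(out):
            def bw():
                go = out.grad
                g_even = np.ascontiguousarray(go[:, :, 0::2])  # [B,O,L]
                g_odd = np.ascontiguousarray(go[:, :, 1::2])
                if w.requires_grad:
                    gw = np.empty_like(w.data)
                    gw[:, :, 0] = np.matmul(a.data, g_even.transpose(0, 2, 1)).sum(axis=0)
                    gw[:, :, 1] = np.matmul(a.data, g_odd.transpose(0, 2, 1)).sum(axis=0)
                    w._accum(gw)
                if bias is not None and bias.requires_grad:
                    bias._accum(go.sum(axis=(0, 2)))
                if a.requires_grad:
                    da = np.matmul(w.data[:, :, 0], g_even)
                    da += np.matmul(w.data[:, :, 1], g_odd)
                    a._accum(da, own=True)
            return bw

        return Tensor._make(y, parents, factory)

    def maxpool2(self):
        """Max-pooling with kernel 2, stride 2 over the last axis."""
        a = self
        even, odd = a.data[..., 0::2], a.data[..., 1::2]
        mask = even >= odd
        y = np.where(mask, even, odd)

        def factory(out):
            def bw():
                g = np.zeros_like(a.data)
                g[..., 0::2] = out.grad * mask
                g[..., 1::2] = out.grad * ~mask
                a._accum(g, own=True)
            return bw

        return Tensor._make(y, (a,), factory)

    def interp_to(self, out_len: int):
        """Linear re-interpolation of the last axis to ``out_len`` samples."""
        a = self
        L = a.shape[-1]
        if L == out_len:
            return a
        pos = np.clip((np.arange(out_len) + 0.5) * L / out_len - 0.5, 0, L - 1)
        i0 = np.floor(pos).astype(np.int64)
        i1 = np.minimum(i0 + 1, L - 1)
        frac = pos - i0
        y = a.data[..., i0] * (1 - frac) + a.data[..., i1] * frac

        def factory(out):
            def bw():
                g = np.zeros_like(a.data)
                np.add.at(g, (Ellipsis, i0), out.grad * (1 - frac))
                np.add.at(g, (Ellipsis, i1), out.grad * frac)
                a._accum(g)
            return bw

        return Tensor._make(y, (a,), factory)


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along an axis (differentiable)."""
    tensors = [Tensor._wrap(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    y = np.concatenate([t.data for t in tensors], axis=axis)

    def factory(out):
        def bw():
            for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
                if t.requires_grad:
                    idx = [slice(None)] * y.ndim
                    idx[axis] = slice(lo, hi)
                    t._accum(out.grad[tuple(idx)])
        return bw

    return Tensor._make(y, tuple(tensors), factory)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalization over (batch, length) per channel for [B,C,L] input.

    In training mode batch statistics are used and the running estimates are
    updated in place; in eval mode the running estimates are used and treated
    as constants.
    """
    if training:
        mu = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        running_mean *= 1 - momentum
        running_mean += momentum * mu
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mu, var = running_mean, running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu[None, :, None]) * inv_std[None, :, None]
    y = gamma.data[None, :, None] * xhat + beta.data[None, :, None]
    parents = (x, gamma, beta)

    def factory(out):
        def bw():
            go = out.grad
            if gamma.requires_grad:
                gamma._accum((go * xhat).sum(axis=(0, 2)))
            if beta.requires_grad:
                beta._accum(go.sum(axis=(0, 2)))
            if x.requires_grad:
                g_xhat = go * gamma.data[None, :, None]
                if training:
                    n = x.data.shape[0] * x.data.shape[2]
                    s1 = g_xhat.sum(axis=(0, 2), keepdims=True)
                    s2 = (g_xhat * xhat).sum(axis=(0, 2), keepdims=True)
                    dx = (inv_std[None, :, None] / n) * (n * g_xhat - s1 - xhat * s2)
                else:
                    dx = g_xhat * inv_std[None, :, None]
                x._accum(dx, own=True)
        return bw

    return Tensor._make(y, parents, factory)
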