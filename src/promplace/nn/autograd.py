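"""Minimal reverse-mode automatic differentiation over numpy arrays.

Supports exactly the operations the place-back and determiner networks
need: broadcasting arithmetic, batched matmul, strided 1-D convolution,
embedding lookup, max/mean reductions, layer normalisation building
blocks, and fused numerically-stable losses. Everything is float32 and
fully deterministic for a given seed.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce ``grad`` back to ``shape`` after numpy broadcasting."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # -- arithmetic -----------------------------------------------------
    @staticmethod
    def _lift(x):
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._lift(other))

    def __rsub__(self, other):
        return Tensor._lift(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._lift(other)
        return self * other.reciprocal()

    def reciprocal(self):
        out = Tensor(1.0 / self.data, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(-g / (self.data * self.data))

        out._backward = bw
        return out

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor(self.data @ other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        out._backward = bw
        return out

    # -- shape ops ------------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def transpose(self, *axes):
        out = Tensor(self.data.transpose(*axes), (self,))
        inv = np.argsort(axes)

        def bw(g):
            if self.requires_grad:
                self._accum(g.transpose(*inv))

        out._backward = bw
        return out

    def swapaxes(self, a, b):
        out = Tensor(np.swapaxes(self.data, a, b), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, a, b))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accum(full)

        out._backward = bw
        return out

    @staticmethod
    def concat(tensors, axis=0):
        tensors = [Tensor._lift(t) for t in tensors]
        out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bw(g):
            parts = np.split(g, splits, axis=axis)
            for t, p in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(p)

        out._backward = bw
        return out

    # -- reductions -----------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis):
        """Max along one axis; ties route the gradient to the first argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = Tensor(np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis).squeeze(axis), (self,))

        def bw(g):
            if self.requires_grad:
                full = np.zeros_like(self.data)
                np.put_along_axis(full, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis=axis)
                self._accum(full)

        out._backward = bw
        return out

    # -- nonlinearities -------------------------------------------------
    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        out._backward = bw
        return out

    def tanh(self):
        y = np.tanh(self.data)
        out = Tensor(y, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * (1.0 - y * y))

        out._backward = bw
        return out

    def sigmoid(self):
        y = 1.0 / (1.0 + np.exp(-np.clip(self.data, -60, 60)))
        out = Tensor(y, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y * (1.0 - y))

        out._backward = bw
        return out

    def exp(self):
        y = np.exp(np.clip(self.data, -60, 60))
        out = Tensor(y, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * y)

        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g / self.data)

        out._backward = bw
        return out

    def sqrt(self):
        y = np.sqrt(self.data)
        out = Tensor(y, (self,))

        def bw(g):
            if self.requires_grad:
                self._accum(g * 0.5 / y)

        out._backward = bw
        return out

    def softmax(self, axis=-1):
        z = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=axis, keepdims=True)
        out = Tensor(p, (self,))

        def bw(g):
            if self.requires_grad:
                dot = (g * p).sum(axis=axis, keepdims=True)
                self._accum(p * (g - dot))

        out._backward = bw
        return out

    # -- structured ops -------------------------------------------------
    @staticmethod
    def embedding(weight: "Tensor", idx: np.ndarray):
        idx = np.asarray(idx)
        out = Tensor(weight.data[idx], (weight,))

        def bw(g):
            if weight.requires_grad:
                full = np.zeros_like(weight.data)
                np.add.at(full, idx.reshape(-1), g.reshape(-1, weight.data.shape[1]))
                weight._accum(full)

        out._backward = bw
        return out

    @staticmethod
    def conv1d(x: "Tensor", w: "Tensor", b: "Tensor", stride: int = 1, padding: int = 0):
        """x: (B, C, L), w: (O, C, K), b: (O,) -> (B, O, Lout)."""
        B, C, L = x.data.shape
        O, _, K = w.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding))) if padding else x.data
        Lp = xp.shape[2]
        Lout = (Lp - K) // stride + 1
        win = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)[:, :, ::stride, :]
        out_data = np.einsum("bclk,ock->bol", win, w.data, optimize=True) + b.data[None, :, None]
        out = Tensor(out_data, (x, w, b))

        def bw(g):
            if w.requires_grad:
                w._accum(np.einsum("bol,bclk->ock", g, win, optimize=True))
            if b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gxp = np.zeros((B, C, Lp), dtype=np.float32)
                pos = stride * np.arange(Lout)
                for k in range(K):
                    gxp[:, :, pos + k] += np.einsum("bol,oc->bcl", g, w.data[:, :, k], optimize=True)
                if padding:
                    gxp = gxp[:, :, padding:-padding]
                x._accum(gxp)

        out._backward = bw
        return out

    def repeat_interleave(self, repeats: int, axis: int):
        out = Tensor(np.repeat(self.data, repeats, axis=axis), (self,))

        def bw(g):
            if self.requires_grad:
                shape = list(self.data.shape)
                shape.insert(axis + 1, repeats)
                self._accum(g.reshape(shape).sum(axis=axis + 1))

        out._backward = bw
        return out

    # -- losses ---------------------------------------------------------
    @staticmethod
    def bce_with_logits(logits: "Tensor", targets: np.ndarray):
        """Mean binary cross-entropy, numerically stable; targets in {0,1}."""
        z = logits.data
        t = np.asarray(targets, dtype=np.float32)
        loss = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
        out = Tensor(loss.mean(), (logits,))

        def bw(g):
            if logits.requires_grad:
                sig = 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
                logits._accum(g * (sig - t) / z.size)

        out._backward = bw
        return out

    @staticmethod
    def softmax_cross_entropy(logits: "Tensor", labels: np.ndarray):
        """Mean categorical cross-entropy; logits (B, C), integer labels (B,)."""
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        p = e / e.sum(axis=1, keepdims=True)
        B = z.shape[0]
        nll = -np.log(np.maximum(p[np.arange(B), labels], 1e-12))
        out = Tensor(nll.mean(), (logits,))

        def bw(g):
            if logits.requires_grad:
                grad = p.copy()
                grad[np.arange(B), labels] -= 1.0
                logits._accum(g * grad / B)

        out._backward = bw
        return out


class Parameter(Tensor):
    """A leaf tensor updated by an optimizer."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)
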