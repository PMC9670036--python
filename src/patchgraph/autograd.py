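"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; :meth:`Tensor.backward` walks the recorded graph in reverse topological
order and accumulates gradients.  Gradients are kept on *every* tensor that
requires them, not only leaves — saliency mapping reads gradients off
intermediate attention tensors.

The op set is deliberately small: exactly what a graph-convolution +
transformer stack and an image backbone need (broadcasting arithmetic,
matmul, softmax, reductions, slicing/concat, im2col for convolution).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "as_tensor", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    # sum axes that were size-1 in the original
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple = ()

    # ------------------------------------------------------------------ basics
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    def _accumulate(self, g: np.ndarray):
        g = _unbroadcast(np.asarray(g), self.data.shape)
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad = self.grad + g

    # ---------------------------------------------------------------- backward
    def backward(self, seed: np.ndarray | None = None):
        """Accumulate gradients of ``self`` w.r.t. every ancestor.

        ``seed`` defaults to 1 and must match ``self.shape`` otherwise.
        """
        if seed is None:
            if self.data.size != 1:
                raise ValueError("backward() without seed requires a scalar output")
            seed = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [self]
        # iterative post-order DFS (graphs can be deep for long training chains)
        visiting: list[tuple[Tensor, bool]] = [(self, False)]
        while visiting:
            node, processed = visiting.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            visiting.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    visiting.append((p, False))
        del stack
        self._accumulate(seed)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # ------------------------------------------------------------- op plumbing
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(p for p in parents if p.requires_grad)
            out._backward = backward
        return out

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(g)
            if b.requires_grad:
                b._accumulate(g)

        return Tensor._make(a.data + b.data, (a, b), bw)

    __radd__ = __add__

    def __neg__(self):
        a = self
        return Tensor._make(-a.data, (a,), lambda g: a._accumulate(-g))

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __mul__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(g * b.data)
            if b.requires_grad:
                b._accumulate(g * a.data)

        return Tensor._make(a.data * b.data, (a, b), bw)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other)
        a, b = self, other

        def bw(g):
            if a.requires_grad:
                a._accumulate(g / b.data)
            if b.requires_grad:
                b._accumulate(-g * a.data / (b.data * b.data))

        return Tensor._make(a.data / b.data, (a, b), bw)

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, p: float):
        a = self
        out_data = a.data ** p

        def bw(g):
            a._accumulate(g * p * a.data ** (p - 1))

        return Tensor._make(out_data, (a,), bw)

    def __matmul__(self, other):
        other = as_tensor(other)
        a, b = self, other
        a1, b1 = a.data.ndim == 1, b.data.ndim == 1

        def bw(g):
            ad = a.data[None, :] if a1 else a.data
            bd = b.data[:, None] if b1 else b.data
            gg = g
            if a1 and b1:
                gg = np.asarray(g).reshape(1, 1)
            elif a1:
                gg = np.expand_dims(g, -2)
            elif b1:
                gg = np.expand_dims(g, -1)
            if a.requires_grad:
                ga = np.matmul(gg, np.swapaxes(bd, -1, -2))
                a._accumulate(ga[..., 0, :] if a1 else ga)
            if b.requires_grad:
                gb = np.matmul(np.swapaxes(ad, -1, -2), gg)
                b._accumulate(gb[..., 0] if b1 else gb)

        return Tensor._make(np.matmul(a.data, b.data), (a, b), bw)

    # -------------------------------------------------------------- elementwise
    def relu(self):
        a = self
        mask = a.data > 0
        return Tensor._make(a.data * mask, (a,), lambda g: a._accumulate(g * mask))

    def gelu(self):
        """Gaussian error linear unit (tanh approximation)."""
        a = self
        c = np.sqrt(2.0 / np.pi)
        x = a.data
        inner = c * (x + 0.044715 * x ** 3)
        t = np.tanh(inner)
        out = 0.5 * x * (1.0 + t)

        def bw(g):
            dinner = c * (1.0 + 3 * 0.044715 * x ** 2)
            grad = 0.5 * (1.0 + t) + 0.5 * x * (1.0 - t ** 2) * dinner
            a._accumulate(g * grad)

        return Tensor._make(out, (a,), bw)

    def exp(self):
        a = self
        out = np.exp(a.data)
        return Tensor._make(out, (a,), lambda g: a._accumulate(g * out))

    def log(self):
        a = self
        return Tensor._make(np.log(a.data), (a,), lambda g: a._accumulate(g / a.data))

    def sqrt(self):
        a = self
        out = np.sqrt(a.data)
        return Tensor._make(out, (a,), lambda g: a._accumulate(g * 0.5 / out))

    def tanh(self):
        a = self
        out = np.tanh(a.data)
        return Tensor._make(out, (a,), lambda g: a._accumulate(g * (1 - out ** 2)))

    # --------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        out = a.data.sum(axis=axis, keepdims=keepdims)

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            a._accumulate(np.broadcast_to(g, a.data.shape))

        return Tensor._make(out, (a,), bw)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    # ------------------------------------------------------------ shape surgery
    def reshape(self, *shape):
        a = self
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        return Tensor._make(
            a.data.reshape(shape), (a,), lambda g: a._accumulate(g.reshape(a.data.shape))
        )

    def transpose(self, *axes):
        a = self
        if not axes:
            axes = tuple(range(a.ndim))[::-1]
        elif len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(
            a.data.transpose(axes), (a,), lambda g: a._accumulate(g.transpose(inv))
        )

    @property
    def T(self):
        return self.transpose()

    def __getitem__(self, idx):
        a = self

        def bw(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._make(a.data[idx], (a,), bw)

    # ------------------------------------------------------------------ softmax
    def softmax(self, axis: int = -1):
        a = self
        x = a.data - a.data.max(axis=axis, keepdims=True)
        e = np.exp(x)
        out = e / e.sum(axis=axis, keepdims=True)

        def bw(g):
            dot = (g * out).sum(axis=axis, keepdims=True)
            a._accumulate((g - dot) * out)

        return Tensor._make(out, (a,), bw)

    def log_softmax(self, axis: int = -1):
        a = self
        x = a.data - a.data.max(axis=axis, keepdims=True)
        lse = np.log(np.exp(x).sum(axis=axis, keepdims=True))
        out = x - lse

        def bw(g):
            soft = np.exp(out)
            a._accumulate(g - soft * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out, (a,), bw)

    # ------------------------------------------------------------------ im2col
    def im2col(self, ksize: int, stride: int, pad: int):
        """Unfold (B, C, H, W) into (B, oh*ow, C*ksize*ksize) patches.

        Convolution then reduces to a matmul; the backward pass scatters
        gradients back with ``col2im``.
        """
        a = self
        B, C, H, W = a.data.shape
        x = np.pad(a.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        oh = (H + 2 * pad - ksize) // stride + 1
        ow = (W + 2 * pad - ksize) // stride + 1
        s0, s1, s2, s3 = x.strides
        windows = np.lib.stride_tricks.as_strided(
            x,
            shape=(B, C, oh, ow, ksize, ksize),
            strides=(s0, s1, s2 * stride, s3 * stride, s2, s3),
        )
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(B, oh * ow, C * ksize * ksize)

        def bw(g):
            g = g.reshape(B, oh, ow, C, ksize, ksize).transpose(0, 3, 1, 2, 4, 5)
            full = np.zeros_like(x)
            for i in range(ksize):
                for j in range(ksize):
                    full[:, :, i : i + oh * stride : stride, j : j + ow * stride : stride] += g[
                        :, :, :, :, i, j
                    ]
            if pad:
                full = full[:, :, pad:-pad, pad:-pad]
            a._accumulate(full)

        out = Tensor._make(np.ascontiguousarray(cols), (a,), bw)
        return out, oh, ow


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def concat(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    return Tensor._make(data, tuple(tensors), bw)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    data = np.stack([t.data for t in tensors], axis=axis)

    def bw(g):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(np.take(g, i, axis=axis))

    return Tensor._make(data, tuple(tensors), bw)
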