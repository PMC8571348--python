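"""Reverse-mode automatic differentiation over NumPy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations applied to
it; calling :meth:`Tensor.backward` on a scalar result walks the recorded
graph in reverse topological order and accumulates gradients.  Only the
operations the package's models need are implemented; broadcasting is
supported in elementwise ops (gradients are summed back over broadcast
axes).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack_last"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to produce ``grad``."""
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
    """An array node in the autodiff graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    # -- graph mechanics ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
            if node._backward is not None:
                node._backward(node.grad)

    def _accumulate(self, grad: np.ndarray) -> None:
        grad = _unbroadcast(np.asarray(grad), self.data.shape)
        self.grad = grad if self.grad is None else self.grad + grad

    # -- elementwise --------------------------------------------------------

    @staticmethod
    def _coerce(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(grad):
            if self.requires_grad:
                self._accumulate(grad)
            if other.requires_grad:
                other._accumulate(grad)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))
        out._backward = lambda grad: self.requires_grad and self._accumulate(-grad)
        return out

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(grad):
            if self.requires_grad:
                self._accumulate(grad * other.data)
            if other.requires_grad:
                other._accumulate(grad * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._coerce(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(grad):
            if self.requires_grad:
                self._accumulate(grad @ np.swapaxes(other.data, -1, -2))
            if other.requires_grad:
                other._accumulate(np.swapaxes(self.data, -1, -2) @ grad)

        out._backward = bw
        return out

    # -- nonlinearities ------------------------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(self.data * mask, parents=(self,))
        out._backward = lambda grad: self.requires_grad and self._accumulate(
            grad * mask
        )
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -500, 500)))
        out = Tensor(s, parents=(self,))
        out._backward = lambda grad: self.requires_grad and self._accumulate(
            grad * s * (1 - s)
        )
        return out

    def tanh(self):
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda grad: self.requires_grad and self._accumulate(
            grad * (1 - t * t)
        )
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))
        out._backward = lambda grad: self.requires_grad and self._accumulate(
            grad / self.data
        )
        return out

    # -- reductions / shaping -------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(grad):
            if not self.requires_grad:
                return
            g = np.asarray(grad)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(
            self.data, np.expand_dims(idx, axis), axis=axis
        ).squeeze(axis)
        out = Tensor(out_data, parents=(self,))

        def bw(grad):
            if not self.requires_grad:
                return
            g = np.zeros_like(self.data)
            np.put_along_axis(
                g, np.expand_dims(idx, axis), np.expand_dims(grad, axis), axis=axis
            )
            self._accumulate(g)

        out._backward = bw
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda grad: self.requires_grad and self._accumulate(
            np.asarray(grad).reshape(self.data.shape)
        )
        return out

    def __getitem__(self, key):
        out = Tensor(self.data[key], parents=(self,))

        def bw(grad):
            if not self.requires_grad:
                return
            g = np.zeros_like(self.data)
            np.add.at(g, key, grad)
            self._accumulate(g)

        out._backward = bw
        return out


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor(np.concatenate(datas, axis=axis), parents=tuple(tensors))
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def bw(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * grad.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(grad[tuple(sl)])

    out._backward = bw
    return out


def stack_last(tensors: list[Tensor]) -> Tensor:
    """Stack equally shaped tensors along a new final axis."""
    out = Tensor(np.stack([t.data for t in tensors], axis=-1), parents=tuple(tensors))

    def bw(grad):
        for i, t in enumerate(tensors):
            if t.requires_grad:
                t._accumulate(grad[..., i])

    out._backward = bw
    return out
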