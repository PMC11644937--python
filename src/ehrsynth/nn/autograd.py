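"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the tabular GAN: dense algebra, the usual
activations, reductions, concatenation/slicing, an embedding lookup and the
minibatch-similarity primitive used by the critic. Gradients are accumulated
into ``Tensor.grad`` by :meth:`Tensor.backward`, which walks the recorded
graph in reverse topological order. Broadcasting is supported; gradients are
summed back over broadcast axes.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np

__all__ = ["Tensor", "concat", "embedding_lookup", "minibatch_similarity"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape needed to differentiate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad
        self.grad: np.ndarray | None = None
        self._backward: Callable[[np.ndarray], None] | None = None
        self._prev: tuple[Tensor, ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @classmethod
    def _make(cls, data, prev: Iterable["Tensor"], backward) -> "Tensor":
        prev = tuple(prev)
        needs = any(p.requires_grad or p._prev for p in prev)
        out = cls(data, requires_grad=needs)
        if needs:
            out._prev = prev
            out._backward = backward
        return out

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)
        # topological order via iterative DFS
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=float)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad and node._backward is None:
                node._accumulate(g)  # leaf (parameter or user input)
            if node._backward is not None:
                for p, pg in zip(node._prev, node._backward(g)):
                    if pg is None or not (p.requires_grad or p._prev):
                        continue
                    if id(p) in grads:
                        grads[id(p)] = grads[id(p)] + pg
                    else:
                        grads[id(p)] = pg

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data + other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g, self.data.shape),
                _unbroadcast(g, other.data.shape),
            ),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data * other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g * other.data, self.data.shape),
                _unbroadcast(g * self.data, other.data.shape),
            ),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data / other.data,
            (self, other),
            lambda g: (
                _unbroadcast(g / other.data, self.data.shape),
                _unbroadcast(-g * self.data / other.data**2, other.data.shape),
            ),
        )

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __matmul__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data @ other.data,
            (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g),
        )

    def __pow__(self, p: float):
        return Tensor._make(
            self.data**p, (self,), lambda g: (g * p * self.data ** (p - 1),)
        )

    # -- reductions & reshapes --------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g):
            if axis is None:
                return (np.broadcast_to(g, self.data.shape).copy(),)
            gg = g
            if not keepdims:
                gg = np.expand_dims(g, axis)
            return (np.broadcast_to(gg, self.data.shape).copy(),)

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], tuple):
            shape = shape[0]
        return Tensor._make(
            self.data.reshape(shape), (self,), lambda g: (g.reshape(self.data.shape),)
        )

    def __getitem__(self, idx):
        def backward(g):
            out = np.zeros_like(self.data)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out_data = np.sqrt(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * 0.5 / out_data,))

    def abs(self):
        return Tensor._make(
            np.abs(self.data), (self,), lambda g: (g * np.sign(self.data),)
        )

    def tanh(self):
        out_data = np.tanh(self.data)
        return Tensor._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(
            out_data, (self,), lambda g: (g * out_data * (1 - out_data),)
        )

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def relu(self):
        mask = (self.data > 0).astype(float)
        return Tensor._make(self.data * mask, (self,), lambda g: (g * mask,))

    def softmax(self, axis: int = -1):
        shifted = self.data - self.data.max(axis=axis, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=axis, keepdims=True)

        def backward(g):
            dot = (g * out_data).sum(axis=axis, keepdims=True)
            return (out_data * (g - dot),)

        return Tensor._make(out_data, (self,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
    )


def embedding_lookup(weight: Tensor, indices: np.ndarray) -> Tensor:
    """Row lookup ``weight[indices]`` with scatter-add gradient."""
    indices = np.asarray(indices, dtype=int)

    def backward(g):
        out = np.zeros_like(weight.data)
        np.add.at(out, indices, g)
        return (out,)

    return Tensor._make(weight.data[indices], (weight,), backward)


def minibatch_similarity(M: Tensor) -> Tensor:
    """Batch-similarity statistics o_i[b] = sum_{j != i} exp(-||M_ib - M_jb||_1).

    ``M`` has shape (n, B, C); the result has shape (n, B). The diagonal term
    contributes exp(0) = 1, so the sum over all j minus one equals the sum
    over j != i.
    """
    Md = M.data
    if Md.ndim != 3:
        raise ValueError("expected (n, B, C) projections")
    diff = Md[:, None, :, :] - Md[None, :, :, :]  # (n, n, B, C)
    L1 = np.abs(diff).sum(axis=-1)  # (n, n, B)
    E = np.exp(-L1)
    out_data = E.sum(axis=1) - 1.0  # remove the j = i term

    def backward(g):
        # d o_{i,b} / d M_{p,b,c}: terms with i = p and with j = p combine to
        # -(g_p + g_j) * E_pj * sign(M_p - M_j), summed over j.
        w = (g[:, None, :] + g[None, :, :]) * E  # (n, n, B)
        gM = -(w[..., None] * np.sign(diff)).sum(axis=1)  # (n, B, C)
        return (gM,)

    return Tensor._make(out_data, (M,), backward)
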