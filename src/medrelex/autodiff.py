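"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operator set the encoder and CNN head need: broadcast
arithmetic, (batched) matrix products, reductions, ``log_softmax``,
embedding lookup with scatter-add backward, slicing, concatenation, GELU /
ReLU / tanh / erf nonlinearities and inverted dropout.  Gradients
accumulate into ``Tensor.grad`` after calling :meth:`Tensor.backward` on a
scalar loss.  All arrays are float64; randomness (dropout) comes from a
caller-supplied :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from typing import Callable, Iterable, Sequence

import numpy as np
from scipy import special as _sp

__all__ = ["Tensor", "concat", "relu", "gelu", "Adam", "clip_global_norm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node in the computation graph wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward: Callable[[np.ndarray], tuple[np.ndarray, ...]] | None = None

    # -- graph plumbing ----------------------------------------------------

    @classmethod
    def _node(cls, data: np.ndarray, parents: Sequence["Tensor"], backward) -> "Tensor":
        out = cls(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def backward(self) -> None:
        """Backpropagate from a scalar; accumulates into ``.grad`` of leaves."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
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
        grads: dict[int, np.ndarray] = {id(self): np.ones_like(self.data)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node._backward is None:
                node.grad = g if node.grad is None else node.grad + g
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if not parent.requires_grad or pg is None:
                    continue
                if id(parent) in grads:
                    grads[id(parent)] = grads[id(parent)] + pg
                else:
                    grads[id(parent)] = pg
            if not node._parents:
                node.grad = g if node.grad is None else node.grad + g

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        sa, sb = self.data.shape, other.data.shape
        return Tensor._node(
            self.data + other.data,
            (self, other),
            lambda g: (_unbroadcast(g, sa), _unbroadcast(g, sb)),
        )

    __radd__ = __add__

    def __neg__(self):
        return Tensor._node(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self.data, other.data
        return Tensor._node(
            a * b,
            (self, other),
            lambda g: (_unbroadcast(g * b, a.shape), _unbroadcast(g * a, b.shape)),
        )

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self * self._wrap(other).power(-1.0)

    def power(self, p: float) -> "Tensor":
        a = self.data
        out = a ** p
        return Tensor._node(out, (self,), lambda g: (g * p * a ** (p - 1.0),))

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        a, b = self.data, other.data
        out = np.matmul(a, b)

        def back(g: np.ndarray):
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            if ga.shape != a.shape:
                ga = _unbroadcast(ga, a.shape)
            if gb.shape != b.shape:
                gb = _unbroadcast(gb, b.shape)
            return ga, gb

        return Tensor._node(out, (self, other), back)

    __matmul__ = matmul

    # -- shape ops ---------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        old = self.data.shape
        return Tensor._node(self.data.reshape(*shape), (self,), lambda g: (g.reshape(old),))

    def transpose(self, *axes) -> "Tensor":
        inv = np.argsort(axes)
        return Tensor._node(
            self.data.transpose(*axes), (self,), lambda g: (g.transpose(*inv),)
        )

    def __getitem__(self, idx) -> "Tensor":
        def back(g: np.ndarray):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._node(self.data[idx], (self,), back)

    # -- reductions --------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        shape = self.data.shape

        def back(g: np.ndarray):
            if axis is None:
                return (np.broadcast_to(g, shape).copy(),)
            gg = g if keepdims else np.expand_dims(g, axis)
            return (np.broadcast_to(gg, shape).copy(),)

        return Tensor._node(self.data.sum(axis=axis, keepdims=keepdims), (self,), back)

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out = self.data.max(axis=axis, keepdims=keepdims)

        def back(g: np.ndarray):
            expanded = out if keepdims else np.expand_dims(out, axis)
            hit = (self.data == expanded).astype(np.float64)
            hit /= hit.sum(axis=axis, keepdims=True)  # split ties evenly
            gg = g if keepdims else np.expand_dims(g, axis)
            return (hit * gg,)

        return Tensor._node(out, (self,), back)

    # -- nonlinearities ----------------------------------------------------

    def exp(self) -> "Tensor":
        out = np.exp(self.data)
        return Tensor._node(out, (self,), lambda g: (g * out,))

    def log(self) -> "Tensor":
        a = self.data
        return Tensor._node(np.log(a), (self,), lambda g: (g / a,))

    def tanh(self) -> "Tensor":
        out = np.tanh(self.data)
        return Tensor._node(out, (self,), lambda g: (g * (1.0 - out * out),))

    def erf(self) -> "Tensor":
        a = self.data
        return Tensor._node(
            _sp.erf(a),
            (self,),
            lambda g: (g * (2.0 / np.sqrt(np.pi)) * np.exp(-a * a),),
        )

    def log_softmax(self, axis: int = -1) -> "Tensor":
        a = self.data
        m = a.max(axis=axis, keepdims=True)
        z = a - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse

        def back(g: np.ndarray):
            soft = np.exp(out)
            return (g - soft * g.sum(axis=axis, keepdims=True),)

        return Tensor._node(out, (self,), back)

    def softmax(self, axis: int = -1) -> "Tensor":
        return self.log_softmax(axis=axis).exp()

    def dropout(self, p: float, rng: np.random.Generator | None, training: bool) -> "Tensor":
        if not training or p <= 0.0:
            return self
        if rng is None:
            raise ValueError("dropout in training mode needs a random generator")
        keep = (rng.random(self.data.shape) >= p).astype(np.float64) / (1.0 - p)
        return self * Tensor(keep)

    # -- gather ------------------------------------------------------------

    def take_rows(self, idx0: np.ndarray, idx1: np.ndarray) -> "Tensor":
        """Gather rows ``self[idx0, idx1, :]`` from a (B, L, H) tensor."""

        def back(g: np.ndarray):
            full = np.zeros_like(self.data)
            np.add.at(full, (idx0, idx1), g)
            return (full,)

        return Tensor._node(self.data[idx0, idx1], (self,), back)


def embedding(table: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``table[ids]`` with scatter-add gradient into the table."""
    ids = np.asarray(ids)

    def back(g: np.ndarray):
        full = np.zeros_like(table.data)
        np.add.at(full, ids, g)
        return (full,)

    return Tensor._node(table.data[ids], (table,), back)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._node(np.concatenate(datas, axis=axis), tuple(tensors), back)


def relu(x: Tensor) -> Tensor:
    a = x.data
    mask = (a > 0).astype(np.float64)
    return Tensor._node(a * mask, (x,), lambda g: (g * mask,))


def gelu(x: Tensor) -> Tensor:
    """Exact Gaussian-error-linear unit: x * Phi(x)."""
    phi = 0.5 * ((x * (1.0 / np.sqrt(2.0))).erf() + 1.0)
    return x * phi


# ---------------------------------------------------------------------------
# optimization
# ---------------------------------------------------------------------------


def clip_global_norm(params: Iterable[Tensor], max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    tensors = [p for p in params if p.grad is not None]
    total = float(np.sqrt(sum(float((p.grad ** 2).sum()) for p in tensors)))
    if total > max_norm and total > 0.0:
        scale = max_norm / total
        for p in tensors:
            p.grad *= scale
    return total


class Adam:
    """Adam with fixed learning rate and bias correction."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            mhat = m / (1.0 - self.b1 ** self.t)
            vhat = v / (1.0 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
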