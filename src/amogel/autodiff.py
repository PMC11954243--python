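"""Minimal vectorized reverse-mode automatic differentiation on numpy arrays.

The graph encoder needs only a small fixed vocabulary of differentiable
operations (dense algebra, pointwise nonlinearities, gather/segment-sum along
the node axis, and a numerically stable softmax built from them), so the
engine stays deliberately tiny: a :class:`Tensor` records its parents and a
backward closure, and :func:`backward` walks the tape in reverse topological
order.  All gradients are checked against central finite differences in the
test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "glorot_uniform"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape`, undoing numpy broadcasting."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An array node in the autodiff tape."""

    __slots__ = ("data", "grad", "parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    # -- helpers ----------------------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64))

    def _accumulate(self, g: np.ndarray) -> None:
        g = _unbroadcast(np.asarray(g, dtype=np.float64), self.data.shape)
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad = self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            self._accumulate(g)
            other._accumulate(g)

        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))
        out._backward = lambda g: self._accumulate(-g)
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            self._accumulate(g * other.data)
            other._accumulate(g * self.data)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, (self, other))

        def bw(g):
            self._accumulate(g / other.data)
            other._accumulate(-g * self.data / (other.data**2))

        out._backward = bw
        return out

    def __pow__(self, p: float):
        out = Tensor(self.data**p, (self,))
        out._backward = lambda g: self._accumulate(g * p * self.data ** (p - 1))
        return out

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._wrap(other)
        out = Tensor(np.matmul(self.data, other.data), (self, other))

        def bw(g):
            a, b = self.data, other.data
            ga = np.matmul(g, np.swapaxes(b, -1, -2))
            gb = np.matmul(np.swapaxes(a, -1, -2), g)
            self._accumulate(_unbroadcast(ga, a.shape))
            other._accumulate(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- pointwise ---------------------------------------------------------
    def exp(self):
        out_data = np.exp(self.data)  # captured by value: no self-referential cycle
        out = Tensor(out_data, (self,))
        out._backward = lambda g: self._accumulate(g * out_data)
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))
        out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def leaky_relu(self, slope: float = 0.2):
        mask = np.where(self.data > 0, 1.0, slope)
        out = Tensor(self.data * mask, (self,))
        out._backward = lambda g: self._accumulate(g * mask)
        return out

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * (np.exp(np.minimum(self.data, 0.0)) - 1.0))
        out = Tensor(out_data, (self,))
        deriv = np.where(pos, 1.0, out_data + alpha)
        out._backward = lambda g: self._accumulate(g * deriv)
        return out

    # -- reductions / shaping ---------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), (self,))
        out._backward = lambda g: self._accumulate(np.asarray(g).reshape(self.data.shape))
        return out

    def take(self, idx: np.ndarray, axis: int) -> "Tensor":
        """Gather rows along `axis` (differentiable index_select)."""
        idx = np.asarray(idx)
        out = Tensor(np.take(self.data, idx, axis=axis), (self,))

        def bw(g):
            acc = np.zeros_like(self.data)
            np.add.at(np.moveaxis(acc, axis, 0), idx, np.moveaxis(np.asarray(g), axis, 0))
            self._accumulate(acc)

        out._backward = bw
        return out

    def segment_sum(self, idx: np.ndarray, num_segments: int, axis: int) -> "Tensor":
        """Sum entries sharing an index along `axis` into `num_segments` slots."""
        idx = np.asarray(idx)
        moved = np.moveaxis(self.data, axis, 0)
        acc = np.zeros((num_segments,) + moved.shape[1:], dtype=np.float64)
        np.add.at(acc, idx, moved)
        out = Tensor(np.moveaxis(acc, 0, axis), (self,))

        def bw(g):
            g_moved = np.moveaxis(np.asarray(g), axis, 0)
            self._accumulate(np.moveaxis(g_moved[idx], 0, axis))

        out._backward = bw
        return out

    def concat(self, others: "list[Tensor]", axis: int) -> "Tensor":
        parts = [self] + list(others)
        out = Tensor(np.concatenate([p.data for p in parts], axis=axis), parts)
        sizes = [p.data.shape[axis] for p in parts]
        offsets = np.cumsum([0] + sizes)

        def bw(g):
            g = np.asarray(g)
            for p, a, b in zip(parts, offsets[:-1], offsets[1:]):
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                p._accumulate(g[tuple(sl)])

        out._backward = bw
        return out

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- backward ----------------------------------------------------------
    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: tapes can exceed the recursion limit
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node.parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    """Glorot/Xavier-uniform initialized trainable tensor."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Adam:
    """Adam with coupled L2 weight decay (decay added to the gradient)."""

    def __init__(self, params: "list[Tensor]", lr: float = 5e-5, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
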