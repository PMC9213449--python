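"""Minimal reverse-mode automatic differentiation on numpy arrays.

A :class:`Tensor` wraps an ndarray and records the operations applied to
it; :meth:`Tensor.backward` walks the tape in reverse topological order
and accumulates gradients into every tensor created with
``requires_grad=True``. Only the primitives needed by the sequence models
in this package are implemented (broadcast arithmetic, matmul, common
nonlinearities, reductions, indexing, concatenation, log-softmax, a 1-D
unfold for convolutions and a per-row padded reverse for bidirectional
recurrence). Gradient correctness is property-tested against central
finite differences.
"""

from __future__ import annotations

from typing import Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data: ArrayLike, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.requires_grad = requires_grad
        self.grad: Optional[np.ndarray] = None
        self._backward = None
        self._prev: Tuple["Tensor", ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _result(data: np.ndarray, prev: Sequence["Tensor"], backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad or p._prev for p in prev):
            out.requires_grad = True
            out._prev = tuple(prev)
            out._backward = backward
        return out

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar tensor")
        topo: List[Tensor] = []
        seen = set()
        stack: List[Tuple[Tensor, bool]] = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    # -- arithmetic --------------------------------------------------------
    @staticmethod
    def _wrap(x: Union["Tensor", ArrayLike]) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._wrap(other)
        data = a.data + b.data

        def bwd(g):
            a._accumulate(_unbroadcast(g, a.data.shape))
            b._accumulate(_unbroadcast(g, b.data.shape))

        return Tensor._result(data, (a, b), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._wrap(other)
        data = a.data * b.data

        def bwd(g):
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

        return Tensor._result(data, (a, b), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        b = Tensor._wrap(other)
        return self * (b ** -1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * (self ** -1.0)

    def __pow__(self, exponent: float):
        a = self
        data = a.data ** exponent

        def bwd(g):
            a._accumulate(g * exponent * a.data ** (exponent - 1.0))

        return Tensor._result(data, (a,), bwd)

    def __matmul__(self, other):
        a, b = self, Tensor._wrap(other)
        data = a.data @ b.data

        def bwd(g):
            ga = g @ np.swapaxes(b.data, -1, -2)
            gb = np.swapaxes(a.data, -1, -2) @ g
            a._accumulate(_unbroadcast(ga, a.data.shape))
            b._accumulate(_unbroadcast(gb, b.data.shape))

        return Tensor._result(data, (a, b), bwd)

    # -- nonlinearities ----------------------------------------------------
    def exp(self):
        a = self
        data = np.exp(a.data)

        def bwd(g):
            a._accumulate(g * data)

        return Tensor._result(data, (a,), bwd)

    def log(self):
        a = self
        data = np.log(a.data)

        def bwd(g):
            a._accumulate(g / a.data)

        return Tensor._result(data, (a,), bwd)

    def tanh(self):
        a = self
        data = np.tanh(a.data)

        def bwd(g):
            a._accumulate(g * (1.0 - data * data))

        return Tensor._result(data, (a,), bwd)

    def sigmoid(self):
        a = self
        data = 1.0 / (1.0 + np.exp(-a.data))

        def bwd(g):
            a._accumulate(g * data * (1.0 - data))

        return Tensor._result(data, (a,), bwd)

    def relu(self):
        a = self
        mask = a.data > 0
        data = a.data * mask

        def bwd(g):
            a._accumulate(g * mask)

        return Tensor._result(data, (a,), bwd)

    # -- reductions & shaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        a = self
        data = a.data.sum(axis=axis, keepdims=keepdims)

        def bwd(g):
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accumulate(np.broadcast_to(gg, a.data.shape).copy())

        return Tensor._result(data, (a,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        a = self
        data = a.data.reshape(*shape)

        def bwd(g):
            a._accumulate(g.reshape(a.data.shape))

        return Tensor._result(data, (a,), bwd)

    def transpose(self, axes: Sequence[int]):
        a = self
        data = a.data.transpose(axes)
        inv = np.argsort(axes)

        def bwd(g):
            a._accumulate(g.transpose(inv))

        return Tensor._result(data, (a,), bwd)

    def __getitem__(self, idx):
        a = self
        data = a.data[idx]

        def bwd(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accumulate(full)

        return Tensor._result(data, (a,), bwd)

    def log_softmax(self, axis: int = -1):
        a = self
        x = a.data
        m = x.max(axis=axis, keepdims=True)
        z = x - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        data = z - lse

        def bwd(g):
            softmax = np.exp(data)
            a._accumulate(g - softmax * g.sum(axis=axis, keepdims=True))

        return Tensor._result(data, (a,), bwd)

    def softmax(self, axis: int = -1):
        a = self
        x = a.data
        z = np.exp(x - x.max(axis=axis, keepdims=True))
        data = z / z.sum(axis=axis, keepdims=True)

        def bwd(g):
            dot = (g * data).sum(axis=axis, keepdims=True)
            a._accumulate(data * (g - dot))

        return Tensor._result(data, (a,), bwd)


def concat(tensors: Sequence[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bwd(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accumulate(piece)

    return Tensor._result(data, tensors, bwd)


def unfold1d(x: Tensor, kernel: int) -> Tensor:
    """Sliding windows along the time axis with zero padding.

    Input (B, T, C) -> output (B, T, kernel*C): position ``t`` holds the
    concatenation of ``x[:, t - k//2 + j, :]`` for ``j`` in ``0..kernel-1``
    (zeros outside the sequence). This is the im2col step of a same-padded
    1-D convolution.
    """
    B, T, C = x.data.shape
    half = kernel // 2
    xp = np.zeros((B, T + kernel - 1, C))
    xp[:, half:half + T] = x.data
    data = np.concatenate([xp[:, j:j + T, :] for j in range(kernel)], axis=2)

    def bwd(g):
        gp = np.zeros((B, T + kernel - 1, C))
        for j in range(kernel):
            gp[:, j:j + T, :] += g[:, :, j * C:(j + 1) * C]
        x._accumulate(gp[:, half:half + T])

    return Tensor._result(data, (x,), bwd)


def reverse_padded(x: Tensor, lengths: np.ndarray) -> Tensor:
    """Reverse each row's first ``lengths[b]`` steps, leave the tail alone.

    Self-inverse permutation per row; used so a backward-direction
    recurrence reads every sequence from its true end regardless of
    padding.
    """
    B, T = x.data.shape[:2]
    idx = np.tile(np.arange(T), (B, 1))
    for b, L in enumerate(lengths):
        idx[b, :L] = np.arange(L - 1, -1, -1)
    rows = np.arange(B)[:, None]
    data = x.data[rows, idx]

    def bwd(g):
        x._accumulate(g[rows, idx])  # involution: same gather

    return Tensor._result(data, (x,), bwd)


class Parameter(Tensor):
    __slots__ = ("name",)

    def __init__(self, data: np.ndarray, name: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: Optional[Tuple[int, ...]] = None) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape or (fan_in, fan_out))


class Adam:
    """Adam optimizer over a list of :class:`Parameter`."""

    def __init__(self, params: Iterable[Parameter], lr: float = 2.5e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
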