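"""Minimal reverse-mode automatic differentiation over numpy arrays.

A tape-based engine sized for the small sequence models in this package:
dense layers, gated recurrent steps, and 1-D convolutions expressed as
slice + matmul. Everything is float64 so gradient checks against central
finite differences hold to ~1e-9 and runs are bit-reproducible on one
machine.

Only the operations the model graphs need are implemented; each op stores
a closure that accumulates gradients into its parents. `Tensor.backward`
runs a topological sort and is valid for scalar outputs (or any output
when a seed gradient is supplied).
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "stack", "sigmoid", "tanh", "relu", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for axis, size in enumerate(shape):
        if size == 1 and grad.shape[axis] != 1:
            grad = grad.sum(axis=axis, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, _parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._parents = _parents
        self._backward = None

    # ---- graph plumbing -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _make(self, data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents),
                     _parents=tuple(p for p in parents if p.requires_grad))
        if out.requires_grad:
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    def backward(self, seed: np.ndarray | None = None) -> None:
        order: list[Tensor] = []
        state: dict[int, int] = {}
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if state.get(id(node)):
                continue
            state[id(node)] = 1
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        if seed is None:
            seed = np.ones_like(self.data)
        self._accum(np.asarray(seed, dtype=np.float64))
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # ---- arithmetic -----------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))

        return self._make(a.data + b.data, (a, b), backward)

    __radd__ = __add__

    def __neg__(self):
        a = self

        def backward(g):
            a._accum(-g)

        return self._make(-a.data, (a,), backward)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))

        return self._make(a.data * b.data, (a, b), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = self._wrap(other)
        a, b = self, other

        def backward(g):
            if a.requires_grad:
                a._accum(g @ b.data.T)
            if b.requires_grad:
                b._accum(a.data.T @ g)

        return self._make(a.data @ b.data, (a, b), backward)

    def __getitem__(self, idx):
        a = self

        def backward(g):
            full = np.zeros_like(a.data)
            np.add.at(full, idx, g)
            a._accum(full)

        return self._make(a.data[idx], (a,), backward)

    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def backward(g):
            a._accum(g.reshape(old))

        return self._make(a.data.reshape(*shape), (a,), backward)

    def sum(self, axis=None, keepdims: bool = False):
        a = self

        def backward(g):
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())

        return self._make(a.data.sum(axis=axis, keepdims=keepdims), (a,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        a = self
        arg = np.argmax(a.data, axis=axis)

        def backward(g):
            full = np.zeros_like(a.data)
            idx = list(np.indices(arg.shape))
            idx.insert(axis if axis >= 0 else a.data.ndim + axis, arg)
            np.add.at(full, tuple(idx), g)
            a._accum(full)

        return self._make(a.data.max(axis=axis), (a,), backward)


# ---- nonlinearities & shape ops -----------------------------------------


def sigmoid(x: Tensor) -> Tensor:
    out_data = 0.5 * (np.tanh(0.5 * x.data) + 1.0)  # numerically stable

    def backward(g):
        x._accum(g * out_data * (1.0 - out_data))

    return x._make(out_data, (x,), backward)


def tanh(x: Tensor) -> Tensor:
    out_data = np.tanh(x.data)

    def backward(g):
        x._accum(g * (1.0 - out_data ** 2))

    return x._make(out_data, (x,), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        x._accum(g * mask)

    return x._make(x.data * mask, (x,), backward)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    datas = [t.data for t in tensors]
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)
    out_data = np.concatenate(datas, axis=axis)
    parents = tuple(tensors)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in parents),
                 _parents=tuple(t for t in parents if t.requires_grad))
    if out.requires_grad:
        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    out_data = np.stack([t.data for t in tensors], axis=axis)

    def backward(g):
        for k, t in enumerate(tensors):
            if t.requires_grad:
                t._accum(np.take(g, k, axis=axis))

    out = Tensor(out_data, requires_grad=any(t.requires_grad for t in tensors),
                 _parents=tuple(t for t in tensors if t.requires_grad))
    if out.requires_grad:
        out._backward = backward
    return out


# ---- optimizer -----------------------------------------------------------


class Adam:
    """Adam over a name->Tensor parameter dict; only names in `mask` update.

    Frozen parameters never receive an update nor optimizer state, so they
    stay bit-identical through any number of steps.
    """

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 mask: set[str] | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.mask = set(params) if mask is None else set(mask)
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.items() if k in self.mask}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items() if k in self.mask}

    def step(self) -> None:
        self.t += 1
        for name in self.mask:
            p = self.params[name]
            if p.grad is None:
                continue
            g = p.grad
            self.m[name] = self.b1 * self.m[name] + (1 - self.b1) * g
            self.v[name] = self.b2 * self.v[name] + (1 - self.b2) * g * g
            mhat = self.m[name] / (1 - self.b1 ** self.t)
            vhat = self.v[name] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
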