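"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine sized for the models in this package
(three-layer LSTMs, pooled classifier heads, a 1-D CNN): float64 throughout,
eager graph construction, topological-order backward.  It exposes exactly the
operations those models need — no more.

Gradients for every primitive are checked against central finite differences
in the test suite.
"""

from __future__ import annotations

import contextlib

import numpy as np

_grad_enabled = True


@contextlib.contextmanager
def no_grad():
    """Disable graph construction (inference / frozen encoding)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) and _grad_enabled
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def zero_grad(self):
        self.grad = None

    def _accumulate(self, g: np.ndarray):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if _grad_enabled and any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic ----------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g, b.shape))

        return Tensor._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(-g)

        return Tensor._make(-self.data, (self,), backward)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    def __rsub__(self, other):
        return Tensor._coerce(other) + (-self)

    def __mul__(self, other):
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(_unbroadcast(g * b.data, a.shape))
            if b.requires_grad:
                b._accumulate(_unbroadcast(g * a.data, b.shape))

        return Tensor._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __matmul__(self, other):
        other = Tensor._coerce(other)

        def backward(g, a=self, b=other):
            if a.requires_grad:
                a._accumulate(g @ b.data.swapaxes(-1, -2))
            if b.requires_grad:
                gb = a.data.swapaxes(-1, -2) @ g
                b._accumulate(_unbroadcast(gb, b.shape))

        return Tensor._make(self.data @ other.data, (self, other), backward)

    # -- elementwise nonlinearities -------------------------------------------
    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g, a=self, s=s):
            if a.requires_grad:
                a._accumulate(g * s * (1 - s))

        return Tensor._make(s, (self,), backward)

    def tanh(self):
        t = np.tanh(self.data)

        def backward(g, a=self, t=t):
            if a.requires_grad:
                a._accumulate(g * (1 - t * t))

        return Tensor._make(t, (self,), backward)

    def relu(self):
        mask = self.data > 0

        def backward(g, a=self, mask=mask):
            if a.requires_grad:
                a._accumulate(g * mask)

        return Tensor._make(self.data * mask, (self,), backward)

    def exp(self):
        e = np.exp(self.data)

        def backward(g, a=self, e=e):
            if a.requires_grad:
                a._accumulate(g * e)

        return Tensor._make(e, (self,), backward)

    def log(self):
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g / a.data)

        return Tensor._make(np.log(self.data), (self,), backward)

    # -- shape ops -------------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def backward(g, a=self, old=old):
            if a.requires_grad:
                a._accumulate(g.reshape(old))

        return Tensor._make(self.data.reshape(*shape), (self,), backward)

    @property
    def T(self) -> "Tensor":
        def backward(g, a=self):
            if a.requires_grad:
                a._accumulate(g.T)

        return Tensor._make(self.data.T, (self,), backward)

    def __getitem__(self, key):
        def backward(g, a=self, key=key):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                np.add.at(full, key, g)
                a._accumulate(full)

        return Tensor._make(self.data[key], (self,), backward)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int = -1) -> "Tensor":
        sizes = [t.data.shape[axis] for t in tensors]
        offs = np.cumsum([0] + sizes)

        def backward(g, ts=tuple(tensors), offs=offs, axis=axis):
            for i, t in enumerate(ts):
                if t.requires_grad:
                    idx = [slice(None)] * g.ndim
                    idx[axis] = slice(offs[i], offs[i + 1])
                    t._accumulate(g[tuple(idx)])

        return Tensor._make(
            np.concatenate([t.data for t in tensors], axis=axis), tensors, backward
        )

    @staticmethod
    def stack(tensors: list["Tensor"], axis: int = 0) -> "Tensor":
        def backward(g, ts=tuple(tensors), axis=axis):
            for i, t in enumerate(ts):
                if t.requires_grad:
                    t._accumulate(np.take(g, i, axis=axis))

        return Tensor._make(
            np.stack([t.data for t in tensors], axis=axis), tensors, backward
        )

    # -- reductions --------------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        def backward(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accumulate(np.broadcast_to(g, a.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                a._accumulate(np.broadcast_to(g, a.shape).copy())

        return Tensor._make(
            self.data.sum(axis=axis, keepdims=keepdims), (self,), backward
        )

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int, keepdims=False):
        """Max over one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)

        def backward(g, a=self, idx=idx, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(a.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            a._accumulate(full)

        return Tensor._make(
            out if keepdims else out.squeeze(axis), (self,), backward
        )

    # -- fused losses -------------------------------------------------------------
    def log_softmax(self, axis: int = -1):
        m = self.data.max(axis=axis, keepdims=True)
        z = self.data - m
        lse = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - lse
        sm = np.exp(out)

        def backward(g, a=self, sm=sm, axis=axis):
            if a.requires_grad:
                a._accumulate(g - sm * g.sum(axis=axis, keepdims=True))

        return Tensor._make(out, (self,), backward)

    def softmax(self, axis: int = -1):
        return self.log_softmax(axis=axis).exp()

    # -- graph traversal -------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited or not node.requires_grad:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=np.float64))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)
                # interior nodes do not need to keep their gradient
                if node is not self and node._parents:
                    node.grad = None


def cross_entropy_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy from logits; targets are integer ids.

    logits: (N, V); targets: (N,).
    """
    logp = logits.log_softmax(axis=-1)
    n = targets.shape[0]
    picked = logp[np.arange(n), targets]
    return -picked.mean()


def bce_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy from logits (numerically stable)."""
    x, t = logits, np.asarray(targets, dtype=np.float64)
    # log(1+exp(x)) = max(x,0) + log1p(exp(-|x|)), expressed via primitives
    xd = logits.data
    softplus = np.maximum(xd, 0) + np.log1p(np.exp(-np.abs(xd)))
    sig = 1.0 / (1.0 + np.exp(-xd))

    def backward(g, a=x, sig=sig, t=t):
        if a.requires_grad:
            a._accumulate(g * (sig - t) / t.size)

    loss = float(np.mean(softplus - xd * t))
    return Tensor._make(np.asarray(loss), (x,), backward)
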