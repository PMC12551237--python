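"""Minimal reverse-mode automatic differentiation over numpy arrays.

Just enough machinery for the compact sequence networks in this package:
broadcast-aware elementwise ops, (batched) matmul, 1-D convolution, softmax
and reductions, with an Adam optimizer.  Gradients are verified against
central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "matmul", "conv1d", "relu", "softmax", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.grad = None
        self._parents = tuple(parents)
        self._backward = backward

    # -- autodiff driver ----------------------------------------------------
    def backward(self) -> None:
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
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    @staticmethod
    def _accum(t: "Tensor", g: np.ndarray) -> None:
        if t.requires_grad:
            t.grad = g if t.grad is None else t.grad + g

    # -- elementwise --------------------------------------------------------
    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(g):
            Tensor._accum(a, _unbroadcast(g, a.data.shape))
            Tensor._accum(b, _unbroadcast(g, b.data.shape))

        return Tensor(a.data + b.data, parents=(a, b), backward=bw)

    __radd__ = __add__

    def __mul__(self, other):
        a, b = self, Tensor._coerce(other)

        def bw(g):
            Tensor._accum(a, _unbroadcast(g * b.data, a.data.shape))
            Tensor._accum(b, _unbroadcast(g * a.data, b.data.shape))

        return Tensor(a.data * b.data, parents=(a, b), backward=bw)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._coerce(other))

    # -- shape --------------------------------------------------------------
    def reshape(self, *shape):
        a = self
        old = a.data.shape

        def bw(g):
            Tensor._accum(a, g.reshape(old))

        return Tensor(a.data.reshape(*shape), parents=(a,), backward=bw)

    def transpose(self, *axes):
        a = self
        inv = np.argsort(axes)

        def bw(g):
            Tensor._accum(a, g.transpose(*inv))

        return Tensor(a.data.transpose(*axes), parents=(a,), backward=bw)

    # -- reductions ---------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        a = self

        def bw(g):
            gg = g
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            Tensor._accum(a, np.broadcast_to(gg, a.data.shape).copy())

        return Tensor(a.data.sum(axis=axis, keepdims=keepdims), parents=(a,), backward=bw)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        Tensor._accum(x, g * mask)

    return Tensor(x.data * mask, parents=(x,), backward=bw)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    a, b = Tensor._coerce(a), Tensor._coerce(b)
    out = np.matmul(a.data, b.data)

    def bw(g):
        if a.requires_grad:
            ga = np.matmul(g, np.swapaxes(b.data, -1, -2))
            Tensor._accum(a, _unbroadcast(ga, a.data.shape))
        if b.requires_grad:
            gb = np.matmul(np.swapaxes(a.data, -1, -2), g)
            Tensor._accum(b, _unbroadcast(gb, b.data.shape))

    return Tensor(out, parents=(a, b), backward=bw)


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)

    def bw(g):
        Tensor._accum(x, s * (g - (g * s).sum(axis=axis, keepdims=True)))

    return Tensor(s, parents=(x,), backward=bw)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def bw(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            Tensor._accum(t, piece)

    return Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        parents=tuple(tensors), backward=bw,
    )


def conv1d(x: Tensor, w: Tensor, padding: int = 0) -> Tensor:
    """1-D convolution: x (B, C_in, L), w (C_out, C_in, K) -> (B, C_out, L_out)."""
    B, Ci, L = x.data.shape
    Co, Ci2, K = w.data.shape
    assert Ci == Ci2, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (B,Ci,Lo,K)
    out = np.einsum("bclk,ock->bol", windows, w.data, optimize=True)
    Lo = out.shape[2]

    def bw(g):
        if w.requires_grad:
            Tensor._accum(w, np.einsum("bclk,bol->ock", windows, g, optimize=True))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for k in range(K):
                gxp[:, :, k:k + Lo] += np.einsum("bol,oc->bcl", g, w.data[:, :, k], optimize=True)
            gx = gxp[:, :, padding:padding + L] if padding else gxp
            Tensor._accum(x, gx)

    return Tensor(out, parents=(x, w), backward=bw)


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad ** 2
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
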