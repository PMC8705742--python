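"""Minimal reverse-mode automatic differentiation over NumPy arrays.

Provides exactly the operations the spatio-temporal graph-convolutional
encoder and the contrastive loss need: broadcast arithmetic, 2D matmul,
ReLU, exp/log/sqrt, axis reductions, reshape/transpose, a skeleton graph
convolution and a 1xG temporal convolution. Gradients are accumulated by a
topologically ordered backward sweep; correctness is checked against
central finite differences in the test suite.

All computation is float64, which makes seeded runs bit-reproducible on a
given platform.
"""

from __future__ import annotations

import numpy as np


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading dims added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A NumPy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents", "name")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None,
                 name: str | None = None):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = tuple(parents)
        self._backward = backward
        self.name = name

    # -- graph plumbing ----------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (default seed: ones for scalars)."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen = set()

        def visit(t: Tensor):
            stack = [(t, False)]
            while stack:
                node, done = stack.pop()
                if done:
                    topo.append(node)
                    continue
                if id(node) in seen or not node.requires_grad:
                    continue
                seen.add(id(node))
                stack.append((node, True))
                for p in node._parents:
                    stack.append((p, False))

        visit(self)
        self._accumulate(np.asarray(grad, dtype=float))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.shape))
        out._backward = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)
        out._backward = bw
        return out

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.shape))
        out._backward = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data / other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(-g * self.data / other.data ** 2, other.shape))
        out._backward = bw
        return out

    def __matmul__(self, other):
        other = self._wrap(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.T)
            if other.requires_grad:
                other._accumulate(self.data.T @ g)
        out._backward = bw
        return out

    # -- elementwise nonlinearities ----------------------------------------

    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * mask)
        out._backward = bw
        return out

    def exp(self):
        val = np.exp(self.data)
        out = Tensor(val, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * val)
        out._backward = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)
        out._backward = bw
        return out

    def sqrt(self):
        val = np.sqrt(self.data)
        out = Tensor(val, parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * 0.5 / val)
        out._backward = bw
        return out

    # -- shape & reductions --------------------------------------------------

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(self.shape))
        out._backward = bw
        return out

    def transpose(self, *axes):
        axes = axes or None
        out = Tensor(np.transpose(self.data, axes), parents=(self,))
        inv = np.argsort(axes) if axes else None

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.transpose(g, inv))
        out._backward = bw
        return out

    @property
    def T(self):
        return self.transpose()

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.shape).copy())
        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def concat(tensors: list, axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis``; the gradient splits back."""
    tensors = [t if isinstance(t, Tensor) else Tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accumulate(g[tuple(sl)])
    out._backward = bw
    return out


def graph_conv(x: Tensor, S: Tensor) -> Tensor:
    """Spatial aggregation over the skeleton: y[n,c,v,t] = sum_w S[v,w] x[n,c,w,t].

    ``x`` is an (N, C, V, T) feature map, ``S`` a (V, V) spatial operator
    (normalized adjacency, possibly masked by learnable edge importance).
    """
    out = Tensor(np.tensordot(S.data, x.data, axes=([1], [2])).transpose(1, 2, 0, 3),
                 parents=(x, S))

    def bw(g):
        if x.requires_grad:
            x._accumulate(np.tensordot(S.data, g, axes=([0], [2])).transpose(1, 2, 0, 3))
        if S.requires_grad:
            S._accumulate(np.tensordot(g, x.data, axes=([0, 1, 3], [0, 1, 3])))
    out._backward = bw
    return out


def temporal_conv(x: Tensor, W: Tensor, b: Tensor | None = None, stride: int = 1) -> Tensor:
    """1xG temporal convolution on an (N, C_in, V, T) map.

    ``W`` has shape (C_out, C_in, G) with G odd; the map is zero-padded by
    G//2 on the time axis, so T is preserved at stride 1 and becomes
    ceil(T/stride) otherwise. The channel mixing of this convolution is the
    weight matrix of the graph layer.
    """
    N, C_in, V, T = x.shape
    C_out, C_in2, G = W.shape
    if C_in2 != C_in:
        raise ValueError(f"channel mismatch: x has {C_in}, W expects {C_in2}")
    if G % 2 != 1:
        raise ValueError("temporal kernel size must be odd")
    pad = G // 2
    T_out = -(-T // stride)  # ceil
    xp = np.pad(x.data, ((0, 0), (0, 0), (0, 0), (pad, pad)))
    y = np.zeros((N, C_out, V, T_out))
    for k in range(G):
        sl = xp[:, :, :, k:k + stride * T_out:stride]
        y += np.tensordot(W.data[:, :, k], sl[:, :, :, :T_out],
                          axes=([1], [1])).transpose(1, 0, 2, 3)
    if b is not None:
        y = y + b.data.reshape(1, C_out, 1, 1)
    parents = (x, W) if b is None else (x, W, b)
    out = Tensor(y, parents=parents)

    def bw(g):
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if W.requires_grad or x.requires_grad:
            gxp = np.zeros_like(xp) if x.requires_grad else None
            for k in range(G):
                sl = xp[:, :, :, k:k + stride * T_out:stride][:, :, :, :T_out]
                if W.requires_grad:
                    gk = np.tensordot(g, sl, axes=([0, 2, 3], [0, 2, 3]))
                    if W.grad is None:
                        W.grad = np.zeros_like(W.data)
                    W.grad[:, :, k] += gk
                if gxp is not None:
                    gx_sl = np.tensordot(W.data[:, :, k], g,
                                         axes=([0], [1])).transpose(1, 0, 2, 3)
                    gxp[:, :, :, k:k + stride * T_out:stride][:, :, :, :T_out] += gx_sl
            if gxp is not None:
                x._accumulate(gxp[:, :, :, pad:pad + T] if pad else gxp)
    out._backward = bw
    return out


def logsumexp_rows(S: Tensor, mask: np.ndarray) -> Tensor:
    """Row-wise log-sum-exp of ``S`` restricted to ``mask`` (boolean, same
    shape), numerically stabilized by the (detached) row max."""
    mask_f = Tensor(mask.astype(float))
    m = np.max(np.where(mask, S.data, -np.inf), axis=1, keepdims=True)
    # zero the shift of excluded entries *before* exponentiating, so an
    # excluded entry larger than the masked max cannot overflow
    shifted = ((S - Tensor(m)) * mask_f).exp() * mask_f
    return shifted.sum(axis=1, keepdims=True).log() + Tensor(m)


class Adam:
    """Adam optimizer with per-parameter-group learning rates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple = (0.9, 0.999), eps: float = 1e-8,
                 lrs: list[float] | None = None):
        self.params = list(params)
        self.lrs = list(lrs) if lrs is not None else [lr] * len(self.params)
        if len(self.lrs) != len(self.params):
            raise ValueError("one learning rate per parameter required")
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lrs[i] * mhat / (np.sqrt(vhat) + self.eps)
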