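"""A small reverse-mode automatic differentiation engine over numpy arrays.

Supports exactly the operations the priors need: broadcasted arithmetic,
elementwise nonlinearities, reductions, log-sum-exp/log-softmax, slicing,
2-D convolution (im2col) and per-sample index selection. Gradients are
accumulated by a tape-based topological backward pass.

Kept deliberately minimal — this is infrastructure for the generative
priors, not a general ML framework.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "conv2d", "logsumexp", "log_softmax", "where", "index_select", "concat", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcasted gradient back to ``shape``."""
    if grad.shape == shape:
        return grad
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- graph construction helper -------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data, requires_grad=any(p.requires_grad for p in parents))
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x))

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        if isinstance(other, (int, float)):
            # python-scalar fast path: no dtype promotion, no extra node
            return self._make(self.data + other, (self,), lambda g: (g,))
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        if isinstance(other, (int, float)):
            return self + (-other)
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        if isinstance(other, (int, float)):
            return self._make(self.data * other, (self,), lambda g: (g * other,))
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / other.data**2, other.shape),
            )

        return self._make(out_data, (self, other), backward)

    def __pow__(self, p: float):
        out_data = self.data**p
        return self._make(out_data, (self,), lambda g: (g * p * self.data ** (p - 1),))

    # -- elementwise nonlinearities -------------------------------------
    def exp(self):
        out_data = np.exp(self.data)
        return self._make(out_data, (self,), lambda g: (g * out_data,))

    def log(self):
        return self._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def tanh(self):
        out_data = np.tanh(self.data)
        return self._make(out_data, (self,), lambda g: (g * (1 - out_data**2),))

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * out_data * (1 - out_data),))

    def softplus(self):
        # numerically stable log(1 + exp(x))
        out_data = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))
        sig = 1.0 / (1.0 + np.exp(-self.data))
        return self._make(out_data, (self,), lambda g: (g * sig,))

    def elu(self, alpha: float = 1.0):
        pos = self.data > 0
        out_data = np.where(pos, self.data, alpha * np.expm1(np.minimum(self.data, 0)))

        def backward(g):
            return (np.where(pos, g, g * (out_data + alpha)),)

        return self._make(out_data, (self,), backward)

    # -- reductions ------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            axes = (axis,) if np.isscalar(axis) else tuple(axis)
            if not keepdims:
                for ax in sorted(ax % self.data.ndim for ax in axes):
                    g = np.expand_dims(g, ax)
            return (np.broadcast_to(g, self.shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        count = self.data.size if axis is None else np.prod(
            [self.data.shape[ax] for ax in ((axis,) if np.isscalar(axis) else axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / count)

    # -- shape ops -------------------------------------------------------
    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)
        return self._make(out_data, (self,), lambda g: (g.reshape(self.shape),))

    def transpose(self, *axes):
        inv = np.argsort(axes)
        return self._make(
            self.data.transpose(axes), (self,), lambda g: (g.transpose(inv),)
        )

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return self._make(out_data, (self,), backward)

    # -- backward pass ---------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
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
        grads = {id(self): np.asarray(grad, dtype=self.data.dtype)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.grad is None:
                node.grad = g.copy()
            else:
                node.grad = node.grad + g
            if node._backward is None:
                continue
            parent_grads = node._backward(g)
            for p, pg in zip(node._parents, parent_grads):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    def zero_grad(self):
        self.grad = None


# -- free functions ------------------------------------------------------

def where(cond: np.ndarray, a: Tensor, b: Tensor) -> Tensor:
    """Elementwise select; ``cond`` is a constant boolean array."""
    a, b = Tensor._wrap(a), Tensor._wrap(b)
    out_data = np.where(cond, a.data, b.data)

    def backward(g):
        return (
            _unbroadcast(np.where(cond, g, 0.0), a.shape),
            _unbroadcast(np.where(cond, 0.0, g), b.shape),
        )

    return Tensor._make(out_data, (a, b), backward)


def logsumexp(t: Tensor, axis: int, keepdims: bool = False) -> Tensor:
    m = t.data.max(axis=axis, keepdims=True)
    shifted = t - Tensor(m)
    out = shifted.exp().sum(axis=axis, keepdims=True).log() + Tensor(m)
    if not keepdims:
        out = out.reshape(*np.squeeze(out.data, axis=axis).shape)
    return out


def log_softmax(t: Tensor, axis: int) -> Tensor:
    return t - logsumexp(t, axis=axis, keepdims=True)


def index_select(t: Tensor, idx: np.ndarray) -> Tensor:
    """Select rows t[idx] along axis 0 (gather with scatter-add backward)."""
    idx = np.asarray(idx)
    out_data = t.data[idx]

    def backward(g):
        full = np.zeros_like(t.data)
        np.add.at(full, idx, g)
        return (full,)

    return Tensor._make(out_data, (t,), backward)


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, constant zero padding.

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw); b: (Cout,) or None.
    Output: (B, Cout, H + 2 pad - kh + 1, W + 2 pad - kw + 1).
    """
    B, Cin, H, W = x.shape
    Cout, Cin2, kh, kw = w.shape
    assert Cin == Cin2, "channel mismatch"
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    patches = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # patches: (B, Cin, Ho, Wo, kh, kw)
    out_data = np.tensordot(patches, w.data, axes=([1, 4, 5], [1, 2, 3]))
    # -> (B, Ho, Wo, Cout) -> (B, Cout, Ho, Wo)
    out_data = np.ascontiguousarray(out_data.transpose(0, 3, 1, 2))
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]

    Ho, Wo = out_data.shape[2], out_data.shape[3]

    def backward(g):
        # g: (B, Cout, Ho, Wo)
        gw = np.tensordot(g, patches, axes=([0, 2, 3], [0, 2, 3]))
        # -> (Cout, Cin, kh, kw)
        gxp = np.zeros_like(xp)
        for u in range(kh):
            for v in range(kw):
                # contribution of kernel tap (u, v)
                gxp[:, :, u : u + Ho, v : v + Wo] += np.tensordot(
                    g, w.data[:, :, u, v], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        gx = gxp[:, :, pad : pad + H, pad : pad + W] if pad else gxp
        grads = [gx, gw]
        if b is not None:
            grads.append(g.sum(axis=(0, 2, 3)))
        return tuple(grads)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor._make(out_data, parents, backward)


class Adam:
    """Adaptive-moment optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for k, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
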