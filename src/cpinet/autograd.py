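"""Reverse-mode automatic differentiation on numpy arrays.

A deliberately small tape-based engine: every :class:`Tensor` wraps an
``ndarray`` and remembers the closure that propagates its output gradient to
its parents.  It implements exactly the operations the interaction network
needs — dense/batched matrix products, valid cross-correlation in 1-D and
3-D (via im2col), max pooling, embedding lookup, LeakyReLU, sigmoid and the
usual reductions — and an Adam optimiser.

Gradients are accumulated in float64.  All ops support broadcasting on the
forward pass; ``_unbroadcast`` folds gradients back onto parameter shapes.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam", "concat", "stack"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to produce it."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """An ndarray plus an optional gradient tape node."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
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
        return self * other ** -1.0

    def __pow__(self, exponent: float):
        out_data = self.data ** exponent

        def backward(g):
            return (g * exponent * self.data ** (exponent - 1.0),)

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            a, b = self.data, other.data
            if b.ndim == 1:
                ga = np.outer(g, b) if a.ndim == 2 else g[..., None] * b
                gb = a.T @ g if a.ndim == 2 else (a * g[..., None]).sum(
                    axis=tuple(range(a.ndim - 1))
                )
            elif a.ndim == 1:
                ga = g @ b.swapaxes(-1, -2)
                gb = np.outer(a, g)
            else:
                ga = g @ b.swapaxes(-1, -2)
                gb = a.swapaxes(-1, -2) @ g
            return (_unbroadcast(ga, self.shape), _unbroadcast(gb, other.shape))

        return self._make(out_data, (self, other), backward)

    def __rmatmul__(self, other):
        return self._wrap(other) @ self

    # -- shape ops ---------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        in_shape = self.shape

        def backward(g):
            return (g.reshape(in_shape),)

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        out_data = self.data.transpose(axes) if axes else self.data.T
        inv = np.argsort(axes) if axes else None

        def backward(g):
            return (g.transpose(inv) if axes else g.T,)

        return self._make(out_data, (self,), backward)

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)
        in_shape = self.shape

        def backward(g):
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, in_shape).copy(),)

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis: int):
        """Maximum along one axis; gradient flows to the (first) argmax."""
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis).squeeze(axis)
        in_shape = self.shape

        def backward(g):
            gx = np.zeros(in_shape)
            np.put_along_axis(
                gx, np.expand_dims(idx, axis), np.expand_dims(g, axis), axis
            )
            return (gx,)

        return self._make(out_data, (self,), backward)

    # -- nonlinearities ----------------------------------------------------
    def leaky_relu(self, negative_slope: float = 0.01):
        mask = self.data >= 0
        out_data = np.where(mask, self.data, negative_slope * self.data)

        def backward(g):
            return (np.where(mask, g, negative_slope * g),)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            return (g * out_data * (1.0 - out_data),)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            return (g / self.data,)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = (self.data > lo) & (self.data < hi)

        def backward(g):
            return (np.where(mask, g, 0.0),)

        return self._make(out_data, (self,), backward)

    # -- gather ------------------------------------------------------------
    def take_rows(self, indices: np.ndarray):
        """Row lookup ``self[indices]`` (embedding); gradient scatter-adds."""
        indices = np.asarray(indices)
        out_data = self.data[indices]
        in_shape = self.shape

        def backward(g):
            gt = np.zeros(in_shape)
            np.add.at(gt, indices, g)
            return (gt,)

        return self._make(out_data, (self,), backward)

    # -- convolution (valid cross-correlation, via im2col) ------------------
    def conv1d(self, weight: "Tensor", bias: "Tensor"):
        """Input (B, C, L), weight (F, C, K), bias (F,) -> (B, F, L-K+1)."""
        x, w = self.data, weight.data
        B, C, L = x.shape
        F, _, K = w.shape
        if L < K:
            raise ValueError(f"input length {L} shorter than kernel {K}")
        cols = np.lib.stride_tricks.sliding_window_view(x, K, axis=2)  # B,C,Lo,K
        Lo = cols.shape[2]
        cols2 = cols.transpose(0, 2, 1, 3).reshape(B, Lo, C * K)
        out_data = cols2 @ w.reshape(F, C * K).T + bias.data
        out_data = out_data.transpose(0, 2, 1)  # B,F,Lo

        def backward(g):
            gf = g.transpose(0, 2, 1)  # B,Lo,F
            gw = np.einsum("blf,blk->fk", gf, cols2).reshape(F, C, K)
            gb = gf.sum(axis=(0, 1))
            gcols = (gf @ w.reshape(F, C * K)).reshape(B, Lo, C, K)
            gx = np.zeros_like(x)
            for k in range(K):
                gx[:, :, k : k + Lo] += gcols[:, :, :, k].transpose(0, 2, 1)
            return (gx, gw, gb)

        return self._make(out_data, (self, weight, bias), backward)

    def conv3d(self, weight: "Tensor", bias: "Tensor"):
        """Input (B, C, D, H, W), weight (F, C, P, Q, R), bias (F,)."""
        x, w = self.data, weight.data
        B, C, D, H, W = x.shape
        F, _, P, Q, R = w.shape
        if D < P or H < Q or W < R:
            raise ValueError(f"kernel {(P, Q, R)} larger than input {(D, H, W)}")
        swv = np.lib.stride_tricks.sliding_window_view(x, (P, Q, R), axis=(2, 3, 4))
        Do, Ho, Wo = swv.shape[2:5]
        cols = swv.reshape(B, C, Do * Ho * Wo, P * Q * R)
        cols = cols.transpose(0, 2, 1, 3).reshape(B, Do * Ho * Wo, C * P * Q * R)
        out_data = cols @ w.reshape(F, -1).T + bias.data  # B,n,F
        out_data = out_data.transpose(0, 2, 1).reshape(B, F, Do, Ho, Wo)

        def backward(g):
            gf = g.reshape(B, F, -1).transpose(0, 2, 1)  # B,n,F
            gw = np.einsum("bnf,bnk->fk", gf, cols).reshape(F, C, P, Q, R)
            gb = gf.sum(axis=(0, 1))
            gcols = (gf @ w.reshape(F, -1)).reshape(B, Do, Ho, Wo, C, P, Q, R)
            gx = np.zeros_like(x)
            for p in range(P):
                for q in range(Q):
                    for r in range(R):
                        gx[:, :, p : p + Do, q : q + Ho, r : r + Wo] += gcols[
                            :, :, :, :, :, p, q, r
                        ].transpose(0, 4, 1, 2, 3)
            return (gx, gw, gb)

        return self._make(out_data, (self, weight, bias), backward)

    # -- pooling -----------------------------------------------------------
    def max_pool1d(self, width: int):
        """Non-overlapping max pool over the last axis of (B, C, L)."""
        x = self.data
        B, C, L = x.shape
        Lo = L // width
        xt = x[:, :, : Lo * width].reshape(B, C, Lo, width)
        idx = np.argmax(xt, axis=3)
        out_data = np.take_along_axis(xt, idx[..., None], axis=3).squeeze(3)

        def backward(g):
            gx = np.zeros_like(x)
            gxt = gx[:, :, : Lo * width].reshape(B, C, Lo, width)
            np.put_along_axis(gxt, idx[..., None], g[..., None], axis=3)
            return (gx,)

        return self._make(out_data, (self,), backward)

    def max_pool3d(self, width: int):
        """Non-overlapping cubic max pool on (B, C, D, H, W)."""
        x = self.data
        B, C, D, H, W = x.shape
        d, h, w_ = D // width, H // width, W // width
        xt = x[:, :, : d * width, : h * width, : w_ * width]
        xt = xt.reshape(B, C, d, width, h, width, w_, width)
        xt = xt.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(B, C, d, h, w_, width ** 3)
        idx = np.argmax(xt, axis=5)
        out_data = np.take_along_axis(xt, idx[..., None], axis=5).squeeze(5)

        def backward(g):
            gxt = np.zeros((B, C, d, h, w_, width ** 3))
            np.put_along_axis(gxt, idx[..., None], g[..., None], axis=5)
            gxt = gxt.reshape(B, C, d, h, w_, width, width, width)
            gxt = gxt.transpose(0, 1, 2, 5, 3, 6, 4, 7)
            gx = np.zeros_like(x)
            gx[:, :, : d * width, : h * width, : w_ * width] = gxt.reshape(
                B, C, d * width, h * width, w_ * width
            )
            return (gx,)

        return self._make(out_data, (self,), backward)

    def avg_pool3d(self, width: int):
        """Non-overlapping cubic average pool on (B, C, D, H, W)."""
        x = self.data
        B, C, D, H, W = x.shape
        d, h, w_ = D // width, H // width, W // width
        xt = x[:, :, : d * width, : h * width, : w_ * width].reshape(
            B, C, d, width, h, width, w_, width
        )
        out_data = xt.mean(axis=(3, 5, 7))
        scale = 1.0 / width ** 3

        def backward(g):
            gx = np.zeros_like(x)
            gview = gx[:, :, : d * width, : h * width, : w_ * width].reshape(
                B, C, d, width, h, width, w_, width
            )
            gview += g[:, :, :, None, :, None, :, None] * scale
            gx[:, :, : d * width, : h * width, : w_ * width] = gview.reshape(
                B, C, d * width, h * width, w_ * width
            )
            return (gx,)

        return self._make(out_data, (self,), backward)

    # -- backprop ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar output")
            grad = np.ones_like(self.data)

        topo: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is not None:
                for parent, pg in zip(t._parents, t._backward(g)):
                    if not parent.requires_grad:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg
            else:  # leaf
                t.grad = g if t.grad is None else t.grad + g
        # the root may itself be a leaf
        if self._backward is None and self.requires_grad and self.grad is None:
            self.grad = np.asarray(grad, dtype=np.float64)


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate tensors along ``axis`` with gradient splitting."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)

        def backward(g):
            return tuple(np.split(g, splits, axis=axis))

        out._backward = backward
    return out


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Stack equal-shaped tensors along a new axis."""
    expanded = [t.reshape(*t.shape[:axis], 1, *t.shape[axis:]) for t in tensors]
    return concat(expanded, axis=axis)


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: list[Tensor], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = [p for p in params if p.requires_grad]
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
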