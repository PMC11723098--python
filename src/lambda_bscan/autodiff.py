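"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical substrate for the SD-CNN / FD-CNN models: a small
tape-based autodiff engine plus the handful of layers the encoder–decoder
architecture needs (strided conv, stride-2 transpose conv, batch norm,
PReLU, sigmoid/softplus gates, channel concatenation) and an Adam
optimizer.  Convolutions are im2col + BLAS matmul; gradients of every op
are checked against central finite differences in the test suite.

Arrays follow the channels-first convention: 2D data is ``(B, C, H, W)``,
1D data is ``(B, C, L)``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor", "Parameter", "Module", "Adam",
    "add", "sub", "mul", "concat", "relu", "sigmoid", "softplus",
    "mean_abs", "mean_abs_cubed",
    "Conv2d", "Conv1d", "ConvTranspose2d", "ConvTranspose1d",
    "BatchNorm", "PReLU",
]


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        for t in topo:
            t.grad = None
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise / structural ops


def add(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data + b.data, parents=(a, b))

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(g, b.shape))

    out._backward = backward
    return out


def sub(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data - b.data, parents=(a, b))

    def backward(g):
        a._accum(_unbroadcast(g, a.shape))
        b._accum(_unbroadcast(-g, b.shape))

    out._backward = backward
    return out


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = Tensor(a.data * b.data, parents=(a, b))

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.shape))
        b._accum(_unbroadcast(g * a.data, b.shape))

    out._backward = backward
    return out


def concat(tensors, axis=1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis),
                 parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    out._backward = backward
    return out


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = Tensor(x.data * mask, parents=(x,))
    out._backward = lambda g: x._accum(g * mask)
    return out


def sigmoid(x: Tensor) -> Tensor:
    # overflow-safe: exp of a non-positive argument only
    e = np.exp(-np.abs(x.data))
    y = np.where(x.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x._accum(g * y * (1.0 - y))
    return out


def softplus(x: Tensor) -> Tensor:
    # numerically stable: log(1+e^x) = max(x,0) + log1p(e^{-|x|})
    e = np.exp(-np.abs(x.data))
    y = np.maximum(x.data, 0.0) + np.log1p(e)
    sig = np.where(x.data >= 0, 1.0 / (1.0 + e), e / (1.0 + e))
    out = Tensor(y, parents=(x,))
    out._backward = lambda g: x._accum(g * sig)
    return out


def mean_abs(a: Tensor, b: Tensor) -> Tensor:
    """Mean absolute error, differentiable (the L1 training loss)."""
    d = a.data - b.data
    out = Tensor(np.mean(np.abs(d)), parents=(a, b))

    def backward(g):
        gd = g * np.sign(d) / d.size
        a._accum(_unbroadcast(gd, a.shape))
        b._accum(_unbroadcast(-gd, b.shape))

    out._backward = backward
    return out


def mean_abs_cubed(a: Tensor, b: Tensor) -> Tensor:
    """Mean |a-b|^3: the focal frequency loss with focusing exponent 1."""
    d = a.data - b.data
    out = Tensor(np.mean(np.abs(d) ** 3), parents=(a, b))

    def backward(g):
        gd = g * 3.0 * d * np.abs(d) / d.size
        a._accum(_unbroadcast(gd, a.shape))
        b._accum(_unbroadcast(-gd, b.shape))

    out._backward = backward
    return out


# ---------------------------------------------------------------------------
# modules


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def parameters(self):
        params = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self):
        for m in self.modules():
            m.training = True

    def eval(self):
        for m in self.modules():
            m.training = False

    def state_dict(self):
        return {i: p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict size mismatch")
        for i, p in enumerate(params):
            p.data[...] = state[i]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """3x3 (or kxk) convolution, 'same' padding, optional stride."""

    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.pad = k // 2
        self.weight = Parameter(_kaiming(rng, (cout, cin, k, k), cin * k * k))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.k, self.stride, self.pad
        B, C, H, W = x.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        Ho, Wo = win.shape[2], win.shape[3]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B, Ho, Wo, C * k * k)
        Wmat = self.weight.data.reshape(self.cout, -1)
        y = cols @ Wmat.T + self.bias.data
        out = Tensor(y.transpose(0, 3, 1, 2), parents=(x, self.weight, self.bias))

        def backward(g):
            gt = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # B,Ho,Wo,cout
            self.bias._accum(gt.sum(axis=(0, 1, 2)))
            gt2 = gt.reshape(-1, self.cout)
            cols2 = cols.reshape(-1, C * k * k)
            self.weight._accum((gt2.T @ cols2).reshape(self.weight.data.shape))
            dcols = (gt2 @ Wmat).reshape(B, Ho, Wo, C, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i:i + Ho * s:s, j:j + Wo * s:s] += dcols[..., i, j]
            x._accum(dxp[:, :, p:p + H, p:p + W])

        out._backward = backward
        return out


class Conv1d(Module):
    """k-tap 1D convolution along the last axis, 'same' padding."""

    def __init__(self, cin, cout, k=3, stride=1, rng=None):
        rng = rng or np.random.default_rng(0)
        self.k, self.stride, self.cin, self.cout = k, stride, cin, cout
        self.pad = k // 2
        self.weight = Parameter(_kaiming(rng, (cout, cin, k), cin * k))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        k, s, p = self.k, self.stride, self.pad
        B, C, L = x.data.shape
        xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
        win = sliding_window_view(xp, k, axis=2)[:, :, ::s]
        Lo = win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, Lo, C * k)
        Wmat = self.weight.data.reshape(self.cout, -1)
        y = cols @ Wmat.T + self.bias.data
        out = Tensor(y.transpose(0, 2, 1), parents=(x, self.weight, self.bias))

        def backward(g):
            gt = np.ascontiguousarray(g.transpose(0, 2, 1))    # B,Lo,cout
            self.bias._accum(gt.sum(axis=(0, 1)))
            gt2 = gt.reshape(-1, self.cout)
            cols2 = cols.reshape(-1, C * k)
            self.weight._accum((gt2.T @ cols2).reshape(self.weight.data.shape))
            dcols = (gt2 @ Wmat).reshape(B, Lo, C, k).transpose(0, 2, 1, 3)
            dxp = np.zeros_like(xp)
            for i in range(k):
                dxp[:, :, i:i + Lo * s:s] += dcols[..., i]
            x._accum(dxp[:, :, p:p + L])

        out._backward = backward
        return out


class ConvTranspose2d(Module):
    """Kernel-2 stride-2 transpose conv: exactly doubles H and W."""

    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.weight = Parameter(_kaiming(rng, (cin, cout, 2, 2), cin))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.data.shape
        y = np.einsum("ncij,coab->noiajb", x.data, self.weight.data, optimize=True)
        y = y.reshape(B, self.cout, 2 * H, 2 * W) + self.bias.data[None, :, None, None]
        out = Tensor(y, parents=(x, self.weight, self.bias))

        def backward(g):
            g6 = g.reshape(B, self.cout, H, 2, W, 2)
            self.bias._accum(g.sum(axis=(0, 2, 3)))
            self.weight._accum(
                np.einsum("ncij,noiajb->coab", x.data, g6, optimize=True))
            x._accum(np.einsum("noiajb,coab->ncij", g6, self.weight.data,
                               optimize=True))

        out._backward = backward
        return out


class ConvTranspose1d(Module):
    """Kernel-2 stride-2 transpose conv along the last axis."""

    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.cin, self.cout = cin, cout
        self.weight = Parameter(_kaiming(rng, (cin, cout, 2), cin))
        self.bias = Parameter(np.zeros(cout))

    def forward(self, x: Tensor) -> Tensor:
        B, C, L = x.data.shape
        y = np.einsum("ncl,coa->nola", x.data, self.weight.data, optimize=True)
        y = y.reshape(B, self.cout, 2 * L) + self.bias.data[None, :, None]
        out = Tensor(y, parents=(x, self.weight, self.bias))

        def backward(g):
            g4 = g.reshape(B, self.cout, L, 2)
            self.bias._accum(g.sum(axis=(0, 2)))
            self.weight._accum(np.einsum("ncl,nola->coa", x.data, g4, optimize=True))
            x._accum(np.einsum("nola,coa->ncl", g4, self.weight.data, optimize=True))

        out._backward = backward
        return out


class BatchNorm(Module):
    """Batch normalization over (B, spatial...) per channel, 1D or 2D data."""

    def __init__(self, nc, momentum=0.1, eps=1e-5):
        self.nc, self.momentum, self.eps = nc, momentum, eps
        self.gamma = Parameter(np.ones(nc))
        self.beta = Parameter(np.zeros(nc))
        self.running_mean = np.zeros(nc)
        self.running_var = np.ones(nc)
        self.training = True

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.data.ndim))
        cshape = (1, self.nc) + (1,) * (x.data.ndim - 2)
        if self.training:
            mean = x.data.mean(axis=axes)
            var = x.data.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean.reshape(cshape)) * inv.reshape(cshape)
        y = self.gamma.data.reshape(cshape) * xhat + self.beta.data.reshape(cshape)
        out = Tensor(y, parents=(x, self.gamma, self.beta))
        m = x.data.size // self.nc
        training = self.training

        def backward(g):
            self.beta._accum(g.sum(axis=axes))
            self.gamma._accum((g * xhat).sum(axis=axes))
            gx = g * self.gamma.data.reshape(cshape)
            if training:
                # full batch-stats gradient
                dxhat = gx
                dvar_term = (dxhat * xhat).sum(axis=axes, keepdims=True)
                dmean_term = dxhat.sum(axis=axes, keepdims=True)
                x._accum(inv.reshape(cshape) * (
                    dxhat - dmean_term / m - xhat * dvar_term / m))
            else:
                x._accum(gx * inv.reshape(cshape))

        out._backward = backward
        return out


class PReLU(Module):
    """Per-channel parametric ReLU with learnable negative slope."""

    def __init__(self, nc, init=0.25):
        self.nc = nc
        self.alpha = Parameter(np.full(nc, init))

    def forward(self, x: Tensor) -> Tensor:
        cshape = (1, self.nc) + (1,) * (x.data.ndim - 2)
        pos = x.data > 0
        a = self.alpha.data.reshape(cshape)
        out = Tensor(np.where(pos, x.data, a * x.data),
                     parents=(x, self.alpha))
        axes = (0,) + tuple(range(2, x.data.ndim))

        def backward(g):
            x._accum(g * np.where(pos, 1.0, a))
            self.alpha._accum((g * np.where(pos, 0.0, x.data)).sum(axis=axes))

        out._backward = backward
        return out


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad ** 2
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
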