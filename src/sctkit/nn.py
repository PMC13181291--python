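"""Minimal reverse-mode autodiff on numpy arrays, with the 2D layers the
translation networks need: strided convolution, instance normalisation,
nearest-neighbour upsampling, and the usual activations.

Design notes: tensors carry float32 data; gradients are accumulated into
``Tensor.grad`` by backward closures recorded at op time; ``backward()``
walks the tape in reverse topological order.  Everything is deterministic
— initialisation and data order are the only sources of randomness and
both are caller-seeded.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_bw")

    def __init__(self, data, parents=(), bw=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self._parents = parents
        self._bw = bw

    @property
    def shape(self):
        return self.data.shape

    def _accum(self, g):
        self.grad = g if self.grad is None else self.grad + g

    def backward(self):
        if self.data.shape != ():
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
        self.grad = np.ones((), dtype=np.float32)
        for t in reversed(topo):
            if t._bw is not None and t.grad is not None:
                t._bw(t.grad)

    # -- elementwise arithmetic -------------------------------------------
    def __add__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        return Tensor(self.data + other.data, (self, other), bw)

    def __sub__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(-g, other.data.shape))

        return Tensor(self.data - other.data, (self, other), bw)

    def __mul__(self, other):
        other = _wrap(other)

        def bw(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor(self.data * other.data, (self, other), bw)

    __radd__ = __add__
    __rmul__ = __mul__


def _wrap(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _unbroadcast(g, shape):
    """Reduce a broadcast gradient back to the original operand shape."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# -- activations -----------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def bw(g):
        x._accum(g * mask)

    return Tensor(x.data * mask, (x,), bw)


def leaky_relu(x: Tensor, slope: float = 0.2) -> Tensor:
    factor = np.where(x.data > 0, np.float32(1.0), np.float32(slope))

    def bw(g):
        x._accum(g * factor)

    return Tensor(x.data * factor, (x,), bw)


def hard_tanh(x: Tensor) -> Tensor:
    """Saturating clip to [-1, 1]; unit gradient inside, zero outside."""
    mask = (np.abs(x.data) <= 1.0).astype(np.float32)

    def bw(g):
        x._accum(g * mask)

    return Tensor(np.clip(x.data, -1.0, 1.0), (x,), bw)


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)

    def bw(g):
        x._accum(g * (1.0 - out * out))

    return Tensor(out, (x,), bw)


# -- structural ops --------------------------------------------------------

def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    na = a.data.shape[axis]

    def bw(g):
        ga, gb = np.split(g, [na], axis=axis)
        a._accum(ga)
        b._accum(gb)

    return Tensor(np.concatenate([a.data, b.data], axis=axis), (a, b), bw)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling of (N, C, H, W)."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def bw(g):
        n, c, h2, w2 = g.shape
        x._accum(g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return Tensor(out, (x,), bw)


def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1, pad: int = 0) -> Tensor:
    """2D convolution (cross-correlation) of (N,C,H,W) with (O,C,k,k)."""
    n, c, h, wd = x.data.shape
    o, c2, k, _ = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    hp, wp = xp.shape[2], xp.shape[3]
    if hp < k or wp < k:
        raise ValueError(f"input {hp}x{wp} smaller than kernel {k}x{k}")
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.einsum("nchwkl,ockl->nohw", win, w.data, optimize=True) + \
        b.data[None, :, None, None]
    ho, wo = out.shape[2], out.shape[3]

    def bw(g):
        w._accum(np.einsum("nchwkl,nohw->ockl", win, g, optimize=True))
        b._accum(g.sum(axis=(0, 2, 3)))
        dxp = np.zeros_like(xp)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += \
                    np.einsum("nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True)
        x._accum(dxp[:, :, pad:pad + h, pad:pad + wd] if pad else dxp)

    return Tensor(out, (x, w, b), bw)


def instance_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalisation over the spatial axes."""
    mu = x.data.mean(axis=(2, 3), keepdims=True)
    var = x.data.var(axis=(2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = gain.data[None, :, None, None] * xhat + bias.data[None, :, None, None]

    def bw(g):
        gain._accum((g * xhat).sum(axis=(0, 2, 3)))
        bias._accum(g.sum(axis=(0, 2, 3)))
        dxhat = g * gain.data[None, :, None, None]
        m1 = dxhat.mean(axis=(2, 3), keepdims=True)
        m2 = (dxhat * xhat).mean(axis=(2, 3), keepdims=True)
        x._accum(inv * (dxhat - m1 - xhat * m2))

    return Tensor(out, (x, gain, bias), bw)


# -- reductions for losses -------------------------------------------------

def mean_abs(a: Tensor, b: Tensor, weight: np.ndarray | None = None) -> Tensor:
    """mean(w * |a - b|); ``weight`` is a constant (no gradient flows
    through it), broadcastable to the input shape."""
    diff = a.data - b.data
    w = np.float32(1.0) if weight is None else weight.astype(np.float32)
    out = np.mean(w * np.abs(diff))
    n = diff.size

    def bw(g):
        grad = (g * w * np.sign(diff) / n) * np.ones_like(diff)
        a._accum(_unbroadcast(grad, a.data.shape))
        b._accum(_unbroadcast(-grad, b.data.shape))

    return Tensor(out, (a, b), bw)


def mean_square_diff(a: Tensor, target: float) -> Tensor:
    """mean((a - target)^2) against a constant target."""
    diff = a.data - np.float32(target)
    out = np.mean(diff * diff)
    n = diff.size

    def bw(g):
        a._accum(g * 2.0 * diff / n)

    return Tensor(out, (a,), bw)


# -- layers ----------------------------------------------------------------

class Module:
    """Base class: parameters are any Tensor attributes of self or of
    Module attributes (recursively), in attribute order."""

    def parameters(self) -> list[Tensor]:
        params = []
        for v in vars(self).values():
            if isinstance(v, Tensor):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Tensor):
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError("state does not match architecture")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError("state does not match architecture")
            p.data = np.asarray(a, dtype=np.float32)


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 pad: int = 0, rng: np.random.Generator | None = None,
                 init_std: float = 0.02):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(rng.normal(0.0, init_std, size=(c_out, c_in, k, k)))
        self.b = Tensor(np.zeros(c_out))
        self.stride, self.pad = stride, pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, self.stride, self.pad)


class InstanceNorm2d(Module):
    def __init__(self, c: int, eps: float = 1e-5):
        self.gain = Tensor(np.ones(c))
        self.bias = Tensor(np.zeros(c))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return instance_norm(x, self.gain, self.bias, self.eps)


class Adam:
    """Adam with the GAN-conventional beta1 = 0.5."""

    def __init__(self, params: list[Tensor], lr: float = 2e-4,
                 beta1: float = 0.5, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad.astype(np.float32)
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            p.data = p.data - self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)
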