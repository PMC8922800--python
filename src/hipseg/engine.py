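"""Minimal reverse-mode automatic differentiation engine for 2D convolutional networks.

The networks in this package are small (desk-scale slices, a few dozen channels), so
they run comfortably on a CPU with vectorised numpy.  This module provides the only
primitives they need: tensors with backpropagation, 2D convolution via im2col,
stride-2 transposed convolution, 2x2 max pooling, dense layers, channel
concatenation, sigmoid/ReLU, the segmentation losses, and an Adam optimiser.

Layout convention: activations are ``(N, C, H, W)`` float32 arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "Module",
    "Conv2d",
    "ConvTranspose2d",
    "Linear",
    "Adam",
    "relu",
    "sigmoid",
    "maxpool2x2",
    "concat_channels",
    "global_avg_pool",
    "flatten",
    "bce_loss",
    "soft_dice_loss",
]

_EPS = 1e-6


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "_backward", "_prev", "requires_grad")

    def __init__(self, data, requires_grad=False, _prev=()):
        self.data = np.asarray(data)
        self.grad = None
        self._backward = None
        self._prev = _prev
        self.requires_grad = requires_grad or any(p.requires_grad for p in _prev)

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Backpropagate from this (scalar) tensor through the graph."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.requires_grad:
                t._backward()
            if t._prev:
                t.grad = None  # free interior gradients; leaves keep theirs

    # -- elementary arithmetic (only what the losses need) ------------------

    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other))
        out = Tensor(self.data + other.data, _prev=(self, other))

        def back():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = back
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other))
        out = Tensor(self.data * other.data, _prev=(self, other))

        def back():
            if self.requires_grad:
                self._accumulate(_unbroadcast(out.grad * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(out.grad * self.data, other.data.shape))

        out._backward = back
        return out

    __radd__ = __add__
    __rmul__ = __mul__

    def sum(self):
        out = Tensor(self.data.sum(keepdims=False), _prev=(self,))

        def back():
            if self.requires_grad:
                self._accumulate(np.broadcast_to(out.grad, self.data.shape))

        out._backward = back
        return out

    def mean(self):
        n = self.data.size
        out = Tensor(self.data.mean(), _prev=(self,))

        def back():
            if self.requires_grad:
                self._accumulate(np.broadcast_to(out.grad / n, self.data.shape))

        out._backward = back
        return out


def _unbroadcast(grad, shape):
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# activations and structural ops
# ---------------------------------------------------------------------------

def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), _prev=(x,))

    def back():
        if x.requires_grad:
            x._accumulate(out.grad * (x.data > 0))

    out._backward = back
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60, 60)))
    out = Tensor(s, _prev=(x,))

    def back():
        if x.requires_grad:
            x._accumulate(out.grad * s * (1.0 - s))

    out._backward = back
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {(h, w)}")
    win = x.data.reshape(n, c, h // 2, 2, w // 2, 2)
    out_data = win.max(axis=(3, 5))
    out = Tensor(out_data, _prev=(x,))

    def back():
        if x.requires_grad:
            mask = win == out_data[:, :, :, None, :, None]
            g = mask * out.grad[:, :, :, None, :, None]
            x._accumulate(g.reshape(n, c, h, w))

    out._backward = back
    return out


def concat_channels(tensors) -> Tensor:
    tensors = list(tensors)
    if len(tensors) == 1:
        return tensors[0]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=1), _prev=tuple(tensors))
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def back():
        parts = np.split(out.grad, splits, axis=1)
        for t, g in zip(tensors, parts):
            if t.requires_grad:
                t._accumulate(g)

    out._backward = back
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), _prev=(x,))

    def back():
        if x.requires_grad:
            x._accumulate(
                np.broadcast_to(out.grad[:, :, None, None] / (h * w), x.data.shape)
            )

    out._backward = back
    return out


def flatten(x: Tensor) -> Tensor:
    n = x.data.shape[0]
    out = Tensor(x.data.reshape(n, -1), _prev=(x,))

    def back():
        if x.requires_grad:
            x._accumulate(out.grad.reshape(x.data.shape))

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def bce_loss(pred: Tensor, target: np.ndarray, pos_weight: float = 1.0) -> Tensor:
    """Mean pixel-wise binary cross-entropy on probabilities.

    ``pos_weight`` scales the positive-class term to counter class imbalance.
    """
    t = np.asarray(target, dtype=pred.data.dtype)
    p = np.clip(pred.data, _EPS, 1.0 - _EPS)
    val = -(pos_weight * t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()
    out = Tensor(np.asarray(val, dtype=pred.data.dtype), _prev=(pred,))

    def back():
        if pred.requires_grad:
            g = (-(pos_weight * t / p) + (1.0 - t) / (1.0 - p)) / t.size
            pred._accumulate(g * out.grad)

    out._backward = back
    return out


def soft_dice_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """1 - soft Dice overlap between a probability map and a binary mask."""
    t = np.asarray(target, dtype=pred.data.dtype)
    p = pred.data
    num = 2.0 * (p * t).sum() + _EPS
    den = p.sum() + t.sum() + _EPS
    out = Tensor(np.asarray(1.0 - num / den, dtype=pred.data.dtype), _prev=(pred,))

    def back():
        if pred.requires_grad:
            g = -(2.0 * t * den - num) / den ** 2
            pred._accumulate(g * out.grad)

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class; discovers parameters and weighted layers by attribute traversal."""

    def parameters(self):
        return [p for lyr in self.weighted_layers() for p in lyr._params()]

    def weighted_layers(self):
        out = []

        def scan(obj):
            if isinstance(obj, (Conv2d, ConvTranspose2d, Linear)):
                out.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    scan(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    scan(v)
            elif isinstance(obj, dict):
                for v in obj.values():
                    scan(v)

        scan(self)
        return out

    def state_arrays(self):
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state has {len(arrays)} arrays, model has {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(p.data.dtype)


def _he_init(rng, fan_in, shape):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    """3x3 (same-padded) or 1x1 convolution, stride 1, via im2col."""

    def __init__(self, in_ch, out_ch, kernel, rng):
        if kernel not in (1, 3):
            raise ValueError("only 1x1 and 3x3 kernels are used here")
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, kernel
        self.weight = Tensor(
            _he_init(rng, in_ch * kernel * kernel, (out_ch, in_ch, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def _params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        k, o = self.kernel, self.out_ch
        pad = k // 2
        def im2col(data):
            xp = np.pad(data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else data
            win = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
            cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
                n * h * w, c * k * k
            )
            return xp, cols

        wf = self.weight.data.reshape(o, -1)
        _, cols = im2col(x.data)
        y = (cols @ wf.T + self.bias.data).reshape(n, h, w, o).transpose(0, 3, 1, 2)
        out = Tensor(np.ascontiguousarray(y), _prev=(x, self.weight, self.bias))
        del cols  # rebuilt in back(); retaining it across the graph costs memory

        def back():
            gy = out.grad.transpose(0, 2, 3, 1).reshape(n * h * w, o)
            xp, cols2 = im2col(x.data)
            if self.weight.requires_grad:
                self.weight._accumulate((gy.T @ cols2).reshape(self.weight.data.shape))
                self.bias._accumulate(gy.sum(axis=0))
            if x.requires_grad:
                gcols = (gy @ wf).reshape(n, h, w, c, k, k)
                gxp = np.zeros_like(xp)
                for i in range(k):
                    for j in range(k):
                        gxp[:, :, i : i + h, j : j + w] += gcols[:, :, :, :, i, j].transpose(
                            0, 3, 1, 2
                        )
                x._accumulate(gxp[:, :, pad : pad + h, pad : pad + w] if pad else gxp)

        out._backward = back
        return out


class ConvTranspose2d(Module):
    """2x2, stride-2 transposed convolution (doubles spatial size)."""

    def __init__(self, in_ch, out_ch, rng):
        self.in_ch, self.out_ch, self.kernel = in_ch, out_ch, 2
        self.weight = Tensor(
            _he_init(rng, in_ch, (in_ch, out_ch, 2, 2)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def _params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        o = self.out_ch
        y6 = np.einsum("nchw,coij->nohiwj", x.data, self.weight.data, optimize=True)
        y = y6.reshape(n, o, 2 * h, 2 * w) + self.bias.data[None, :, None, None]
        out = Tensor(y.astype(x.data.dtype, copy=False), _prev=(x, self.weight, self.bias))

        def back():
            gy6 = out.grad.reshape(n, o, h, 2, w, 2)
            if self.weight.requires_grad:
                self.weight._accumulate(
                    np.einsum("nchw,nohiwj->coij", x.data, gy6, optimize=True)
                )
                self.bias._accumulate(out.grad.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                x._accumulate(
                    np.einsum("nohiwj,coij->nchw", gy6, self.weight.data, optimize=True)
                )

        out._backward = back
        return out


class Linear(Module):
    def __init__(self, in_features, out_features, rng):
        self.in_features, self.out_features = in_features, out_features
        self.weight = Tensor(
            _he_init(rng, in_features, (in_features, out_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features, dtype=np.float32), requires_grad=True)

    def _params(self):
        return [self.weight, self.bias]

    def __call__(self, x: Tensor) -> Tensor:
        out = Tensor(x.data @ self.weight.data + self.bias.data,
                     _prev=(x, self.weight, self.bias))

        def back():
            if self.weight.requires_grad:
                self.weight._accumulate(x.data.T @ out.grad)
                self.bias._accumulate(out.grad.sum(axis=0))
            if x.requires_grad:
                x._accumulate(out.grad @ self.weight.data.T)

        out._backward = back
        return out


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
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
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
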