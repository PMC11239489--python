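"""Minimal reverse-mode autodiff on numpy arrays, with the 3D layers the
denoiser needs: same-padded 3x3x3 convolution, 2x average pooling, nearest
upsampling, instance normalization, SiLU, dropout, concatenation, and an
Adam optimizer with cosine learning-rate decay.

Scope is deliberately narrow: float32/float64 dense tensors, static graphs
built per forward pass, gradients accumulated into ``Tensor.grad``.  Every
operation's backward pass is exercised against central finite differences in
the test suite.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "avg_pool3d",
    "upsample_nearest3d",
    "instance_norm3d",
    "silu",
    "dropout",
    "concat",
    "add",
    "sub",
    "mul",
    "square",
    "tsum",
    "Adam",
]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False,
                 parents: tuple = (),
                 backward: Callable[[np.ndarray], None] | None = None):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents
        )
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Reverse-mode sweep from this tensor (scalar unless grad given)."""
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that requires no grad")
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
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("implicit backward needs a scalar")
            grad = np.ones_like(self.data)
        self._accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum gradient over axes that were broadcast in the forward pass."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data - b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(-g, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def bwd(g):
        if a.requires_grad:
            a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def square(a: Tensor) -> Tensor:
    def bwd(g):
        a._accumulate(2.0 * a.data * g)

    return Tensor(a.data**2, parents=(a,), backward=bwd)


def tsum(a: Tensor) -> Tensor:
    def bwd(g):
        a._accumulate(np.full_like(a.data, float(g)))

    return Tensor(np.asarray(a.data.sum()), parents=(a,), backward=bwd)


def silu(a: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-a.data))
    out_data = a.data * s

    def bwd(g):
        a._accumulate(g * s * (1.0 + a.data * (1.0 - s)))

    return Tensor(out_data, parents=(a,), backward=bwd)


def dropout(a: Tensor, rate: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    """Channel dropout (zeroes whole feature channels), inverted scaling."""
    if not train or rate <= 0.0:
        return a
    b, c = a.data.shape[:2]
    keep = (rng.random((b, c)) >= rate).astype(a.data.dtype) / (1.0 - rate)
    mask = keep.reshape(b, c, *([1] * (a.data.ndim - 2)))
    out_data = a.data * mask

    def bwd(g):
        a._accumulate(g * mask)

    return Tensor(out_data, parents=(a,), backward=bwd)


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    out_data = np.concatenate([a.data, b.data], axis=axis)
    na = a.data.shape[axis]

    def bwd(g):
        ga, gb = np.split(g, [na], axis=axis)
        if a.requires_grad:
            a._accumulate(ga)
        if b.requires_grad:
            b._accumulate(gb)

    return Tensor(out_data, parents=(a, b), backward=bwd)


# ---------------------------------------------------------------------------
# convolution


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    """Sliding 3D windows of a padded (B, C, D, H, W) array."""
    pad = k // 2
    xp = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3)
    w = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))
    return w  # (B, C, D, H, W, k, k, k)


def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 3D convolution (cross-correlation).

    ``x``: (B, Cin, D, H, W); ``weight``: (Cout, Cin, k, k, k); ``bias``:
    (Cout,).
    """
    k = weight.data.shape[-1]
    win = _windows(x.data, k)
    out_data = np.einsum("bidhwxyz,oixyz->bodhw", win, weight.data,
                         optimize=True)
    if bias is not None:
        out_data += bias.data.reshape(1, -1, 1, 1, 1)

    def bwd(g):
        if weight.requires_grad:
            gw = np.einsum("bodhw,bidhwxyz->oixyz", g, win, optimize=True)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            wf = weight.data[:, :, ::-1, ::-1, ::-1]
            gwin = _windows(g, k)
            gx = np.einsum("bodhwxyz,oixyz->bidhw", gwin, wf, optimize=True)
            x._accumulate(gx)

    parents = (x, weight) if bias is None else (x, weight, bias)
    return Tensor(out_data, parents=parents, backward=bwd)


def avg_pool3d(x: Tensor) -> Tensor:
    """2x2x2 average pooling (spatial dims must be even)."""
    b, c, d, h, w = x.data.shape
    r = x.data.reshape(b, c, d // 2, 2, h // 2, 2, w // 2, 2)
    out_data = r.mean(axis=(3, 5, 7))

    def bwd(g):
        gx = np.repeat(np.repeat(np.repeat(g, 2, 2), 2, 3), 2, 4) / 8.0
        x._accumulate(gx)

    return Tensor(out_data, parents=(x,), backward=bwd)


def upsample_nearest3d(x: Tensor) -> Tensor:
    """Nearest-neighbor 2x upsampling."""
    out_data = np.repeat(np.repeat(np.repeat(x.data, 2, 2), 2, 3), 2, 4)

    def bwd(g):
        b, c, d, h, w = x.data.shape
        r = g.reshape(b, c, d, 2, h, 2, w, 2)
        x._accumulate(r.sum(axis=(3, 5, 7)))

    return Tensor(out_data, parents=(x,), backward=bwd)


def instance_norm3d(x: Tensor, gamma: Tensor, beta: Tensor,
                    eps: float = 1e-5) -> Tensor:
    """Per-sample per-channel normalization over spatial dims, with affine
    scale/shift (``gamma``/``beta`` of shape (C,))."""
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (1, -1, 1, 1, 1)
    out_data = xhat * gamma.data.reshape(gshape) + beta.data.reshape(gshape)
    m = float(np.prod([x.data.shape[a] for a in axes]))

    def bwd(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3, 4)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gh = g * gamma.data.reshape(gshape)
            s1 = gh.sum(axis=axes, keepdims=True)
            s2 = (gh * xhat).sum(axis=axes, keepdims=True)
            gx = inv * (gh - s1 / m - xhat * s2 / m)
            x._accumulate(gx)

    return Tensor(out_data, parents=(x, gamma, beta), backward=bwd)


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with optional cosine decay of the learning rate."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, total_steps: int | None = None,
                 min_lr_fraction: float = 0.05):
        self.params = params
        self.base_lr = lr
        self.betas = betas
        self.eps = eps
        self.total_steps = total_steps
        self.min_lr_fraction = min_lr_fraction
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def current_lr(self) -> float:
        if self.total_steps is None:
            return self.base_lr
        frac = min(1.0, self.t / max(1, self.total_steps))
        cos = 0.5 * (1.0 + math.cos(math.pi * frac))
        lo = self.base_lr * self.min_lr_fraction
        return lo + (self.base_lr - lo) * cos

    def step(self) -> None:
        self.t += 1
        lr = self.current_lr()
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(m) for m in state["m"]]
        self.v = [np.array(v) for v in state["v"]]
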