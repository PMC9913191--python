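"""Minimal reverse-mode automatic differentiation on numpy arrays.

The detector only needs a handful of differentiable operations —
convolution (via im2col), batch normalisation, leaky ReLU, elementwise
add, channel concatenation and nearest-neighbour upsampling — so rather
than a general tensor algebra this module implements exactly those, each
with a hand-derived backward pass.  Gradients are checked against finite
differences in the test suite.

All tensors are float32, NCHW layout.
"""

from __future__ import annotations

from typing import Callable, Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "conv2d", "batch_norm", "leaky_relu", "add", "concat", "upsample2x"]


class Tensor:
    """An array with an optional gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        requires_grad: bool = False,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], None] | None = None,
    ):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents
        self._backward = backward

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.asarray(g, dtype=np.float32).copy()
        else:
            self.grad += g

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor through the recorded graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        if grad is None:
            grad = np.ones_like(self.data)
        self.accumulate(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, int, int]:
    """(N,C,H,W) -> (N, OH*OW, C*k*k) patch matrix."""
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    oh = (h + 2 * pad - k) // stride + 1
    ow = (w + 2 * pad - k) // stride + 1
    win = sliding_window_view(x, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
        n, oh * ow, c * k * k
    )
    return cols, oh, ow


def _col2im(
    dcols: np.ndarray,
    x_shape: tuple[int, int, int, int],
    k: int,
    stride: int,
    pad: int,
    oh: int,
    ow: int,
) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter patch gradients back to the image."""
    n, c, h, w = x_shape
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    d6 = dcols.reshape(n, oh, ow, c, k, k).transpose(0, 3, 1, 2, 4, 5)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += d6[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + h, pad : pad + w]
    return dxp


def conv2d(
    x: Tensor, weight: Tensor, bias: Tensor | None = None, stride: int = 1, pad: int = 0
) -> Tensor:
    """2-D convolution, weight shape (F, C, k, k)."""
    f, c, k, _ = weight.data.shape
    cols, oh, ow = _im2col(x.data, k, stride, pad)
    wmat = weight.data.reshape(f, c * k * k)
    out = cols @ wmat.T  # (N, OH*OW, F)
    if bias is not None:
        out += bias.data
    n = x.data.shape[0]
    out = np.ascontiguousarray(out.transpose(0, 2, 1)).reshape(n, f, oh, ow)

    parents = (x, weight) + ((bias,) if bias is not None else ())

    def _backward(g: np.ndarray) -> None:
        gmat = np.ascontiguousarray(g.reshape(n, f, oh * ow).transpose(0, 2, 1))
        if weight.requires_grad:
            dw = np.einsum("npf,npk->fk", gmat, cols, optimize=True)
            weight.accumulate(dw.reshape(weight.data.shape))
        if bias is not None and bias.requires_grad:
            bias.accumulate(gmat.sum(axis=(0, 1)))
        if x.requires_grad:
            dcols = gmat @ wmat
            x.accumulate(_col2im(dcols, x.data.shape, k, stride, pad, oh, ow))

    return Tensor(out, parents=parents, backward=_backward)


def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalisation; updates running stats in place."""
    xd = x.data
    if training:
        mean = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mean[None, :, None, None]) * invstd[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def _backward(g: np.ndarray) -> None:
        if gamma.requires_grad:
            gamma.accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta.accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
            if training:
                m = g.shape[0] * g.shape[2] * g.shape[3]
                gmean = g.mean(axis=(0, 2, 3))[None, :, None, None]
                gxhat = (g * xhat).mean(axis=(0, 2, 3))[None, :, None, None]
                x.accumulate(gi * (g - gmean - xhat * gxhat))
            else:
                x.accumulate(gi * g)

    return Tensor(out, parents=(x, gamma, beta), backward=_backward)


def leaky_relu(x: Tensor, slope: float = 0.1) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, slope * x.data)

    def _backward(g: np.ndarray) -> None:
        if x.requires_grad:
            x.accumulate(np.where(mask, g, slope * g))

    return Tensor(out, parents=(x,), backward=_backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def _backward(g: np.ndarray) -> None:
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return Tensor(out, parents=(a, b), backward=_backward)


def concat(tensors: Iterable[Tensor], axis: int = 1) -> Tensor:
    ts = list(tensors)
    out = np.concatenate([t.data for t in ts], axis=axis)
    sizes = [t.data.shape[axis] for t in ts]
    offsets = np.cumsum([0] + sizes)

    def _backward(g: np.ndarray) -> None:
        for t, lo, hi in zip(ts, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                idx = [slice(None)] * g.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(g[tuple(idx)])

    return Tensor(out, parents=tuple(ts), backward=_backward)


def upsample2x(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x spatial upsampling."""
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def _backward(g: np.ndarray) -> None:
        if x.requires_grad:
            n, c, h2, w2 = g.shape
            x.accumulate(
                g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
            )

    return Tensor(out, parents=(x,), backward=_backward)
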