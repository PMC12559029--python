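"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The unfolded denoiser needs only a small, fixed set of differentiable
primitives (1-D convolution, batch normalization, max pooling, zero-stuffed
upsampling, ReLU, channel concatenation and elementwise arithmetic), so the
engine implements exactly those with hand-derived vector-Jacobian products
and a topological-order backward pass.  Everything runs in float64 on CPU;
gradients are finite-difference checked in the test suite.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "scale",
    "relu",
    "conv1d",
    "zero_upsample",
    "maxpool1d",
    "concat_channels",
    "batchnorm",
    "mean_square",
]


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple["Tensor", ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g

    def backward(self) -> None:
        """Backpropagate from this (scalar) node through the graph."""
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # convenience operators (graph-building)
    def __add__(self, other):
        return add(self, other)

    def __sub__(self, other):
        return sub(self, other)

    def __mul__(self, other):
        return mul(self, other)

    def __neg__(self):
        return scale(self, -1.0)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs_grad(*tensors: Tensor) -> bool:
    return any(t.requires_grad or t._backward is not None for t in tensors)


def _make(data: np.ndarray, parents: tuple[Tensor, ...], backward) -> Tensor:
    out = Tensor(data)
    if _needs_grad(*parents):
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


def add(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data + b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def sub(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data - b.data

    def backward(g):
        a._accumulate(_unbroadcast(g, a.data.shape))
        b._accumulate(-_unbroadcast(g, b.data.shape))

    return _make(data, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    data = a.data * b.data

    def backward(g):
        a._accumulate(_unbroadcast(g * b.data, a.data.shape))
        b._accumulate(_unbroadcast(g * a.data, b.data.shape))

    return _make(data, (a, b), backward)


def scale(a, c: float) -> Tensor:
    a = _as_tensor(a)
    data = a.data * c

    def backward(g):
        a._accumulate(g * c)

    return _make(data, (a,), backward)


def relu(a) -> Tensor:
    a = _as_tensor(a)
    mask = a.data > 0
    data = a.data * mask

    def backward(g):
        a._accumulate(g * mask)

    return _make(data, (a,), backward)


def _windows(x: np.ndarray, k: int) -> np.ndarray:
    # (B, C, L') -> (B, C, L'-k+1, k) sliding view
    return np.lib.stride_tricks.sliding_window_view(x, k, axis=-1)


def conv1d(x, w, b=None) -> Tensor:
    """'Same'-padded 1-D cross-correlation.

    ``x``: (B, C_in, L); ``w``: (C_out, C_in, k) with odd k; ``b``: (C_out,).
    """
    x, w = _as_tensor(x), _as_tensor(w)
    B, Ci, L = x.data.shape
    Co, Ci_w, k = w.data.shape
    if Ci != Ci_w:
        raise ValueError(f"channel mismatch: input {Ci} vs weight {Ci_w}")
    if k % 2 != 1:
        raise ValueError(f"kernel size must be odd, got {k}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p)))
    win = _windows(xp, k)  # (B, Ci, L, k)
    data = np.einsum("bclk,ock->bol", win, w.data, optimize=True)
    parents = [x, w]
    if b is not None:
        b = _as_tensor(b)
        data = data + b.data[None, :, None]
        parents.append(b)

    def backward(g):
        # dW
        if w.requires_grad or w._backward is not None:
            dw = np.einsum("bol,bclk->ock", g, win, optimize=True)
            w._accumulate(dw)
        # dX: full correlation of g with kernel flipped along k
        if x.requires_grad or x._backward is not None:
            gp = np.pad(g, ((0, 0), (0, 0), (p, p)))
            gwin = _windows(gp, k)  # (B, Co, L, k)
            dx = np.einsum("bolk,ock->bcl", gwin, w.data[:, :, ::-1], optimize=True)
            x._accumulate(dx)
        if b is not None:
            b._accumulate(g.sum(axis=(0, 2)))

    return _make(data, tuple(parents), backward)


def zero_upsample(x, factor: int = 2) -> Tensor:
    """Insert ``factor - 1`` zeros between samples (transposed-conv stride)."""
    x = _as_tensor(x)
    B, C, L = x.data.shape
    data = np.zeros((B, C, L * factor))
    data[..., ::factor] = x.data

    def backward(g):
        x._accumulate(g[..., ::factor])

    return _make(data, (x,), backward)


def maxpool1d(x, factor: int = 2) -> Tensor:
    x = _as_tensor(x)
    B, C, L = x.data.shape
    if L % factor != 0:
        raise ValueError(f"length {L} not divisible by pool factor {factor}")
    blocks = x.data.reshape(B, C, L // factor, factor)
    idx = blocks.argmax(axis=-1)
    data = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gx = np.zeros_like(blocks)
        np.put_along_axis(gx, idx[..., None], g[..., None], axis=-1)
        x._accumulate(gx.reshape(B, C, L))

    return _make(data, (x,), backward)


def concat_channels(a, b) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    ca = a.data.shape[1]
    data = np.concatenate([a.data, b.data], axis=1)

    def backward(g):
        a._accumulate(g[:, :ca])
        b._accumulate(g[:, ca:])

    return _make(data, (a, b), backward)


def batchnorm(
    x,
    gamma,
    beta,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (batch, time).

    In training mode the batch statistics are used and the running buffers
    are updated in place; in eval mode the running buffers are used.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    B, C, L = x.data.shape
    m = B * L
    if training:
        mean = x.data.mean(axis=(0, 2))
        var = x.data.var(axis=(0, 2))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean = running_mean
        var = running_var
    std = np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None]) / std[None, :, None]
    data = gamma.data[None, :, None] * xhat + beta.data[None, :, None]

    def backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2)))
        beta._accumulate(g.sum(axis=(0, 2)))
        if x.requires_grad or x._backward is not None:
            gscale = gamma.data[None, :, None] / std[None, :, None]
            if training:
                sum_g = g.sum(axis=(0, 2), keepdims=True)
                sum_gx = (g * xhat).sum(axis=(0, 2), keepdims=True)
                dx = gscale * (g - sum_g / m - xhat * sum_gx / m)
            else:
                dx = gscale * g
            x._accumulate(dx)

    return _make(data, (x, gamma, beta), backward)


def mean_square(a) -> Tensor:
    """mean(a**2) — the building block of the MSE loss."""
    a = _as_tensor(a)
    data = np.array(np.mean(a.data**2))

    def backward(g):
        a._accumulate(g * 2.0 * a.data / a.data.size)

    return _make(data, (a,), backward)
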