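"""Minimal reverse-mode autodiff over NumPy arrays.

Implements exactly the operations an encoder--decoder segmentation network
needs: 2-D convolution (im2col), batch normalization, 2x2 max pooling,
nearest/bilinear upsampling, channel concatenation, ReLU/sigmoid, and the
training losses. Tensors are NCHW float32 throughout; every op records a
backward closure and ``Tensor.backward`` runs a topological sweep.

All backward passes are verified against central finite differences in the
test suite.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "conv2d",
    "batch_norm2d",
    "max_pool2x2",
    "upsample_nearest2x",
    "resize_bilinear",
    "concat_channels",
    "bce_loss",
    "soft_dice_loss",
]


class Tensor:
    """A NumPy array plus gradient bookkeeping.

    Parameters with ``requires_grad=True`` accumulate into ``.grad``;
    intermediate results carry closures that push gradients to parents.
    """

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward: Callable[[np.ndarray], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def zero_grad(self) -> None:
        self.grad = None

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this tensor (defaults to d(self)/d(self)=1)."""
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        # iterative postorder topological sort
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
                if id(p) not in seen:
                    stack.append((p, False))

        grads: dict[int, np.ndarray] = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is not None:
                for parent, pg in zip(node._parents, node._backward(g)):
                    if pg is None:
                        continue
                    if id(parent) in grads:
                        grads[id(parent)] = grads[id(parent)] + pg
                    else:
                        grads[id(parent)] = pg


def _make(data: np.ndarray, parents: Sequence[Tensor], backward) -> Tensor:
    out = Tensor(data)
    if any(p.requires_grad or p._parents for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, size in enumerate(shape):
        if size == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def add(a: Tensor, b: Tensor) -> Tensor:
    out = a.data + b.data

    def backward(g):
        return _unbroadcast(g, a.data.shape), _unbroadcast(g, b.data.shape)

    return _make(out, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out = a.data * b.data

    def backward(g):
        return (
            _unbroadcast(g * b.data, a.data.shape),
            _unbroadcast(g * a.data, b.data.shape),
        )

    return _make(out, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = np.where(mask, x.data, 0.0).astype(np.float32)

    def backward(g):
        return (g * mask,)

    return _make(out, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    out = 1.0 / (1.0 + np.exp(-x.data))

    def backward(g):
        return (g * out * (1.0 - out),)

    return _make(out.astype(np.float32), (x,), backward)


# ---------------------------------------------------------------------------
# convolution


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    """Return patches of shape (N, Ho, Wo, C*kh*kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    view = sliding_window_view(x, (kh, kw), axis=(2, 3))
    view = view[:, :, ::stride, ::stride]  # N, C, Ho, Wo, kh, kw
    n, c, ho, wo = view.shape[:4]
    cols = view.transpose(0, 2, 3, 1, 4, 5).reshape(n, ho, wo, c * kh * kw)
    return np.ascontiguousarray(cols), ho, wo


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    """Scatter-add patch gradients (N, Ho, Wo, C*kh*kw) back to input shape."""
    n, c, h, w = xshape
    ho, wo = dcols.shape[1], dcols.shape[2]
    dxp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=np.float32)
    dcols = dcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[
                :, :, i, j
            ]
    if pad:
        dxp = dxp[:, :, pad:-pad, pad:-pad]
    return dxp


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D cross-correlation; weight is (Cout, Cin, kh, kw)."""
    cout, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(
            f"channel mismatch: input has {x.data.shape[1]} channels, kernel expects {cin}"
        )
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = weight.data.reshape(cout, -1)
    out = cols @ wmat.T  # N, Ho, Wo, Cout
    if bias is not None:
        out += bias.data.reshape(1, 1, 1, cout)
    out = out.transpose(0, 3, 1, 2)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1)  # N, Ho, Wo, Cout
        gflat = gmat.reshape(-1, cout)
        dw = (gflat.T @ cols.reshape(-1, cols.shape[-1])).reshape(weight.data.shape)
        dcols = gmat @ wmat  # N, Ho, Wo, Cin*kh*kw
        dx = _col2im(dcols, x.data.shape, kh, kw, stride, pad)
        grads = [dx, dw]
        if bias is not None:
            grads.append(gflat.sum(axis=0))
        return grads

    parents = (x, weight) if bias is None else (x, weight, bias)
    return _make(np.ascontiguousarray(out, dtype=np.float32), parents, backward)


# ---------------------------------------------------------------------------
# batch normalization


def batch_norm2d(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Per-channel batch normalization over (N, H, W).

    In training mode batch statistics are used and the running buffers are
    updated in place; in eval mode the running statistics are used, making
    inference deterministic.
    """
    c = x.data.shape[1]
    gshape = (1, c, 1, 1)
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu.reshape(gshape)) * inv_std.reshape(gshape)
    out = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def backward(g):
        dgamma = (g * xhat).sum(axis=(0, 2, 3))
        dbeta = g.sum(axis=(0, 2, 3))
        gs = gamma.data.reshape(gshape) * inv_std.reshape(gshape)
        if training:
            gmean = g.mean(axis=(0, 2, 3)).reshape(gshape)
            gxhat_mean = (g * xhat).mean(axis=(0, 2, 3)).reshape(gshape)
            dx = gs * (g - gmean - xhat * gxhat_mean)
        else:
            dx = gs * g
        return dx.astype(np.float32), dgamma, dbeta

    return _make(out.astype(np.float32), (x, gamma, beta), backward)


# ---------------------------------------------------------------------------
# pooling and upsampling


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2x2 requires even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    blocks = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, ho, wo, 4
    )
    idx = blocks.argmax(axis=-1)
    out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dblocks = np.zeros((n, c, ho, wo, 4), dtype=np.float32)
        np.put_along_axis(dblocks, idx[..., None], g[..., None], axis=-1)
        dx = dblocks.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            n, c, h, w
        )
        return (dx,)

    return _make(np.ascontiguousarray(out), (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    out = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        dx = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
        return (dx,)

    return _make(out, (x,), backward)


def _linear_resize_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-interpolation matrix for bilinear resize (half-pixel centers)."""
    mat = np.zeros((n_out, n_in), dtype=np.float32)
    if n_in == 1:
        mat[:, 0] = 1.0
        return mat
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0.0, n_in - 1.0)
    i0 = np.floor(src).astype(int)
    i1 = np.minimum(i0 + 1, n_in - 1)
    frac = (src - i0).astype(np.float32)
    np.add.at(mat, (np.arange(n_out), i0), 1.0 - frac)
    np.add.at(mat, (np.arange(n_out), i1), frac)
    return mat


def resize_bilinear(x: Tensor, target_hw: tuple[int, int]) -> Tensor:
    """Bilinear spatial resize to (H, W); linear and hence cheap to transpose."""
    h_in, w_in = x.data.shape[2:]
    h_out, w_out = target_hw
    wr = _linear_resize_matrix(h_out, h_in)
    wc = _linear_resize_matrix(w_out, w_in)
    out = np.einsum("ph,nchw,qw->ncpq", wr, x.data, wc, optimize=True)

    def backward(g):
        dx = np.einsum("ph,ncpq,qw->nchw", wr, g, wc, optimize=True)
        return (dx.astype(np.float32),)

    return _make(out.astype(np.float32), (x,), backward)


def concat_channels(tensors: Sequence[Tensor]) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]
    edges = np.cumsum([0] + sizes)

    def backward(g):
        return [g[:, edges[i] : edges[i + 1]] for i in range(len(sizes))]

    return _make(out, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# losses


def bce_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy over all pixels, with clamped probabilities."""
    y = np.asarray(target, dtype=np.float32)
    if y.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: prediction {pred.data.shape}, target {y.shape}")
    p = np.clip(pred.data, eps, 1.0 - eps)
    out = -(y * np.log(p) + (1.0 - y) * np.log1p(-p)).mean()

    def backward(g):
        inside = (pred.data > eps) & (pred.data < 1.0 - eps)
        dp = (p - y) / (p * (1.0 - p)) / p.size
        return (np.where(inside, dp, 0.0).astype(np.float32) * g,)

    return _make(np.float32(out), (pred,), backward)


def soft_dice_loss(pred: Tensor, target: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice, averaged over the batch; a region-overlap loss option."""
    y = np.asarray(target, dtype=np.float32)
    if y.shape != pred.data.shape:
        raise ValueError(f"shape mismatch: prediction {pred.data.shape}, target {y.shape}")
    p = pred.data
    axes = tuple(range(1, p.ndim))
    inter = (p * y).sum(axis=axes)
    denom = p.sum(axis=axes) + y.sum(axis=axes)
    dice = (2.0 * inter + smooth) / (denom + smooth)
    out = 1.0 - dice.mean()

    def backward(g):
        n = p.shape[0]
        shape = (n,) + (1,) * (p.ndim - 1)
        d_inter = 2.0 / (denom + smooth)
        d_denom = -(2.0 * inter + smooth) / (denom + smooth) ** 2
        dp = -(d_inter.reshape(shape) * y + d_denom.reshape(shape)) / n
        return (dp.astype(np.float32) * g,)

    return _make(np.float32(out), (pred,), backward)
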