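"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the numerical core behind the segmentation networks: a tape-free
graph of :class:`Tensor` nodes, each holding a float32 array and a closure
that propagates gradients to its parents.  Only the operations the UNet
variants need are provided (elementwise arithmetic, matmul, 3x3/1x1
convolution, 2x2 max-pooling, 2x2 transposed convolution, reductions,
sigmoid/ReLU/exp/sqrt, concatenation, reshape).  Convolution is lowered to
batched matrix multiplication via an im2col view so the heavy lifting runs
through BLAS; the column matrix is recomputed during the backward pass
instead of being cached, trading a little compute for a much smaller peak
memory footprint.

Everything is float32 and single-threaded-deterministic: identical inputs,
parameters and operation order reproduce bit-identical results.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "constant",
    "add",
    "sub",
    "mul",
    "div",
    "neg",
    "matmul",
    "relu",
    "sigmoid",
    "exp",
    "sqrt",
    "reduce_sum",
    "reduce_mean",
    "reduce_max",
    "reshape",
    "concat",
    "conv2d",
    "conv_transpose2d_2x2",
    "maxpool2d_2x2",
    "softmax_channel",
    "Adam",
]


class Tensor:
    """Node in the computation graph: a float32 array plus backward plumbing."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None):
        """Backpropagate from this node (defaults to d(self)/d(self) = 1)."""
        if grad is None:
            grad = np.ones_like(self.data)
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
        self.grad = np.asarray(grad, dtype=np.float32)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None

    # Operator sugar used sparingly by the layer code.
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __truediv__(self, other):
        return div(self, _as_tensor(other))

    def __neg__(self):
        return neg(self)


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def constant(x) -> Tensor:
    """A graph leaf that never receives gradients."""
    return Tensor(x)


def _accumulate(node: Tensor, grad: np.ndarray):
    if not node.requires_grad:
        return
    if node.grad is None:
        node.grad = grad.astype(np.float32, copy=True)
    else:
        node.grad += grad


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# elementwise ops


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data + b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data - b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g, a.shape))
        _accumulate(b, _unbroadcast(-g, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data * b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g * b.data, a.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def div(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out_data = a.data / b.data

    def bwd(g):
        _accumulate(a, _unbroadcast(g / b.data, a.shape))
        _accumulate(b, _unbroadcast(-g * a.data / (b.data * b.data), b.shape))

    return Tensor(out_data, parents=(a, b), backward=bwd)


def neg(a: Tensor) -> Tensor:
    def bwd(g):
        _accumulate(a, -g)

    return Tensor(-a.data, parents=(a,), backward=bwd)


def relu(a: Tensor) -> Tensor:
    mask = a.data > 0
    out_data = np.where(mask, a.data, 0.0)

    def bwd(g):
        _accumulate(a, g * mask)

    return Tensor(out_data, parents=(a,), backward=bwd)


def sigmoid(a: Tensor) -> Tensor:
    # Numerically stable logistic.
    x = a.data
    out_data = np.where(x >= 0, 1.0 / (1.0 + np.exp(-np.abs(x))),
                        np.exp(-np.abs(x)) / (1.0 + np.exp(-np.abs(x)))).astype(
        np.float32
    )

    def bwd(g):
        _accumulate(a, g * out_data * (1.0 - out_data))

    return Tensor(out_data, parents=(a,), backward=bwd)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def bwd(g):
        _accumulate(a, g * out_data)

    return Tensor(out_data, parents=(a,), backward=bwd)


def sqrt(a: Tensor) -> Tensor:
    out_data = np.sqrt(a.data)

    def bwd(g):
        _accumulate(a, g * 0.5 / out_data)

    return Tensor(out_data, parents=(a,), backward=bwd)


# ---------------------------------------------------------------------------
# reductions and shape ops


def reduce_sum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            for ax in sorted(ax % a.ndim for ax in axes):
                g = np.expand_dims(g, ax)
        _accumulate(a, np.broadcast_to(g, a.shape).astype(np.float32))

    return Tensor(out_data, parents=(a,), backward=bwd)


def reduce_mean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    if axis is None:
        count = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        count = int(np.prod([a.shape[ax] for ax in axes]))
    s = reduce_sum(a, axis=axis, keepdims=keepdims)
    return mul(s, constant(np.float32(1.0 / count)))


def reduce_max(a: Tensor, axis: int, keepdims=False) -> Tensor:
    """Max along one axis; gradient is split equally among tied maxima."""
    out_data = a.data.max(axis=axis, keepdims=keepdims)

    def bwd(g):
        g = np.asarray(g)
        m = a.data.max(axis=axis, keepdims=True)
        mask = (a.data == m).astype(np.float32)
        mask /= mask.sum(axis=axis, keepdims=True)
        if not keepdims:
            g = np.expand_dims(g, axis)
        _accumulate(a, (g * mask).astype(np.float32))

    return Tensor(out_data, parents=(a,), backward=bwd)


def reshape(a: Tensor, shape) -> Tensor:
    out_data = a.data.reshape(shape)

    def bwd(g):
        _accumulate(a, g.reshape(a.shape))

    return Tensor(out_data, parents=(a,), backward=bwd)


def concat(tensors, axis=1) -> Tensor:
    tensors = [_as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            _accumulate(t, g[tuple(idx)])

    return Tensor(out_data, parents=tuple(tensors), backward=bwd)


# ---------------------------------------------------------------------------
# convolution / pooling (NCHW layout)


def _im2col(xp: np.ndarray, k: int, H: int, W: int) -> np.ndarray:
    """(N, C, H+2p, W+2p) -> contiguous (N, C*k*k, H*W) column matrix.

    Built from k*k contiguous slice copies, which is far faster than
    gathering a strided window view.
    """
    N, C = xp.shape[:2]
    cols = np.empty((N, C, k * k, H, W), dtype=np.float32)
    for ki in range(k):
        for kj in range(k):
            cols[:, :, ki * k + kj] = xp[:, :, ki : ki + H, kj : kj + W]
    return cols.reshape(N, C * k * k, H * W)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, pad: int | None = None) -> Tensor:
    """2D convolution, stride 1.  w: (Cout, Cin, k, k); 'same' padding by default."""
    N, C, H, W = x.shape
    Co, Ci, k, _ = w.shape
    if Ci != C:
        raise ValueError(f"conv2d channel mismatch: input {C}, weight {Ci}")
    if pad is None:
        pad = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    cols = _im2col(xp, k, H, W)
    w2 = w.data.reshape(Co, Ci * k * k)
    out_data = np.matmul(w2, cols).reshape(N, Co, H, W)
    if b is not None:
        out_data += b.data.reshape(1, Co, 1, 1)

    def bwd(g):
        gf = g.reshape(N, Co, H * W)
        if w.requires_grad:
            xp2 = (
                np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
                if pad
                else x.data
            )
            cols_b = _im2col(xp2, k, H, W)
            dw = np.matmul(gf, cols_b.transpose(0, 2, 1)).sum(axis=0)
            _accumulate(w, dw.reshape(w.shape))
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = np.matmul(w2.T, gf).reshape(N, C, k, k, H, W)
            dxp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki : ki + H, kj : kj + W] += dcols[:, :, ki, kj]
            dx = dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp
            _accumulate(x, dx)

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def maxpool2d_2x2(x: Tensor) -> Tensor:
    N, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError(f"maxpool2d_2x2 needs even spatial dims, got {H}x{W}")
    xr = x.data.reshape(N, C, H // 2, 2, W // 2, 2)
    out_data = xr.max(axis=(3, 5))

    def bwd(g):
        m = out_data[:, :, :, None, :, None]
        mask = (xr == m).astype(np.float32)
        mask /= mask.sum(axis=(3, 5), keepdims=True)
        dx = mask * g[:, :, :, None, :, None]
        _accumulate(x, dx.reshape(N, C, H, W))

    return Tensor(out_data, parents=(x,), backward=bwd)


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2x2 stride 2.  w: (Cin, Cout, 2, 2)."""
    N, C, H, W = x.shape
    Ci, Co = w.shape[:2]
    if Ci != C:
        raise ValueError(f"conv_transpose2d channel mismatch: input {C}, weight {Ci}")
    t = np.tensordot(x.data, w.data, axes=([1], [0]))  # (N, H, W, Co, 2, 2)
    out_data = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5)).reshape(
        N, Co, 2 * H, 2 * W
    )
    if b is not None:
        out_data += b.data.reshape(1, Co, 1, 1)

    def bwd(g):
        gr = g.reshape(N, Co, H, 2, W, 2).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,Co,2,2
        if x.requires_grad:
            dx = np.tensordot(gr, w.data, axes=([3, 4, 5], [1, 2, 3]))  # N,H,W,Ci
            _accumulate(x, np.ascontiguousarray(dx.transpose(0, 3, 1, 2)))
        if w.requires_grad:
            dw = np.tensordot(x.data, gr, axes=([0, 2, 3], [0, 1, 2]))  # Ci,Co,2,2
            _accumulate(w, dw)
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))

    parents = (x, w) if b is None else (x, w, b)
    return Tensor(out_data, parents=parents, backward=bwd)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def bwd(g):
        if a.requires_grad:
            _accumulate(a, g @ b.data.T)
        if b.requires_grad:
            _accumulate(b, a.data.T @ g)

    return Tensor(out_data, parents=(a, b), backward=bwd)


def softmax_channel(x: Tensor) -> Tensor:
    """Softmax along axis 1 of an NCHW tensor (the max shift is detached)."""
    shift = constant(x.data.max(axis=1, keepdims=True))
    e = exp(sub(x, shift))
    return div(e, reduce_sum(e, axis=1, keepdims=True))


# ---------------------------------------------------------------------------
# optimizer


class Adam:
    """Adam with the standard bias correction; state is per-parameter."""

    def __init__(self, params, lr=1e-5, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = float(eps)
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.data -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
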