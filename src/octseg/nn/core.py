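"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operations the segmentation network needs: broadcast
arithmetic, ReLU/sigmoid, NCHW convolutions (im2col + BLAS matmul), 2x2
transposed convolution, nearest-neighbour upsampling, max-pooling with
residual (argmax-zeroed) output, channel-wise max/mean pooling, batch
normalisation, channel concatenation, and fused segmentation losses.

Gradients accumulate into ``Tensor.grad``; ``Tensor.backward`` walks the tape
in reverse topological order.  Dtype follows the inputs, so float64 can be
used for numerical gradient checks while training runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "add",
    "mul",
    "relu",
    "sigmoid",
    "concat_channels",
    "conv2d",
    "conv_transpose2x2",
    "upsample_nearest2",
    "maxpool_residual",
    "channel_max",
    "channel_mean",
    "batchnorm2d_train",
    "weighted_cross_entropy",
    "soft_dice_loss",
    "softmax",
]


class Tensor:
    """A numpy array plus gradient bookkeeping."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents: tuple = ()
        self._backward = None

    # -- convenience -------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def __add__(self, other):
        return add(self, other)

    def __mul__(self, other):
        return mul(self, other)

    # -- autograd ----------------------------------------------------------
    def backward(self, grad=None):
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
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen and p.requires_grad:
                    stack.append((p, False))
        self.grad = np.asarray(grad)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
    else:
        t.grad = t.grad + g


def _node(data, parents, backward) -> Tensor:
    out = Tensor(data)
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._parents = parents
        out._backward = backward
    return out


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum *g* over the axes that were broadcast to reach ``g.shape``."""
    if g.shape == shape:
        return g
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise
# ---------------------------------------------------------------------------

def add(a: Tensor, b) -> Tensor:
    if not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=a.dtype))
    data = a.data + b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g, a.data.shape))
        _accumulate(b, _unbroadcast(g, b.data.shape))

    return _node(data, (a, b), backward)


def mul(a: Tensor, b) -> Tensor:
    if not isinstance(b, Tensor):
        b = Tensor(np.asarray(b, dtype=a.dtype))
    data = a.data * b.data

    def backward(g):
        _accumulate(a, _unbroadcast(g * b.data, a.data.shape))
        _accumulate(b, _unbroadcast(g * a.data, b.data.shape))

    return _node(data, (a, b), backward)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    data = x.data * mask

    def backward(g):
        _accumulate(x, g * mask)

    return _node(data, (x,), backward)


def sigmoid(x: Tensor) -> Tensor:
    data = _sigmoid(x.data)

    def backward(g):
        _accumulate(x, g * data * (1.0 - data))

    return _node(data, (x,), backward)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=z.dtype if z.dtype.kind == "f" else np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def concat_channels(tensors: list[Tensor]) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=1)
    sizes = [t.data.shape[1] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            _accumulate(t, g[:, lo:hi])

    return _node(data, tuple(tensors), backward)


# ---------------------------------------------------------------------------
# convolution machinery
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    windows = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    cols = np.ascontiguousarray(windows).reshape(n, c * kh * kw, ho * wo)
    return cols, ho, wo


def _col2im(cols: np.ndarray, xshape, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = xshape
    ho = (h + 2 * pad - kh) // stride + 1
    wo = (w + 2 * pad - kw) // stride + 1
    gx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    cols6 = cols.reshape(n, c, kh, kw, ho, wo)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + stride * ho:stride, j:j + stride * wo:stride] += cols6[:, :, i, j]
    if pad:
        gx = gx[:, :, pad:-pad, pad:-pad]
    return gx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation of NCHW *x* with OIHW weight *w* (the CNN convention)."""
    cout, cin, kh, kw = w.data.shape
    n = x.data.shape[0]
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out = np.matmul(wmat, cols)               # (n, cout, ho*wo) via broadcast
    out = out.reshape(n, cout, ho, wo)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        gmat = g.reshape(n, cout, ho * wo)
        if w.requires_grad:
            gw = np.matmul(gmat, cols.transpose(0, 2, 1)).sum(axis=0)
            _accumulate(w, gw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gcols = np.matmul(wmat.T, gmat)
            _accumulate(x, _col2im(gcols, x.data.shape, kh, kw, stride, pad))

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out, parents, backward)


def fixed_conv3(x: Tensor, kernel: np.ndarray) -> Tensor:
    """Per-channel same-size cross-correlation with one fixed 3x3 kernel,
    using edge-replicated padding (so zero-sum kernels annihilate constants
    everywhere, including the image border).

    The caller is responsible for flipping the kernel when true convolution
    semantics are wanted.  No gradient flows to the kernel.
    """
    k = np.asarray(kernel, dtype=x.dtype)
    data = _corr_same_perchannel(x.data, k)

    def backward(g):
        # adjoint of (edge-pad then valid correlation): full correlation with
        # the flipped kernel, then fold the padded-border gradient back onto
        # the edge pixels it was replicated from
        gp = _corr_valid(np.pad(g, ((0, 0), (0, 0), (2, 2), (2, 2))), k[::-1, ::-1])
        gx = gp[:, :, 1:-1, 1:-1].copy()
        gx[:, :, 0, :] += gp[:, :, 0, 1:-1]
        gx[:, :, -1, :] += gp[:, :, -1, 1:-1]
        gx[:, :, :, 0] += gp[:, :, 1:-1, 0]
        gx[:, :, :, -1] += gp[:, :, 1:-1, -1]
        gx[:, :, 0, 0] += gp[:, :, 0, 0]
        gx[:, :, 0, -1] += gp[:, :, 0, -1]
        gx[:, :, -1, 0] += gp[:, :, -1, 0]
        gx[:, :, -1, -1] += gp[:, :, -1, -1]
        _accumulate(x, gx)

    return _node(data, (x,), backward)


def _corr_valid(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    n, c, h, w = x.shape
    kh, kw = k.shape
    cols, ho, wo = _im2col(x.reshape(n * c, 1, h, w), kh, kw, 1, 0)
    out = np.matmul(k.reshape(1, kh * kw).astype(x.dtype), cols)
    return out.reshape(n, c, ho, wo)


def _corr_same_perchannel(x: np.ndarray, k: np.ndarray) -> np.ndarray:
    pad = k.shape[0] // 2
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="edge")
    return _corr_valid(xp, k)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (learned x2 upsampling).

    Weight layout (cin, cout, 2, 2); output spatial dims double.
    """
    n, cin, h, wid = x.data.shape
    cin_w, cout, kh, kw = w.data.shape
    t = np.tensordot(x.data, w.data, axes=([1], [0]))   # (n, h, w, o, 2, 2)
    out = np.ascontiguousarray(t.transpose(0, 3, 1, 4, 2, 5))
    out = out.reshape(n, cout, h * 2, wid * 2)
    if b is not None:
        out = out + b.data.reshape(1, cout, 1, 1)

    def backward(g):
        gb = g.reshape(n, cout, h, 2, wid, 2)
        if w.requires_grad:
            gw = np.tensordot(x.data, gb, axes=([0, 2, 3], [0, 2, 4]))
            _accumulate(w, gw)
        if b is not None and b.requires_grad:
            _accumulate(b, g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx = np.tensordot(gb, w.data, axes=([1, 3, 5], [1, 2, 3]))
            _accumulate(x, gx.transpose(0, 3, 1, 2))

    parents = (x, w, b) if b is not None else (x, w)
    return _node(out, parents, backward)


def upsample_nearest2(x: Tensor) -> Tensor:
    data = x.data.repeat(2, axis=2).repeat(2, axis=3)

    def backward(g):
        n, c, h2, w2 = g.shape
        _accumulate(x, g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5)))

    return _node(data, (x,), backward)


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------

def maxpool_residual(x: Tensor, k: int = 2) -> tuple[Tensor, Tensor]:
    """Max pooling plus the residual map with each window argmax zeroed.

    Ties break to the first occurrence in row-major window order.  The pooled
    map feeds the next encoder stage; the residual map feeds the skip path.
    """
    n, c, h, w = x.data.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {k}")
    blocks = x.data.reshape(n, c, h // k, k, w // k, k)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // k, w // k, k * k)
    arg = flat.argmax(axis=-1)               # first occurrence, row-major
    pooled = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]

    onehot = np.zeros(flat.shape, dtype=bool)
    np.put_along_axis(onehot, arg[..., None], True, axis=-1)
    keep = ~onehot.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
    keep = keep.reshape(n, c, h, w)
    residual = x.data * keep

    def backward_pooled(g):
        gflat = np.zeros(flat.shape, dtype=g.dtype)
        np.put_along_axis(gflat, arg[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // k, w // k, k, k).transpose(0, 1, 2, 4, 3, 5)
        _accumulate(x, gx.reshape(n, c, h, w))

    def backward_residual(g):
        _accumulate(x, g * keep)

    return (_node(pooled, (x,), backward_pooled),
            _node(residual, (x,), backward_residual))


def channel_max(x: Tensor) -> Tensor:
    arg = x.data.argmax(axis=1, keepdims=True)
    data = np.take_along_axis(x.data, arg, axis=1)

    def backward(g):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, arg, g, axis=1)
        _accumulate(x, gx)

    return _node(data, (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    c = x.data.shape[1]
    data = x.data.mean(axis=1, keepdims=True)

    def backward(g):
        _accumulate(x, np.broadcast_to(g / c, x.data.shape))

    return _node(data, (x,), backward)


# ---------------------------------------------------------------------------
# batch normalisation
# ---------------------------------------------------------------------------

def batchnorm2d_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Training-mode batch norm over (N, H, W).  Returns (out, mean, var)."""
    axes = (0, 2, 3)
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gshape = (1, -1, 1, 1)
    data = gamma.data.reshape(gshape) * xhat + beta.data.reshape(gshape)

    def backward(g):
        if gamma.requires_grad:
            _accumulate(gamma, (g * xhat).sum(axis=axes))
        if beta.requires_grad:
            _accumulate(beta, g.sum(axis=axes))
        if x.requires_grad:
            gxhat = g * gamma.data.reshape(gshape)
            term = (gxhat - gxhat.mean(axis=axes, keepdims=True)
                    - xhat * (gxhat * xhat).mean(axis=axes, keepdims=True))
            _accumulate(x, inv * term)

    return _node(data, (x, gamma, beta), backward), mu.squeeze(), var.squeeze() * m / max(m - 1, 1)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def softmax(z: np.ndarray, axis: int = 1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_cross_entropy(logits: Tensor, labels: np.ndarray,
                           weights: np.ndarray) -> Tensor:
    """sum_i w_i * (-log p_{label_i}) over pixels, fused with softmax.

    *labels* is (N, H, W) int, *weights* (N, H, W) float; the caller encodes
    any normalisation (mean, boundary band weighting) into the weights.
    """
    p = softmax(logits.data, axis=1)
    n, k, h, w = p.shape
    idx = np.expand_dims(labels, 1)
    p_true = np.take_along_axis(p, idx, axis=1)[:, 0]
    loss = float(np.sum(weights * (-np.log(np.maximum(p_true, 1e-12)))))

    def backward(g):
        onehot = np.zeros_like(p)
        np.put_along_axis(onehot, idx, 1.0, axis=1)
        _accumulate(logits, g * weights[:, None] * (p - onehot))

    return _node(np.asarray(loss, dtype=logits.dtype), (logits,), backward)


def soft_dice_loss(logits: Tensor, labels: np.ndarray, n_classes: int,
                   eps: float = 1e-6) -> Tensor:
    """1 - mean-over-classes soft Dice between softmax(logits) and labels."""
    p = softmax(logits.data, axis=1)
    onehot = np.zeros_like(p)
    np.put_along_axis(onehot, np.expand_dims(labels, 1), 1.0, axis=1)
    axes = (0, 2, 3)
    inter = (p * onehot).sum(axis=axes)
    union = p.sum(axis=axes) + onehot.sum(axis=axes)
    dice = (2.0 * inter + eps) / (union + eps)
    loss = 1.0 - dice.mean()

    def backward(g):
        k = n_classes
        # d(dice_c)/d(p_c,i) = (2 t_i (U+eps) - (2 I+eps)) / (U+eps)^2
        num = 2.0 * onehot * (union + eps).reshape(1, k, 1, 1) \
            - (2.0 * inter + eps).reshape(1, k, 1, 1)
        gp = -(1.0 / k) * num / ((union + eps) ** 2).reshape(1, k, 1, 1)
        # chain through softmax: gz = p * (gp - sum_c gp_c p_c)
        inner = (gp * p).sum(axis=1, keepdims=True)
        _accumulate(logits, g * p * (gp - inner))

    return _node(np.asarray(loss, dtype=logits.dtype), (logits,), backward)
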