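"""Minimal CPU neural-network engine for the segmentation architectures.

Implements exactly the pieces the encoder-decoder families need — N-D
convolution (2D/3D, stride 1, same/valid padding), 2x max pooling with
stored argmax indices, index-based unpooling, 2x up-convolution (transposed
convolution), batch normalisation, ReLU, dropout, a class-weighted
cross-entropy head and Adam — with explicit forward/backward passes on
numpy arrays.  Tensors are channels-first: ``(N, C, *spatial)``.

The engine favours clarity and testability (every layer is finite-
difference checkable) over raw speed; desk-scale training of the small
U-Net variants runs in seconds per hundred steps.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "MaxPool",
    "MaxUnpool",
    "UpConv",
    "WeightedCrossEntropy",
    "Adam",
    "conv_output_size",
]


class Param:
    """A trainable array with its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


def conv_output_size(size: int, kernel: int, padding: str) -> int:
    """Spatial output size of a stride-1 convolution."""
    if padding == "same":
        return size
    if padding == "valid":
        return size - kernel + 1
    raise ValueError(f"unknown padding {padding!r}")


class Layer:
    def params(self) -> list[Param]:
        return []


class Conv(Layer):
    """Stride-1 N-D convolution (cross-correlation), kernel k, He init."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, dim: int, padding: str, rng):
        self.in_ch, self.out_ch, self.k, self.dim, self.padding = in_ch, out_ch, kernel, dim, padding
        fan_in = in_ch * kernel**dim
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch) + (kernel,) * dim))
        self.b = Param(np.zeros(out_ch))
        self._xp: np.ndarray | None = None

    def params(self):
        return [self.W, self.b]

    def _pad_width(self):
        p = (self.k - 1) // 2 if self.padding == "same" else 0
        return p

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p = self._pad_width()
        if p:
            pad = [(0, 0), (0, 0)] + [(p, p)] * self.dim
            x = np.pad(x, pad)
        if any(s < self.k for s in x.shape[2:]):
            raise ValueError(
                f"input spatial size {x.shape[2:]} below kernel {self.k} in valid-padding conv"
            )
        self._xp = x
        spatial_axes = tuple(range(2, 2 + self.dim))
        win = sliding_window_view(x, (self.k,) * self.dim, axis=spatial_axes)
        # win: (N, C, *S_out, *k); contract C and kernel dims with W
        axes_w = [1] + list(range(2 + self.dim, 2 + 2 * self.dim))
        y = np.tensordot(win, self.W.value, axes=(axes_w, list(range(1, 2 + self.dim))))
        y = np.moveaxis(y, -1, 1)
        return y + self.b.value.reshape((1, -1) + (1,) * self.dim)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xp = self._xp
        spatial_axes = tuple(range(2, 2 + self.dim))
        win = sliding_window_view(xp, (self.k,) * self.dim, axis=spatial_axes)
        # dW: contract over batch and output spatial positions
        axes_g = [0] + list(range(2, 2 + self.dim))
        dW = np.tensordot(g, win, axes=(axes_g, axes_g))  # (out_ch, C, *k)
        self.W.grad += dW
        self.b.grad += g.sum(axis=tuple([0] + list(spatial_axes)))
        # dx: full correlation of g with the flipped kernel
        p = self._pad_width()
        q = self.k - 1 - p
        gp = np.pad(g, [(0, 0), (0, 0)] + [(q, q)] * self.dim) if q else g
        winG = sliding_window_view(gp, (self.k,) * self.dim, axis=spatial_axes)
        Wf = np.flip(self.W.value, axis=tuple(range(2, 2 + self.dim)))
        Wf = np.swapaxes(Wf, 0, 1)  # (in_ch, out_ch, *k)
        axes_w = [1] + list(range(2 + self.dim, 2 + 2 * self.dim))
        # padding by k-1-p on each side makes the correlation output line up
        # with the original (unpadded) input grid directly
        dxp = np.tensordot(winG, Wf, axes=(axes_w, list(range(1, 2 + self.dim))))
        dxp = np.moveaxis(dxp, -1, 1)
        self._xp = None
        return dxp


class BatchNorm(Layer):
    """Per-channel batch normalisation with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple([0] + list(range(2, x.ndim)))
        shape = (1, -1) + (1,) * (x.ndim - 2)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean.reshape(shape)) * inv.reshape(shape)
        self._cache = (xhat, inv, axes, shape, x.shape)
        return self.gamma.value.reshape(shape) * xhat + self.beta.value.reshape(shape)

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape, xshape = self._cache
        m = np.prod([xshape[a] for a in axes])
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        gxhat = g * self.gamma.value.reshape(shape)
        dx = (
            gxhat
            - gxhat.mean(axis=axes).reshape(shape)
            - xhat * (gxhat * xhat).mean(axis=axes).reshape(shape)
        ) * inv.reshape(shape)
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        out = g * self._mask
        self._mask = None
        return out


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float, rng):
        self.p, self.rng = p, rng
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, g: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return g
        out = g * self._mask
        self._mask = None
        return out


def _blockify(x: np.ndarray, dim: int) -> np.ndarray:
    """(N, C, *2S) -> (N, C, *S, 2**dim) by factor-2 blocks."""
    n, c = x.shape[:2]
    s = [v // 2 for v in x.shape[2:]]
    if dim == 2:
        r = x.reshape(n, c, s[0], 2, s[1], 2)
        r = r.transpose(0, 1, 2, 4, 3, 5)
        return r.reshape(n, c, s[0], s[1], 4)
    r = x.reshape(n, c, s[0], 2, s[1], 2, s[2], 2)
    r = r.transpose(0, 1, 2, 4, 6, 3, 5, 7)
    return r.reshape(n, c, s[0], s[1], s[2], 8)


def _unblockify(blocks: np.ndarray, dim: int) -> np.ndarray:
    n, c = blocks.shape[:2]
    s = blocks.shape[2 : 2 + dim]
    if dim == 2:
        r = blocks.reshape(n, c, s[0], s[1], 2, 2)
        r = r.transpose(0, 1, 2, 4, 3, 5)
        return r.reshape(n, c, 2 * s[0], 2 * s[1])
    r = blocks.reshape(n, c, s[0], s[1], s[2], 2, 2, 2)
    r = r.transpose(0, 1, 2, 5, 3, 6, 4, 7)
    return r.reshape(n, c, 2 * s[0], 2 * s[1], 2 * s[2])


class MaxPool(Layer):
    """2x max pooling storing argmax indices for unpooling/backprop."""

    def __init__(self, dim: int):
        self.dim = dim
        self.idx = None
        self._in_shape = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if any(v % 2 for v in x.shape[2:]):
            raise ValueError(f"max pooling requires even spatial sizes, got {x.shape[2:]}")
        self._in_shape = x.shape
        blocks = _blockify(x, self.dim)
        self.idx = blocks.argmax(axis=-1)
        return np.take_along_axis(blocks, self.idx[..., None], axis=-1)[..., 0]

    def backward(self, g: np.ndarray) -> np.ndarray:
        blocks = np.zeros(g.shape + (2**self.dim,))
        np.put_along_axis(blocks, self.idx[..., None], g[..., None], axis=-1)
        return _unblockify(blocks, self.dim)


class MaxUnpool(Layer):
    """Upsample by placing values at the argmax indices stored by a pool."""

    def __init__(self, pool: MaxPool):
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        blocks = np.zeros(x.shape + (2**self.pool.dim,))
        np.put_along_axis(blocks, self.pool.idx[..., None], x[..., None], axis=-1)
        return _unblockify(blocks, self.pool.dim)

    def backward(self, g: np.ndarray) -> np.ndarray:
        blocks = _blockify(g, self.pool.dim)
        return np.take_along_axis(blocks, self.pool.idx[..., None], axis=-1)[..., 0]


class UpConv(Layer):
    """Transposed convolution with kernel 2, stride 2 (the up-convolution)."""

    def __init__(self, in_ch: int, out_ch: int, dim: int, rng):
        self.dim = dim
        fan_in = in_ch
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_ch, out_ch) + (2,) * dim))
        self.b = Param(np.zeros(out_ch))
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        # (N, Cin, *S) x (Cin, Cout, *2) -> (N, *S, Cout, *2)
        y = np.tensordot(x, self.W.value, axes=([1], [0]))
        y = np.moveaxis(y, 1 + self.dim, 1)  # (N, Cout, *S, *2)
        # interleave kernel offsets into the spatial grid
        blocks = y.reshape(y.shape[: 2 + self.dim] + (2**self.dim,))
        out = _unblockify(blocks, self.dim)
        return out + self.b.value.reshape((1, -1) + (1,) * self.dim)

    def backward(self, g: np.ndarray) -> np.ndarray:
        blocks = _blockify(g, self.dim)  # (N, Cout, *S, 2**dim)
        gy = blocks.reshape(blocks.shape[:-1] + (2,) * self.dim)  # (N,Cout,*S,*2)
        self.b.grad += g.sum(axis=tuple([0] + list(range(2, g.ndim))))
        x = self._x
        # dW: contract batch + spatial between x and gy
        axes_x = [0] + list(range(2, 2 + self.dim))
        axes_g = [0] + list(range(2, 2 + self.dim))
        dW = np.tensordot(x, gy, axes=(axes_x, axes_g))  # (Cin, Cout, *2)
        self.W.grad += dW
        # dx: contract Cout and kernel dims
        axes_gk = [1] + list(range(2 + self.dim, 2 + 2 * self.dim))
        axes_wk = [1] + list(range(2, 2 + self.dim))
        dx = np.tensordot(gy, self.W.value, axes=(axes_gk, axes_wk))  # (N, *S, Cin)
        self._x = None
        return np.moveaxis(dx, -1, 1)


class WeightedCrossEntropy:
    """Two-class softmax cross-entropy with per-class weights.

    ``weights = (w_background, w_canal)``; targets are {0,1} arrays of the
    spatial shape.  Probabilities are clipped to [eps, 1-eps].
    """

    def __init__(self, weights: tuple[float, float] = (1.0, 1.0), eps: float = 1e-7):
        self.weights = (float(weights[0]), float(weights[1]))
        self.eps = eps

    def loss_and_grad(self, logits: np.ndarray, target: np.ndarray):
        if logits.shape[1] != 2:
            raise ValueError("expected 2-class logits on channel axis 1")
        t = np.asarray(target)
        if t.shape != logits.shape[:1] + logits.shape[2:]:
            raise ValueError(f"target shape {t.shape} does not match logits {logits.shape}")
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        p = np.clip(p, self.eps, 1.0 - self.eps)
        w_bg, w_fg = self.weights
        wmap = np.where(t > 0, w_fg, w_bg)
        p_true = np.where(t > 0, p[:, 1], p[:, 0])
        n = t.size
        loss = -(wmap * np.log(p_true)).sum() / n
        onehot = np.stack([1.0 - t, t.astype(np.float64)], axis=1)
        grad = wmap[:, None] * (p - onehot) / n
        return loss, grad

    def probabilities(self, logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        return ez / ez.sum(axis=1, keepdims=True)


class Adam:
    """Adam optimizer over a list of :class:`Param`."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
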