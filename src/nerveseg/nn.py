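"""Minimal NumPy neural-network layers for 2-D segmentation.

Implements exactly the operators the encoder–decoder architecture needs:
3x3 'same' convolutions (im2col + BLAS matmul), ReLU, 2x2 max-pooling,
2x2 stride-2 learned transposed convolution, a 1x1 projection, and a fused
softmax + categorical cross-entropy head, together with the Adam update.
All arrays are float32, NCHW layout; every source of randomness is an
explicit ``numpy.random.Generator``, so runs are deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv3x3",
    "Conv1x1",
    "ReLU",
    "MaxPool2",
    "UpConv2",
    "softmax2",
    "softmax_xent_grad",
    "Adam",
]


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N, C*9, H*W) patch matrix for a padded 3x3 window."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, 3, 3, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return np.ascontiguousarray(view).reshape(n, c * 9, h * w)


def _col2im3(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col3` (scatter-add of patch gradients)."""
    n, c, h, w = shape
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    d = dcols.reshape(n, c, 3, 3, h, w)
    for i in range(3):
        for j in range(3):
            dxp[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dxp[:, :, 1 : 1 + h, 1 : 1 + w]


class Conv3x3:
    """3x3 convolution, stride 1, zero 'same' padding."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.w = _he_init(rng, (out_ch, in_ch * 9), fan_in=in_ch * 9)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, int, int, int] | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col3(x)
        out = np.matmul(self.w, cols) + self.b[:, None]
        if train:
            self._cols, self._xshape = cols, x.shape
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray):
        n, f, h, w = dout.shape
        d2 = dout.reshape(n, f, h * w)
        self.dw = np.einsum("nfp,ncp->fc", d2, self._cols, optimize=True)
        self.db = d2.sum(axis=(0, 2))
        dcols = np.matmul(self.w.T, d2)
        self._cols = None
        return _col2im3(dcols, self._xshape)

    @property
    def grads(self):
        return [self.dw, self.db]


class Conv1x1:
    """1x1 projection (per-pixel linear map across channels)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.w = _he_init(rng, (out_ch, in_ch), fan_in=in_ch)
        self.b = np.zeros(out_ch, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        x2 = x.reshape(n, c, h * w)
        out = np.matmul(self.w, x2) + self.b[:, None]
        if train:
            self._x2 = x2
        return out.reshape(n, -1, h, w)

    def backward(self, dout: np.ndarray):
        n, f, h, w = dout.shape
        d2 = dout.reshape(n, f, h * w)
        self.dw = np.einsum("nfp,ncp->fc", d2, self._x2, optimize=True)
        self.db = d2.sum(axis=(0, 2))
        dx = np.matmul(self.w.T, d2)
        self._x2 = None
        return dx.reshape(n, -1, h, w)

    @property
    def grads(self):
        return [self.dw, self.db]


class ReLU:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * self._mask
        self._mask = None
        return dx


class MaxPool2:
    """2x2 max pooling, stride 2. Input H, W must be even."""

    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        if train:
            self._mask = xr == out[:, :, :, None, :, None]
            self._shape = x.shape
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dx = self._mask * dout[:, :, :, None, :, None]
        self._mask = None
        return dx.reshape(n, c, h, w)


class UpConv2:
    """Learned 2x upsampling: transposed convolution, 2x2 kernel, stride 2."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.w = _he_init(rng, (in_ch, out_ch, 2, 2), fan_in=in_ch)
        self.b = np.zeros(out_ch, dtype=np.float32)

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        # (N,C,h,w) x (C,F,2,2) -> (N,h,w,F,2,2)
        t = np.tensordot(x, self.w, axes=([1], [0]))
        out = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, -1, 2 * h, 2 * w)
        out += self.b[None, :, None, None]
        if train:
            self._x = x
        return out

    def backward(self, dout: np.ndarray):
        n, f, h2, w2 = dout.shape
        h, w = h2 // 2, w2 // 2
        d6 = dout.reshape(n, f, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)  # (N,h,w,F,2,2)
        self.dw = np.tensordot(self._x, d6, axes=([0, 2, 3], [0, 1, 2]))  # (C,F,2,2)
        self.db = dout.sum(axis=(0, 2, 3))
        dx = np.tensordot(d6, self.w, axes=([3, 4, 5], [1, 2, 3]))  # (N,h,w,C)
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    @property
    def grads(self):
        return [self.dw, self.db]


def softmax2(logits: np.ndarray) -> np.ndarray:
    """Per-pixel softmax over the channel axis of an NCHW logit tensor."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent_grad(logits: np.ndarray, onehot: np.ndarray):
    """Fused softmax + categorical cross-entropy.

    Returns ``(loss, dlogits)`` where the loss is averaged over every pixel
    of the batch and ``dlogits`` is the gradient of that mean.
    """
    p = softmax2(logits)
    npix = logits.shape[0] * logits.shape[2] * logits.shape[3]
    loss = -float(np.sum(onehot * np.log(np.maximum(p, 1e-12)))) / npix
    dlogits = (p - onehot) / p.dtype.type(npix)
    return loss, dlogits


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updates in place)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * np.square(g)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
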