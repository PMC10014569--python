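"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the segmentation network needs: 'same'-padded convolutions
(stride 1 or 2), 2x transposed convolutions, ReLU, residual convolution
sets, and a pixel-wise softmax cross-entropy head.  All arrays are NCHW
float32; convolutions run through sliding-window views and tensordot so
the heavy lifting stays in BLAS.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2d",
    "ConvTranspose2d",
    "ReLU",
    "ResidualConvSet",
    "softmax",
    "softmax_cce",
]


def _same_pad(k: int) -> int:
    return (k - 1) // 2


def conv2d_forward(x, W, b, stride: int, pad: int):
    N, C, H, Wd = x.shape
    O, _, k, _ = W.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::stride, ::stride]
    out = np.tensordot(win, W, axes=([1, 4, 5], [1, 2, 3]))  # N,Ho,Wo,O
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2)) + b[None, :, None, None]
    return out, win


def conv2d_backward(dy, win, x_shape, W, stride: int, pad: int):
    N, C, H, Wd = x_shape
    O, _, k, _ = W.shape
    dW = np.tensordot(dy, win, axes=([0, 2, 3], [0, 2, 3]))  # O,C,k,k
    db = dy.sum(axis=(0, 2, 3))
    # dx: dilate dy by the stride, pad, correlate with the flipped kernel
    Ho, Wo = dy.shape[2:]
    dil_h, dil_w = stride * (Ho - 1) + 1, stride * (Wo - 1) + 1
    dyd = np.zeros((N, O, dil_h, dil_w), dtype=dy.dtype)
    dyd[:, :, ::stride, ::stride] = dy
    pl = k - 1 - pad
    pr_h = H + k - 1 - dil_h - pl
    pr_w = Wd + k - 1 - dil_w - pl
    dyp = np.pad(dyd, ((0, 0), (0, 0), (pl, pr_h), (pl, pr_w)))
    wflip = W[:, :, ::-1, ::-1]
    win2 = sliding_window_view(dyp, (k, k), axis=(2, 3))
    dx = np.tensordot(win2, wflip, axes=([1, 4, 5], [0, 2, 3]))  # N,H,W,C
    return np.ascontiguousarray(dx.transpose(0, 3, 1, 2)), dW, db


class Layer:
    def parameters(self):
        return []

    def forward(self, x):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv2d(Layer):
    """'same'-padded kxk convolution, stride 1 or 2, He-initialized."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 1, rng=None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * k * k))
        self.W = (rng.standard_normal((cout, cin, k, k)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.k, self.stride, self.pad = k, stride, _same_pad(k)
        self._cache = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        out, win = conv2d_forward(x, self.W, self.b, self.stride, self.pad)
        self._cache = (win, x.shape)
        return out

    def backward(self, dy):
        win, x_shape = self._cache
        dx, dW, db = conv2d_backward(dy, win, x_shape, self.W, self.stride, self.pad)
        self.dW += dW
        self.db += db
        return dx


class ConvTranspose2d(Layer):
    """2x2 stride-2 transposed convolution (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng=None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / (cin * 4))
        self.W = (rng.standard_normal((cin, cout, 2, 2)) * scale).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def parameters(self):
        return [(self.W, self.dW), (self.b, self.db)]

    def forward(self, x):
        N, C, H, Wd = x.shape
        t = np.tensordot(x, self.W, axes=(1, 0))  # N,H,W,O,2,2
        O = self.W.shape[1]
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(N, O, 2 * H, 2 * Wd)
        self._cache = x
        return y + self.b[None, :, None, None]

    def backward(self, dy):
        x = self._cache
        N, C, H, Wd = x.shape
        O = self.W.shape[1]
        d = dy.reshape(N, O, H, 2, Wd, 2).transpose(0, 2, 4, 1, 3, 5)  # N,H,W,O,2,2
        self.db += dy.sum(axis=(0, 2, 3))
        self.dW += np.tensordot(x, d, axes=([0, 2, 3], [0, 1, 2]))
        dx = np.tensordot(d, self.W, axes=([3, 4, 5], [1, 2, 3]))  # N,H,W,C
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))


class ReLU(Layer):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return np.where(self._mask, dy, 0.0)


class ResidualConvSet(Layer):
    """Two 3x3 conv+ReLU with an identity shortcut around the pair.

    When the channel count changes, the shortcut is a 1x1 projection.
    The shortcut is added after the second activation.
    """

    def __init__(self, cin: int, cout: int, rng=None):
        self.conv1 = Conv2d(cin, cout, 3, 1, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(cout, cout, 3, 1, rng)
        self.relu2 = ReLU()
        self.proj = Conv2d(cin, cout, 1, 1, rng) if cin != cout else None

    def parameters(self):
        out = self.conv1.parameters() + self.conv2.parameters()
        if self.proj is not None:
            out += self.proj.parameters()
        return out

    def forward(self, x):
        h = self.relu2.forward(self.conv2.forward(self.relu1.forward(self.conv1.forward(x))))
        s = self.proj.forward(x) if self.proj is not None else x
        return h + s

    def backward(self, dy):
        ds = self.proj.backward(dy) if self.proj is not None else dy
        dx = self.conv1.backward(
            self.relu1.backward(self.conv2.backward(self.relu2.backward(dy)))
        )
        return dx + ds


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def softmax_cce(logits: np.ndarray, target: np.ndarray):
    """Pixel-wise two-class categorical cross entropy.

    ``logits``: (N, 2, H, W); ``target``: (N, H, W) bool (True = vessel).
    Returns (mean loss, dlogits).
    """
    p = softmax(logits, axis=1)
    t = target.astype(np.int64)
    n_pix = t.size
    eps = 1e-12
    p_true = np.take_along_axis(p, t[:, None], axis=1)[:, 0]
    loss = float(-np.log(p_true + eps).mean())
    onehot = np.stack([1 - t, t], axis=1).astype(p.dtype)
    dlogits = (p - onehot) / n_pix
    return loss, dlogits
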