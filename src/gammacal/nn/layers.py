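"""Layers with explicit forward/backward passes.

Every layer caches what its backward pass needs during ``forward`` and
exposes trainable arrays in ``params`` with matching gradients in ``grads``.
Convolutions use im2col so the heavy lifting is a single matrix product.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Conv2D", "ConvTranspose2D", "MaxPool2D", "ReLU"]


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*kh*kw) patch matrix for same-padded conv."""
    n, c, h, w = x.shape
    ph, pw = kh // 2, kw // 2
    xp = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw) -> matrix
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)


def _col2im(dcols: np.ndarray, shape: tuple, kh: int, kw: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients back."""
    n, c, h, w = shape
    ph, pw = kh // 2, kw // 2
    d = dcols.reshape(n, h, w, c, kh, kw)
    dxp = np.zeros((n, c, h + 2 * ph, w + 2 * pw))
    for a in range(kh):
        for b in range(kw):
            dxp[:, :, a : a + h, b : b + w] += d[:, :, :, :, a, b].transpose(0, 3, 1, 2)
    if ph == 0 and pw == 0:
        return dxp
    return dxp[:, :, ph : ph + h, pw : pw + w]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}


class Conv2D(Layer):
    """Same-padded stride-1 convolution, odd square kernel."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel * kernel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_channels, fan_in))
        self.params = {"W": w, "b": np.zeros(out_channels)}
        self.grads = {"W": np.zeros_like(w), "b": np.zeros(out_channels)}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        cols = _im2col(x, self.kernel, self.kernel)
        y = cols @ self.params["W"].T + self.params["b"]
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, xshape = self._cache
        n, c, h, w = xshape
        dmat = dy.transpose(0, 2, 3, 1).reshape(n * h * w, self.out_channels)
        self.grads["W"] += dmat.T @ cols
        self.grads["b"] += dmat.sum(axis=0)
        dcols = dmat @ self.params["W"]
        return _col2im(dcols, xshape, self.kernel, self.kernel)


class ConvTranspose2D(Layer):
    """2x2 stride-2 transposed convolution (the up-convolution)."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = in_channels  # each output pixel sees one input pixel per in-channel
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_channels, out_channels, 2, 2))
        self.params = {"W": w, "b": np.zeros(out_channels)}
        self.grads = {"W": np.zeros_like(w), "b": np.zeros(out_channels)}
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        t = np.tensordot(x, self.params["W"], axes=([1], [0]))  # (N, H, W, F, 2, 2)
        y = t.transpose(0, 3, 1, 4, 2, 5).reshape(n, self.out_channels, 2 * h, 2 * w)
        y += self.params["b"][None, :, None, None]
        self._cache = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        n, c, h, w = x.shape
        dt = dy.reshape(n, self.out_channels, h, 2, w, 2).transpose(0, 2, 4, 1, 3, 5)
        self.grads["W"] += np.tensordot(x, dt, axes=([0, 2, 3], [0, 1, 2]))
        self.grads["b"] += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dt, self.params["W"], axes=([3, 4, 5], [1, 2, 3]))
        return dx.transpose(0, 3, 1, 2)


class MaxPool2D(Layer):
    """2x2 max pooling, stride 2; ties route the gradient to the first
    maximal element (numpy argmax convention)."""

    def __init__(self):
        super().__init__()
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError("max pooling requires even spatial dimensions")
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = xr.argmax(axis=-1)
        y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, c, h, w) = self._cache
        dxr = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dxr, idx[..., None], dy[..., None], axis=-1)
        dxr = dxr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(n, c, h, w)


class ReLU(Layer):
    def __init__(self):
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0)
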