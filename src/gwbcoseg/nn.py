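"""Minimal numpy CNN engine: the layers a 2-D U-Net needs, with backprop.

Layers operate on NCHW float arrays.  Each parameterized layer owns its
weight arrays and matching gradient buffers; ``forward(x, train=True)``
caches what the matching ``backward(dout)`` needs.  Convolutions are
evaluated as an im2col matrix product; the 2×2 stride-2 pool and up-conv
exploit the non-overlapping geometry (pure reshapes / einsums), which keeps
a 64×64 forward pass in the low milliseconds on one CPU core.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit


class Layer:
    """Base: parameterized layers expose params/grads dicts by name."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0


class Conv2d(Layer):
    """k×k convolution, stride 1, 'same' padding for odd k (pad=(k-1)//2)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        self.cin, self.cout, self.k = cin, cout, k
        self.pad = (k - 1) // 2
        fan_in = cin * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, k, k))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def _windows(self, x: np.ndarray) -> np.ndarray:
        """(N, C, H, W, k, k) sliding windows of the 'same'-padded input."""
        p = self.pad
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        return sliding_window_view(x, (self.k, self.k), axis=(2, 3))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        win = self._windows(x)
        out = np.einsum("nchwab,ocab->nohw", win, self.W,
                        optimize=True) + self.b[:, None, None]
        if train:
            self._cache = win
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        win = self._cache
        self.dW += np.einsum("nchwab,nohw->ocab", win, dout, optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        # gradient wrt the input of a stride-1 'same' conv is the 'same' conv
        # of dout with the spatially flipped, channel-transposed kernel
        p = self.pad
        if p:
            dout = np.pad(dout, ((0, 0), (0, 0), (p, p), (p, p)))
        dwin = sliding_window_view(dout, (self.k, self.k), axis=(2, 3))
        return np.einsum("nohwab,ocab->nchw", dwin,
                         self.W[:, :, ::-1, ::-1], optimize=True)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool2(Layer):
    """2×2 max pooling, stride 2 (input H, W must be even)."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        idx = flat.argmax(axis=-1)
        out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, x.shape)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        idx, xshape = self._cache
        n, c, h, w = xshape
        dflat = np.zeros((n, c, h // 2, w // 2, 4))
        np.put_along_axis(dflat, idx[..., None], dout[..., None], axis=-1)
        return dflat.reshape(n, c, h // 2, w // 2, 2, 2
                             ).transpose(0, 1, 2, 4, 3, 5).reshape(xshape)


class UpConv2(Layer):
    """2×2 transposed convolution, stride 2: doubles spatial resolution."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        fan_in = cin
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(cin, cout, 2, 2))
        self.b = np.zeros(cout)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, _, h, w = x.shape
        out = np.einsum("nchw,coab->nohawb", x, self.W, optimize=True)
        out = out.reshape(n, self.cout, 2 * h, 2 * w) + self.b[:, None, None]
        if train:
            self._x = x
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, _, h2, w2 = dout.shape
        d = dout.reshape(n, self.cout, h2 // 2, 2, w2 // 2, 2)
        self.dW += np.einsum("nchw,nohawb->coab", self._x, d, optimize=True)
        self.db += dout.sum(axis=(0, 2, 3))
        return np.einsum("nohawb,coab->nchw", d, self.W, optimize=True)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


def bce_dice_loss(logits: np.ndarray, target: np.ndarray,
                  dice_weight: float = 1.0, eps: float = 1.0
                  ) -> tuple[float, np.ndarray]:
    """Pixelwise binary cross-entropy plus soft-Dice loss.

    The Dice term counters the severe foreground/background imbalance of
    organ masks; eps smooths the empty-mask case.  Returns (loss, dL/dlogits).
    """
    s = sigmoid(logits)
    npix = logits.size
    # numerically stable BCE on logits
    bce = float(np.mean(np.maximum(logits, 0) - logits * target
                        + np.log1p(np.exp(-np.abs(logits)))))
    inter = float((s * target).sum())
    denom = float(s.sum() + target.sum())
    dice = (2.0 * inter + eps) / (denom + eps)
    loss = bce + dice_weight * (1.0 - dice)
    dbce = (s - target) / npix
    # d(1 - dice)/ds, then chain through the sigmoid
    ddice_ds = -(2.0 * target * (denom + eps) - (2.0 * inter + eps)) / (denom + eps) ** 2
    dlogits = dbce + dice_weight * ddice_ds * s * (1.0 - s)
    return loss, dlogits


class Adam:
    """Adaptive-moment gradient descent over a list of (param, grad) pairs."""

    def __init__(self, pairs: list[tuple[np.ndarray, np.ndarray]],
                 lr: float = 1e-4, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.pairs = pairs
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p, _ in pairs]
        self.v = [np.zeros_like(p) for p, _ in pairs]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (p, g) in enumerate(self.pairs):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
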