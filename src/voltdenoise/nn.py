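"""Minimal convolutional-network engine (numpy, hand-written backprop).

Implements exactly the pieces the denoiser needs: same-padding 2-D
convolutions (im2col + BLAS matmul), batch normalization, PReLU with a
learnable per-channel slope, residual blocks, and the Adam optimizer.
Arrays are NCHW, float32 by default (float64 available for gradient
checks). Forward passes cache what backward needs; calling ``backward`` is
only valid after a training-mode forward.

The engine is deliberately small — a fixed feed-forward topology rather
than a general autograd graph — which keeps the arithmetic transparent and
testable against finite differences.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv2d", "BatchNorm2d", "PReLU", "ResidualBlock", "DenoiserNet", "Adam"]


class Conv2d:
    """3x3 (or any odd k) same-convolution with zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dtype=np.float32):
        if kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel_size
        self.dtype = dtype
        fan_in = in_channels * kernel_size * kernel_size
        # He-normal initialization suits the PReLU family
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, out_channels)).astype(dtype)
        self.b = np.zeros(out_channels, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        B, C, H, W = x.shape
        if C != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {C}")
        p = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (self.k, self.k), axis=(2, 3))  # B,C,H,W,k,k
        cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(B * H * W, C * self.k * self.k)
        y = cols @ self.W + self.b
        if training:
            self._cache = (cols, (B, C, H, W))
        return y.reshape(B, H, W, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (B, C, H, W) = self._cache
        dyr = dy.transpose(0, 2, 3, 1).reshape(-1, self.cout)
        self.dW += cols.T @ dyr
        self.db += dyr.sum(axis=0)
        dcols = (dyr @ self.W.T).reshape(B, H, W, C, self.k, self.k)
        p = self.k // 2
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=dcols.dtype)
        dct = dcols.transpose(0, 3, 1, 2, 4, 5)  # B,C,H,W,k,k
        for i in range(self.k):
            for j in range(self.k):
                dxp[:, :, i : i + H, j : j + W] += dct[:, :, :, :, i, j]
        return dxp[:, :, p : p + H, p : p + W]

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm2d:
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 dtype=np.float32):
        self.gamma = np.ones(channels, dtype=dtype)
        self.beta = np.zeros(channels, dtype=dtype)
        self.dgamma = np.zeros(channels, dtype=dtype)
        self.dbeta = np.zeros(channels, dtype=dtype)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.eps, self.momentum = eps, momentum
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        if training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        if training:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        B, C, H, W = dy.shape
        n = B * H * W
        self.dgamma += (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta += dy.sum(axis=(0, 2, 3))
        dxhat = dy * self.gamma[None, :, None, None]
        s1 = dxhat.sum(axis=(0, 2, 3), keepdims=True)
        s2 = (dxhat * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv_std[None, :, None, None] / n) * (n * dxhat - s1 - xhat * s2)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class PReLU:
    """Rectifier with a learnable per-channel negative slope."""

    def __init__(self, channels: int, init: float = 0.25, dtype=np.float32):
        self.a = np.full(channels, init, dtype=dtype)
        self.da = np.zeros(channels, dtype=dtype)
        self._cache = None

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        pos = x > 0
        if training:
            self._cache = (x, pos)
        return np.where(pos, x, self.a[None, :, None, None] * x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, pos = self._cache
        neg = ~pos
        self.da += (dy * x * neg).sum(axis=(0, 2, 3))
        return dy * np.where(pos, 1.0, self.a[None, :, None, None])

    def params(self):
        return {"a": self.a}

    def grads(self):
        return {"a": self.da}


class ResidualBlock:
    """conv-BN-PReLU-conv-BN with an identity skip from input to output."""

    def __init__(self, channels: int, kernel_size: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.conv1 = Conv2d(channels, channels, kernel_size, rng, dtype)
        self.bn1 = BatchNorm2d(channels, dtype=dtype)
        self.act = PReLU(channels, dtype=dtype)
        self.conv2 = Conv2d(channels, channels, kernel_size, rng, dtype)
        self.bn2 = BatchNorm2d(channels, dtype=dtype)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.act.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        return x + h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.bn2.backward(dy)
        dh = self.conv2.backward(dh)
        dh = self.act.backward(dh)
        dh = self.bn1.backward(dh)
        dh = self.conv1.backward(dh)
        return dy + dh

    def sublayers(self):
        return {"conv1": self.conv1, "bn1": self.bn1, "act": self.act,
                "conv2": self.conv2, "bn2": self.bn2}


class DenoiserNet:
    """Lead-in conv -> n residual blocks -> lead-out conv to one channel."""

    def __init__(
        self,
        in_channels: int,
        feature_width: int = 64,
        n_blocks: int = 4,
        kernel_size: int = 3,
        rng: np.random.Generator | None = None,
        dtype=np.float32,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.in_channels = in_channels
        self.feature_width = feature_width
        self.kernel_size = kernel_size
        self.dtype = dtype
        self.conv_in = Conv2d(in_channels, feature_width, kernel_size, rng, dtype)
        self.blocks = [ResidualBlock(feature_width, kernel_size, rng, dtype) for _ in range(n_blocks)]
        self.conv_out = Conv2d(feature_width, 1, kernel_size, rng, dtype)

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        h = self.conv_in.forward(np.asarray(x, dtype=self.dtype), training)
        for blk in self.blocks:
            h = blk.forward(h, training)
        return self.conv_out.forward(h, training)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dh = self.conv_out.backward(dy)
        for blk in reversed(self.blocks):
            dh = blk.backward(dh)
        return self.conv_in.backward(dh)

    def _layers(self) -> dict[str, object]:
        layers = {"conv_in": self.conv_in, "conv_out": self.conv_out}
        for i, blk in enumerate(self.blocks):
            for name, sub in blk.sublayers().items():
                layers[f"block{i}.{name}"] = sub
        return layers

    def params(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": arr
                for ln, layer in self._layers().items()
                for pn, arr in layer.params().items()}

    def grads(self) -> dict[str, np.ndarray]:
        return {f"{ln}.{pn}": arr
                for ln, layer in self._layers().items()
                for pn, arr in layer.grads().items()}

    def zero_grad(self) -> None:
        for g in self.grads().values():
            g[...] = 0.0

    def state_dict(self) -> dict[str, np.ndarray]:
        out = dict(self.params())
        for ln, layer in self._layers().items():
            if isinstance(layer, BatchNorm2d):
                for sn, arr in layer.state().items():
                    out[f"{ln}.{sn}"] = arr
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.params())
        for ln, layer in self._layers().items():
            if isinstance(layer, BatchNorm2d):
                for sn, arr in layer.state().items():
                    own[f"{ln}.{sn}"] = arr
        for key, target in own.items():
            if key not in state:
                raise KeyError(f"missing parameter {key} in state dict")
            target[...] = state[key]


class Adam:
    """Adam with bias correction; the learning rate may change per step."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
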