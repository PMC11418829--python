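"""Minimal deterministic 3D convolutional network engine (NumPy, CPU).

Implements exactly the pieces the cardiac architecture needs: 3D
convolution with TensorFlow-style "same" padding and ceil-mode output
sizing, per-channel batch normalization, ReLU, inverted dropout, flatten,
dense layers, softmax cross-entropy, and Adam.  Samples are processed one
at a time (the training batch size is 1), with data layout (T, H, W, C).

All randomness (weight init, dropout masks) flows from a single
``numpy.random.Generator``, so training is bit-reproducible given a seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Conv3D", "BatchNorm", "ReLU", "Dropout", "Flatten", "Dense",
           "Network", "Adam", "softmax", "softmax_cross_entropy",
           "same_pad_amount", "conv_output_size"]


def conv_output_size(size: int, stride: int) -> int:
    """Output extent of a same-padded convolution with ceil-mode sizing."""
    return -(-size // stride)


def same_pad_amount(size: int, kernel: int, stride: int) -> tuple[int, int]:
    out = conv_output_size(size, stride)
    total = max((out - 1) * stride + kernel - size, 0)
    before = total // 2
    return before, total - before


class Layer:
    """Base layer: forward(x, train) -> y; backward(dy) -> dx."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3D(Layer):
    """Same-padded strided 3D convolution over a (T, H, W, C) sample.

    The kernel's first axis convolves the temporal dimension, the other
    two the spatial dimensions.  He-normal initialization.
    """

    def __init__(self, in_channels: int, out_channels: int,
                 kernel: tuple[int, int, int] = (3, 3, 3),
                 stride: tuple[int, int, int] = (1, 1, 1),
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.stride = stride
        self.in_channels = in_channels
        self.out_channels = out_channels
        fan_in = int(np.prod(kernel)) * in_channels
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(*kernel, in_channels, out_channels))
        self.W = w.astype(np.float64)
        self.b = np.zeros(out_channels)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        pads = [same_pad_amount(x.shape[i], self.kernel[i], self.stride[i])
                for i in range(3)]
        xp = np.pad(x, (*pads, (0, 0)))
        win = sliding_window_view(xp, (kt, kh, kw), axis=(0, 1, 2))
        win = win[::st, ::sh, ::sw]                     # (Ot,Oh,Ow,C,kt,kh,kw)
        cols = np.ascontiguousarray(np.moveaxis(win, 3, -1))  # (...,kt,kh,kw,C)
        ot, oh, ow = cols.shape[:3]
        flat = cols.reshape(ot * oh * ow, -1)
        wm = self.W.reshape(-1, self.out_channels)
        out = flat @ wm + self.b
        if train:
            self._cache = (flat, xp.shape, (ot, oh, ow), pads, x.shape)
        return out.reshape(ot, oh, ow, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        flat, xp_shape, (ot, oh, ow), pads, x_shape = self._cache
        kt, kh, kw = self.kernel
        st, sh, sw = self.stride
        dout = dy.reshape(-1, self.out_channels)
        wm = self.W.reshape(-1, self.out_channels)
        self.grads[0][...] = (flat.T @ dout).reshape(self.W.shape)
        self.grads[1][...] = dout.sum(axis=0)
        dcols = (dout @ wm.T).reshape(ot, oh, ow, kt, kh, kw, self.in_channels)
        dxp = np.zeros(xp_shape)
        for a in range(kt):
            for b_ in range(kh):
                for c in range(kw):
                    dxp[a:a + ot * st:st,
                        b_:b_ + oh * sh:sh,
                        c:c + ow * sw:sw] += dcols[:, :, :, a, b_, c, :]
        (p0, _), (p1, _), (p2, _) = pads
        return dxp[p0:p0 + x_shape[0], p1:p1 + x_shape[1], p2:p2 + x_shape[2]]


class BatchNorm(Layer):
    """Per-channel normalization over all positions of the sample.

    With a training batch of one this normalizes each channel over the
    sample's spatiotemporal positions; running statistics (momentum 0.1)
    are used at inference.
    """

    def __init__(self, channels: int, momentum: float = 0.1,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if train:
            self._cache = (xhat, inv, axes, x.shape)
        return self.gamma * xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv, axes, shape = self._cache
        n = int(np.prod([shape[a] for a in axes]))
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        dxhat = dy * self.gamma
        return (inv / n) * (n * dxhat - dxhat.sum(axis=axes)
                            - xhat * (dxhat * xhat).sum(axis=axes))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / in_features),
                            size=(in_features, out_features))
        self.b = np.zeros(out_features)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0][...] = np.outer(self._x, dy)
        self.grads[1][...] = dy
        return dy @ self.W.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def softmax_cross_entropy(logits: np.ndarray, target: int) -> tuple[float, np.ndarray]:
    """Loss and gradient w.r.t. logits for one sample."""
    p = softmax(logits)
    loss = -float(np.log(max(p[target], 1e-300)))
    grad = p.copy()
    grad[target] -= 1.0
    return loss, grad


class Network:
    """An ordered, named stack of layers with shared RNG."""

    def __init__(self, layers: list[tuple[str, Layer]]) -> None:
        self.layers = layers
        self._by_name = dict(layers)
        if len(self._by_name) != len(layers):
            raise ValueError("layer names must be unique")

    def forward(self, x: np.ndarray, train: bool = False,
                upto: str | None = None) -> np.ndarray:
        """Run the stack; optionally stop after (and return) layer ``upto``."""
        for name, layer in self.layers:
            x = layer.forward(x, train)
            if upto is not None and name == upto:
                return x
        if upto is not None:
            raise KeyError(f"no layer named {upto!r}")
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for _, layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def parameters(self) -> list[np.ndarray]:
        return [p for _, l in self.layers for p in l.params]

    @property
    def gradients(self) -> list[np.ndarray]:
        return [g for _, l in self.layers for g in l.grads]


class Adam:
    """Adam optimizer over a fixed parameter list (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m += (1 - self.beta1) * (g - m)
            v += (1 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
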