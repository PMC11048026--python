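"""Minimal feed-forward neural-network engine on numpy.

Provides exactly the layer vocabulary the model observers need — 3x3
size-preserving convolutions, dense layers, LeakyReLU, sigmoid — with
manual backpropagation, Adam, and binary/pixelwise cross-entropy losses.
Everything runs in float32; convolutions use im2col so the inner loops are
BLAS matrix products.  All randomness (initialization, shuffling) flows
through an explicit numpy Generator, so training is reproducible for a
fixed seed and thread configuration.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Dense",
    "Conv2D",
    "LeakyReLU",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Sequential",
    "Adam",
    "bce_loss",
    "mse_loss",
    "iterate_minibatches",
]

_F32 = np.float32


def _init_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """Uniform fan-in scaled initialization, U(-1/sqrt(fan_in), +1/sqrt(fan_in))."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(_F32)


class Layer:
    """Base layer: forward caches what backward needs; params/grads exposed."""

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, g):  # pragma: no cover - abstract
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = _init_uniform(rng, (n_in, n_out), n_in)
        self.b = np.zeros(n_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.dW[...] = self._x.T @ g
        self.db[...] = g.sum(axis=0)
        return g @ self.W.T

    @property
    def weight_matrices(self):
        return [self.W]


class Conv2D(Layer):
    """k x k convolution with zero padding (size-preserving), NHWC layout.

    Implemented as a sum of k*k channel-mixing matrix products over shifted
    slices of the padded input, which keeps the inner loop in BLAS without
    materializing an im2col patch matrix.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator, kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd to preserve spatial size")
        self.k = kernel
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * kernel * kernel
        self.W = _init_uniform(rng, (kernel, kernel, c_in, c_out), fan_in)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        #: set False on a network's first layer to skip the input gradient
        self.needs_input_grad = True

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        B, H, W, C = x.shape
        if C != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {C}")
        p = self.k // 2
        self._xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        self._hw = (H, W)
        if self.c_in == 1:
            # single input channel: one im2col matrix product is cheaper
            # than accumulating k*k shifted products into a wide output
            win = np.lib.stride_tricks.sliding_window_view(
                self._xp[..., 0], (self.k, self.k), axis=(1, 2)
            )
            self._cols = win.reshape(B * H * W, self.k * self.k)
            y = self._cols @ self.W.reshape(self.k * self.k, self.c_out) + self.b
            return y.reshape(B, H, W, self.c_out)
        out = np.broadcast_to(self.b, (B, H, W, self.c_out)).copy()
        for dy in range(self.k):
            for dx in range(self.k):
                out += self._xp[:, dy : dy + H, dx : dx + W, :] @ self.W[dy, dx]
        return out

    def backward(self, g):
        H, W = self._hw
        p = self.k // 2
        k = self.k
        self.db[...] = g.sum(axis=(0, 1, 2))
        if self.c_out == 1 and self.c_in > 1:
            # single output channel: both gradients collapse to one im2col
            # product with the (single-channel) upstream gradient
            B = g.shape[0]
            gp = np.pad(g[..., 0], ((0, 0), (p, p), (p, p)))
            gwin = np.lib.stride_tricks.sliding_window_view(
                np.pad(gp, ((0, 0), (p, p), (p, p))), (k, k), axis=(1, 2)
            )  # (B, H+2p, W+2p, k, k) aligned to padded-input positions
            g_cols = gwin.reshape(B * (H + 2 * p) * (W + 2 * p), k * k)
            xp_flat = self._xp.reshape(-1, self.c_in)
            # dW[dy,dx,c] = sum_n xp[n + (dy,dx)] * g[n]
            dW = (g_cols.T @ xp_flat).reshape(k, k, self.c_in)[::-1, ::-1]
            self.dW[...] = dW[..., None]
            if not self.needs_input_grad:
                return None
            gwin2 = np.lib.stride_tricks.sliding_window_view(
                gp, (k, k), axis=(1, 2)
            )  # (B, H, W, k, k)
            g_cols2 = gwin2.reshape(B * H * W, k * k)
            Wback = self.W[::-1, ::-1, :, 0].reshape(k * k, self.c_in)
            return (g_cols2 @ Wback).reshape(B, H, W, self.c_in)
        if self.c_in == 1:
            g_flat = g.reshape(-1, self.c_out)
            self.dW[...] = (self._cols.T @ g_flat).reshape(k, k, 1, self.c_out)
            if not self.needs_input_grad:
                return None
            gp = np.pad(g, ((0, 0), (p, p), (p, p), (0, 0)))
            dx = np.zeros((g.shape[0], H, W, 1), dtype=_F32)
            for dy in range(k):
                for dx_ in range(k):
                    dx += gp[:, k - 1 - dy : k - 1 - dy + H,
                             k - 1 - dx_ : k - 1 - dx_ + W, :] @ self.W[dy, dx_].T
            return dx
        gp = None
        dx = None
        if self.needs_input_grad:
            gp = np.pad(g, ((0, 0), (p, p), (p, p), (0, 0)))
            dx = np.zeros((g.shape[0], H, W, self.c_in), dtype=_F32)
        for dy in range(k):
            for dx_ in range(k):
                xs = self._xp[:, dy : dy + H, dx_ : dx_ + W, :]
                self.dW[dy, dx_] = np.tensordot(xs, g, axes=([0, 1, 2], [0, 1, 2]))
                if dx is not None:
                    # transposed convolution: flipped kernel, channels swapped
                    dx += gp[:, k - 1 - dy : k - 1 - dy + H,
                             k - 1 - dx_ : k - 1 - dx_ + W, :] @ self.W[dy, dx_].T
        return dx

    @property
    def weight_matrices(self):
        return [self.W]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = _F32(slope)

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, g):
        return np.where(self._mask, g, self.slope * g)


class Sigmoid(Layer):
    def forward(self, x):
        # clamp pre-activations so float32 output stays strictly inside (0, 1)
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -15.0, 15.0)))
        return self._y

    def backward(self, g):
        return g * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class Reshape(Layer):
    """Reshape (B, n) -> (B, *target) for dense-to-conv transitions."""

    def __init__(self, target: tuple[int, ...]):
        self.target = target

    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], *self.target)

    def backward(self, g):
        return g.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
            if g is None:  # first layer skipped its input gradient
                break
        return g

    def weight_matrices(self):
        """Weight matrices of parametric layers (biases excluded), recursive."""
        out = []
        for layer in self.layers:
            if isinstance(layer, Sequential):
                out += layer.weight_matrices()
            else:
                out += getattr(layer, "weight_matrices", [])
        return out

    def weight_sq_norm(self) -> float:
        return float(sum(np.sum(w.astype(np.float64) ** 2)
                         for w in self.weight_matrices()))


class Adam:
    """Adam optimizer over a fixed parameter list (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= (self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)).astype(p.dtype)


_EPS = 1e-7


def bce_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Binary cross-entropy, mean over all elements; returns (loss, dL/dpred)."""
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    t = target
    loss = float(-np.mean(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)))
    grad = ((p - t) / (p * (1.0 - p)) / p.size).astype(_F32)
    return loss, grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    loss = float(np.mean(diff**2))
    grad = (2.0 * diff / diff.size).astype(_F32)
    return loss, grad


def iterate_minibatches(n: int, batch_size: int, rng: np.random.Generator):
    """Yield shuffled index arrays covering range(n)."""
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]
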