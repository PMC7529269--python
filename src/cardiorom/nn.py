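"""Minimal feedforward/convolutional network stack with reverse-mode
gradients, written on numpy.

Only what the DL-ROM needs is provided: dense layers, strided 2D
convolutions and transposed convolutions (im2col based), ELU activations,
a sequential container and an Adam optimizer.  Gradients are exact
(checked against finite differences in the test suite).  All computation
is float64 and deterministic given the seeded initializer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class; layers own parameter arrays and matching gradient slots."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._neg = x < 0
        self._y = np.where(self._neg, self.alpha * np.expm1(x), x)
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * np.where(self._neg, self._y + self.alpha, 1.0)


class Reshape(Layer):
    def __init__(self, shape_out: tuple[int, ...]) -> None:
        super().__init__()
        self.shape_out = shape_out

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape_in = x.shape
        return x.reshape((x.shape[0], *self.shape_out))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape_in)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape_in = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape_in)


def _im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(B, C, H, W) -> (B, Ho, Wo, C, k, k) strided patches (view-copy)."""
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (B, C, H', W', k, k)
    win = win[:, :, ::stride, ::stride]
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))


class Conv2D(Layer):
    """Strided convolution with symmetric zero padding p = (k - 1) // 2.

    Output size is floor((H + 2p - k) / stride) + 1; for even H, odd k and
    stride 2 this halves the spatial size.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_in, k, k, c_out))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_size(self, h: int) -> int:
        return (h + 2 * self.pad - self.k) // self.stride + 1

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, H, Wd = x.shape
        cols = _im2col(x, self.k, self.stride, self.pad)  # (B,Ho,Wo,C,k,k)
        self._cols_shape = cols.shape
        self._cols = cols.reshape(B, cols.shape[1], cols.shape[2], -1)
        self._x_shape = x.shape
        y = self._cols @ self.W.reshape(-1, self.c_out) + self.b
        return y.transpose(0, 3, 1, 2)  # (B, c_out, Ho, Wo)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, _, Ho, Wo = dy.shape
        dyt = dy.transpose(0, 2, 3, 1)  # (B, Ho, Wo, c_out)
        self.grads[0] += (
            np.tensordot(self._cols, dyt, axes=([0, 1, 2], [0, 1, 2]))
        ).reshape(self.W.shape)
        self.grads[1] += dyt.sum(axis=(0, 1, 2))
        dcols = (dyt @ self.W.reshape(-1, self.c_out).T).reshape(self._cols_shape)
        # scatter patches back (col2im)
        _, C, H, Wd = self._x_shape
        xp = np.zeros((B, C, H + 2 * self.pad, Wd + 2 * self.pad))
        dcols_t = dcols.transpose(0, 3, 1, 2, 4, 5)  # (B, C, Ho, Wo, k, k)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                xp[:, :, i : i + s * Ho : s, j : j + s * Wo : s] += dcols_t[
                    :, :, :, :, i, j
                ]
        p = self.pad
        return xp[:, :, p : p + H, p : p + Wd]


class ConvTranspose2D(Layer):
    """Transposed (fractionally-strided) convolution, the adjoint of Conv2D.

    Output size is (H - 1) * stride - 2p + k + output_padding; with the
    same k, stride and p as the mirrored Conv2D and output_padding chosen
    as stride - 1 (for odd k) it exactly doubles the spatial size.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator, output_padding: int | None = None
                 ) -> None:
        super().__init__()
        self.k, self.stride, self.pad = k, stride, (k - 1) // 2
        self.op = stride - 1 if output_padding is None else output_padding
        self.c_in, self.c_out = c_in, c_out
        fan_in = c_in * k * k
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_in, c_out, k, k))
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def out_size(self, h: int) -> int:
        return (h - 1) * self.stride - 2 * self.pad + self.k + self.op

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, C, Hi, Wi = x.shape
        self._x = x
        Ho = self.out_size(Hi)
        Wo = self.out_size(Wi)
        # contributions t[b, hi, wi, c_out, ki, kj]
        t = np.tensordot(x.transpose(0, 2, 3, 1), self.W, axes=([3], [0]))
        ypad = np.zeros((B, self.c_out, Ho + 2 * self.pad, Wo + 2 * self.pad))
        tt = t.transpose(0, 3, 1, 2, 4, 5)  # (B, c_out, Hi, Wi, k, k)
        s = self.stride
        for i in range(self.k):
            for j in range(self.k):
                ypad[:, :, i : i + s * Hi : s, j : j + s * Wi : s] += tt[
                    :, :, :, :, i, j
                ]
        p = self.pad
        y = ypad[:, :, p : p + Ho, p : p + Wo] + self.b[None, :, None, None]
        self._out_hw = (Ho, Wo)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, _, Ho, Wo = dy.shape
        Hi, Wi = self._x.shape[2], self._x.shape[3]
        p, s, k = self.pad, self.stride, self.k
        dypad = np.pad(dy, ((0, 0), (0, 0), (p, p), (p, p)))
        dcols = np.empty((B, self.c_out, Hi, Wi, k, k))
        for i in range(k):
            for j in range(k):
                dcols[:, :, :, :, i, j] = dypad[
                    :, :, i : i + s * Hi : s, j : j + s * Wi : s
                ]
        # dW[c_in, c_out, ki, kj] = sum_{b,hi,wi} x * dcols
        self.grads[0] += np.tensordot(
            self._x, dcols, axes=([0, 2, 3], [0, 2, 3])
        )
        self.grads[1] += dy.sum(axis=(0, 2, 3))
        dx = np.tensordot(dcols, self.W, axes=([1, 4, 5], [1, 2, 3]))
        return dx.transpose(0, 3, 1, 2)


class Sequential:
    """Chain of layers with flat parameter access for the optimizer."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self) -> None:
        for g in self.grads:
            g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        for p, w in zip(self.params, weights):
            p[...] = w


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
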