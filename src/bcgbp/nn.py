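"""Minimal 1-D convolutional network engine (numpy, CPU, float32).

Implements exactly the layer set the BP regressor needs — same-padding 1-D
convolution, batch normalization, ReLU, factor-2 max pooling, global average
pooling, a dense head — with reverse-mode gradients and an Adam optimizer.
Convolutions are evaluated as K batched matrix products over shifted views
(no im2col materialization), so the whole forward/backward pass runs on
BLAS.  All randomness is drawn from a caller-supplied
``numpy.random.Generator``, so training is reproducible on CPU.

Array convention: activations are channels-last ``(batch, length, channels)``
float32; the dense head takes ``(batch, channels)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "BatchNorm1D",
    "ReLU",
    "MaxPool1D",
    "GlobalAvgPool",
    "Dense",
    "Sequential",
    "Adam",
]

_EPS = 1e-5


class Layer:
    """Base layer: parameter/gradient dicts plus forward/backward."""

    #: set False on the first layer to skip its input-gradient computation
    needs_input_grad: bool = True

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray | None:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Conv1D(Layer):
    """Same-padding 1-D convolution, stride 1, He-initialized.

    Weights are stored as ``(kernel, c_in, c_out)``; the convolution is a sum
    of ``kernel`` shifted batched GEMMs on the padded input.
    """

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for symmetric same-padding")
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        fan_in = c_in * kernel
        w = rng.standard_normal((kernel, c_in, c_out)) * np.sqrt(2.0 / fan_in)
        self.params = {"W": w.astype(np.float32), "b": np.zeros(c_out, dtype=np.float32)}
        self._xp: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, _ = x.shape
        pad = self.kernel // 2
        xp = np.pad(x, ((0, 0), (pad, pad), (0, 0)))
        w = self.params["W"]
        if self.c_in <= 4:
            # few input channels: shifted GEMMs have a tiny inner dimension,
            # so materialize windows into one well-shaped product instead
            win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
            col = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
                b * length, self.kernel * self.c_in
            )
            y = col @ w.reshape(self.kernel * self.c_in, self.c_out)
            y = y.reshape(b, length, self.c_out)
            if train:
                self._col, self._xp, self._length = col, xp, length
        else:
            y = np.empty((b, length, self.c_out), dtype=np.float32)
            np.matmul(xp[:, 0:length, :], w[0], out=y)
            for k in range(1, self.kernel):
                y += xp[:, k : k + length, :] @ w[k]
            if train:
                self._col, self._xp, self._length = None, xp, length
        y += self.params["b"]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray | None:
        xp, length = self._xp, self._length
        w = self.params["W"]
        b = gy.shape[0]
        if self._col is not None:
            g2 = gy.reshape(b * length, self.c_out)
            self.grads["W"] = (self._col.T @ g2).reshape(
                self.kernel, self.c_in, self.c_out
            )
        else:
            gw = np.empty_like(w)
            for k in range(self.kernel):
                gw[k] = np.tensordot(xp[:, k : k + length, :], gy, axes=([0, 1], [0, 1]))
            self.grads["W"] = gw
        self.grads["b"] = gy.sum(axis=(0, 1))
        gx = None
        if self.needs_input_grad:
            pad = self.kernel // 2
            gxp = np.zeros_like(xp)
            for k in range(self.kernel):
                gxp[:, k : k + length, :] += gy @ w[k].T
            gx = gxp[:, pad : pad + length, :]
        self._xp = None
        self._col = None
        return gx


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.1):
        super().__init__()
        self.momentum = momentum
        self.params = {
            "gamma": np.ones(channels, dtype=np.float32),
            "beta": np.zeros(channels, dtype=np.float32),
        }
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = (1.0 / np.sqrt(var + _EPS)).astype(np.float32)
        xhat = x - mean
        xhat *= invstd
        if train:
            self._xhat, self._invstd = xhat, invstd
        y = xhat * self.params["gamma"]
        y += self.params["beta"]
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._xhat, self._invstd
        m = gy.shape[0] * gy.shape[1]
        self.grads["gamma"] = np.einsum("blc,blc->c", gy, xhat)
        self.grads["beta"] = np.einsum("blc->c", gy)
        coeff = self.params["gamma"] * invstd / np.float32(m)
        gx = gy * np.float32(m)
        gx -= self.grads["beta"]
        xhat *= self.grads["gamma"]
        gx -= xhat
        gx *= coeff
        self._xhat = None
        return gx.astype(np.float32, copy=False)


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._mask = x > 0
        return np.maximum(x, 0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        gx = gy * self._mask
        self._mask = None
        return gx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along length by an integer factor."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, c = x.shape
        if length % self.factor:
            raise ValueError(f"length {length} not divisible by pool factor {self.factor}")
        xr = x.reshape(b, length // self.factor, self.factor, c)
        if self.factor == 2:
            a0, a1 = xr[:, :, 0, :], xr[:, :, 1, :]
            mask = a1 > a0
            if train:
                self._mask = mask
            return np.where(mask, a1, a0)
        arg = xr.argmax(axis=2)
        if train:
            self._arg = arg
        return np.take_along_axis(xr, arg[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        b, lo, c = gy.shape
        gx = np.zeros((b, lo, self.factor, c), dtype=np.float32)
        if self.factor == 2:
            mask = self._mask
            gx[:, :, 0, :] = np.where(mask, 0, gy)
            gx[:, :, 1, :] = np.where(mask, gy, 0)
            self._mask = None
        else:
            np.put_along_axis(gx, self._arg[:, :, None, :], gy[:, :, None, :], axis=2)
            self._arg = None
        return gx.reshape(b, lo * self.factor, c)


class GlobalAvgPool(Layer):
    """Average over the length axis: (B, L, C) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._in_len = x.shape[1]
        return x.mean(axis=1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        scale = np.float32(1.0 / self._in_len)
        return np.broadcast_to((gy * scale)[:, None, :], (gy.shape[0], self._in_len, gy.shape[1])).copy()


class Dense(Layer):
    """Fully connected layer with identity activation."""

    def __init__(self, c_in: int, c_out: int):
        super().__init__()
        # zero weight init keeps the initial prediction at the bias value;
        # gradients flow immediately because the input features are nonzero
        self.params = {
            "W": np.zeros((c_in, c_out), dtype=np.float32),
            "b": np.zeros(c_out, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        gx = gy @ self.params["W"].T
        self._x = None
        return gx


class Sequential:
    """Ordered layer stack; the first parametric layer skips its input grad."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers
        if layers:
            layers[0].needs_input_grad = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> None:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)

    def n_params(self) -> int:
        return sum(layer.n_params() for layer in self.layers)

    def get_weights(self) -> dict[str, np.ndarray]:
        out = {}
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                out[f"{i}.{name}"] = p.copy()
            if isinstance(layer, BatchNorm1D):
                out[f"{i}.running_mean"] = layer.running_mean.copy()
                out[f"{i}.running_var"] = layer.running_var.copy()
        return out

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = weights[f"{i}.{name}"].copy()
            if isinstance(layer, BatchNorm1D):
                layer.running_mean = weights[f"{i}.running_mean"].copy()
                layer.running_var = weights[f"{i}.running_var"].copy()


class Adam:
    """Adam optimizer over every parameter of a :class:`Sequential`."""

    def __init__(self, model: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.model = model
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, layer in enumerate(self.model.layers):
            for name, p in layer.params.items():
                g = layer.grads[name].astype(np.float32, copy=False)
                key = (i, name)
                if key not in self.m:
                    self.m[key] = np.zeros_like(p)
                    self.v[key] = np.zeros_like(p)
                self.m[key] = self.beta1 * self.m[key] + (1 - self.beta1) * g
                self.v[key] = self.beta2 * self.v[key] + (1 - self.beta2) * g * g
                p -= self.lr * (self.m[key] / b1t) / (np.sqrt(self.v[key] / b2t) + self.eps)
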