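"""Differentiable layers (channels-last layout).

2-D tensors are (batch, height, width, channels); 1-D tensors are
(batch, length, channels).  Each layer implements ``forward(x, training)``
and ``backward(dout)`` (returning the gradient w.r.t. its input) and
exposes its parameters as (value, gradient) pairs for the optimiser.
Weight gradients are accumulated into ``grads`` during backward.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..errors import ConfigurationError


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return []


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)


class Conv2D(Layer):
    """Valid (no-padding) 2-D convolution, stride 1, channels-last."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator):
        self.k = kernel
        self.w = _he_init(rng, (kernel, kernel, in_ch, out_ch),
                          kernel * kernel * in_ch)
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        if x.shape[1] < self.k or x.shape[2] < self.k:
            raise ConfigurationError(
                f"Conv2D: input {x.shape[1:3]} smaller than kernel {self.k}"
            )
        self._x = x
        patches = sliding_window_view(x, (self.k, self.k), axis=(1, 2))
        # patches: (B, Ho, Wo, Cin, k, k)
        self._patches = patches
        return np.einsum("bhwcij,ijco->bhwo", patches, self.w) + self.b

    def backward(self, dout):
        self.dw += np.einsum("bhwcij,bhwo->ijco", self._patches, dout)
        self.db += dout.sum(axis=(0, 1, 2))
        dx = np.zeros_like(self._x)
        ho, wo = dout.shape[1], dout.shape[2]
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i:i + ho, j:j + wo, :] += np.einsum(
                    "bhwo,co->bhwc", dout, self.w[i, j])
        return dx

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Conv1D(Layer):
    """1-D convolution over the length axis with 'same' zero padding
    and arbitrary stride (output length = ceil(L / stride))."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int,
                 rng: np.random.Generator):
        self.k = kernel
        self.stride = stride
        self.w = _he_init(rng, (kernel, in_ch, out_ch), kernel * in_ch)
        self.b = np.zeros(out_ch)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _padding(self, length: int) -> tuple[int, int, int]:
        out_len = -(-length // self.stride)
        pad_total = max((out_len - 1) * self.stride + self.k - length, 0)
        return out_len, pad_total // 2, pad_total - pad_total // 2

    def forward(self, x, training=False):
        length = x.shape[1]
        out_len, pad_l, pad_r = self._padding(length)
        xp = np.pad(x, ((0, 0), (pad_l, pad_r), (0, 0)))
        self._xp_shape, self._pad_l, self._length = xp.shape, pad_l, length
        patches = sliding_window_view(xp, self.k, axis=1)[:, ::self.stride]
        # patches: (B, out_len, Cin, k)
        self._patches = patches
        return np.einsum("blck,kco->blo", patches, self.w) + self.b

    def backward(self, dout):
        self.dw += np.einsum("blck,blo->kco", self._patches, dout)
        self.db += dout.sum(axis=(0, 1))
        dxp = np.zeros(self._xp_shape)
        out_len = dout.shape[1]
        for i in range(self.k):
            # input positions hit by tap i: t = l*stride + i
            dxp[:, i:i + (out_len - 1) * self.stride + 1:self.stride, :] += (
                dout @ self.w[i].T
            )
        return dxp[:, self._pad_l:self._pad_l + self._length, :]

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]


class MaxPool2D(Layer):
    """2x2 max pooling with floor semantics (trailing row/col dropped)."""

    def __init__(self, pool: int = 2):
        self.p = pool

    def forward(self, x, training=False):
        p = self.p
        b, h, w, c = x.shape
        ho, wo = h // p, w // p
        self._in_shape = x.shape
        a = x[:, :ho * p, :wo * p, :].reshape(b, ho, p, wo, p, c)
        a = a.transpose(0, 1, 3, 2, 4, 5).reshape(b, ho, wo, p * p, c)
        self._a_shape = a.shape
        self._idx = a.argmax(axis=3)
        return np.take_along_axis(a, self._idx[:, :, :, None, :], axis=3)[
            :, :, :, 0, :]

    def backward(self, dout):
        p = self.p
        b, h, w, c = self._in_shape
        ho, wo = h // p, w // p
        da = np.zeros(self._a_shape)
        np.put_along_axis(da, self._idx[:, :, :, None, :],
                          dout[:, :, :, None, :], axis=3)
        da = da.reshape(b, ho, wo, p, p, c).transpose(0, 1, 3, 2, 4, 5)
        dx = np.zeros(self._in_shape)
        dx[:, :ho * p, :wo * p, :] = da.reshape(b, ho * p, wo * p, c)
        return dx


class MaxPool1D(Layer):
    """Max pooling over the length axis, floor semantics."""

    def __init__(self, pool: int = 2):
        self.p = pool

    def forward(self, x, training=False):
        p = self.p
        b, length, c = x.shape
        lo = length // p
        self._in_shape = x.shape
        a = x[:, :lo * p, :].reshape(b, lo, p, c)
        self._idx = a.argmax(axis=2)
        return np.take_along_axis(a, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dout):
        p = self.p
        b, length, c = self._in_shape
        lo = length // p
        da = np.zeros((b, lo, p, c))
        np.put_along_axis(da, self._idx[:, :, None, :], dout[:, :, None, :],
                          axis=2)
        dx = np.zeros(self._in_shape)
        dx[:, :lo * p, :] = da.reshape(b, lo * p, c)
        return dx


class BatchNorm(Layer):
    """Batch normalisation over all axes except the trailing channel axis."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        self._axes = axes
        self._n = x.size // x.shape[-1]
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean) / self._std
        self._training = training
        return self.gamma * self._xhat + self.beta

    def backward(self, dout):
        axes = self._axes
        self.dgamma += (dout * self._xhat).sum(axis=axes)
        self.dbeta += dout.sum(axis=axes)
        dxhat = dout * self.gamma
        if not self._training:
            return dxhat / self._std
        n = self._n
        return (dxhat - dxhat.mean(axis=axes)
                - self._xhat * (dxhat * self._xhat).mean(axis=axes)) / self._std

    def parameters(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._in_shape)


class GlobalAvgPool1D(Layer):
    def forward(self, x, training=False):
        self._length = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dout):
        return np.repeat(dout[:, None, :], self._length, axis=1) / self._length


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator):
        self.w = _he_init(rng, (in_features, out_features), in_features)
        self.b = np.zeros(out_features)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, training=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dout):
        self.dw += self._x.T @ dout
        self.db += dout.sum(axis=0)
        return dout @ self.w.T

    def parameters(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ResidualBlock1D(Layer):
    """Basic 1-D residual block: two 3-tap convolutions with batch norm,
    ReLU between, identity (or 1-tap strided projection) shortcut, add,
    final ReLU.  The first convolution carries the downsampling stride."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1D(in_ch, out_ch, 3, stride, rng)
        self.bn1 = BatchNorm(out_ch)
        self.relu1 = ReLU()
        self.conv2 = Conv1D(out_ch, out_ch, 3, 1, rng)
        self.bn2 = BatchNorm(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.proj: Conv1D | None = Conv1D(in_ch, out_ch, 1, stride, rng)
            self.proj_bn: BatchNorm | None = BatchNorm(out_ch)
        else:
            self.proj = self.proj_bn = None
        self.relu_out = ReLU()

    def forward(self, x, training=False):
        h = self.conv1.forward(x, training)
        h = self.bn1.forward(h, training)
        h = self.relu1.forward(h, training)
        h = self.conv2.forward(h, training)
        h = self.bn2.forward(h, training)
        if self.proj is not None:
            s = self.proj.forward(x, training)
            s = self.proj_bn.forward(s, training)
        else:
            s = x
        return self.relu_out.forward(h + s, training)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dx = self.conv1.backward(dh)
        if self.proj is not None:
            ds = self.proj_bn.backward(d)
            dx = dx + self.proj.backward(ds)
        else:
            dx = dx + d
        return dx

    def parameters(self):
        params = (self.conv1.parameters() + self.bn1.parameters()
                  + self.conv2.parameters() + self.bn2.parameters())
        if self.proj is not None:
            params += self.proj.parameters() + self.proj_bn.parameters()
        return params
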