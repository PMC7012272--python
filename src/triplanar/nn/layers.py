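"""Minimal channels-last neural-network layers with explicit backprop.

Everything here operates on float arrays whose first axis is the batch and
whose last axis is the channel/feature axis.  Convolutions are stride-1
"valid" (no padding); pooling is non-overlapping with floor division of
the spatial extent.  Each layer caches what its backward pass needs during
``forward(..., training=True)``.

Parameters are exposed through :meth:`Layer.param_arrays` as
``(name, array, trainable)`` triples; batch-norm contributes its running
mean/variance as non-trainable entries so that whole-model parameter
counts include normalization statistics.
"""

from __future__ import annotations

import math

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax: exp(z - max z) normalized along ``axis``."""
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Layer:
    name: str = ""

    def forward(self, x, training: bool = False):
        raise NotImplementedError

    def backward(self, dout):
        raise NotImplementedError

    def param_arrays(self) -> list[tuple[str, np.ndarray, bool]]:
        return []

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    @property
    def n_parameters(self) -> int:
        return sum(a.size for _, a, _ in self.param_arrays())


class ConvND(Layer):
    """Stride-1 valid convolution over 1, 2 or 3 spatial dims (channels last).

    Weight shape is ``(*kernel, C_in, C_out)``, bias ``(C_out,)``.
    """

    def __init__(self, nd, in_channels, out_channels, kernel_size, rng, bias=True, name=""):
        self.nd = nd
        self.kernel = (kernel_size,) * nd if np.isscalar(kernel_size) else tuple(kernel_size)
        self.cin, self.cout = in_channels, out_channels
        k = int(np.prod(self.kernel))
        self.W = glorot_uniform(
            rng, self.kernel + (in_channels, out_channels), k * in_channels, k * out_channels
        )
        self.b = np.zeros(out_channels, dtype=np.float32) if bias else None
        self.name = name or f"conv{nd}d"
        self._cache = None
        self.dW = None
        self.db = None

    def out_spatial(self, spatial) -> tuple[int, ...]:
        return tuple(s - k + 1 for s, k in zip(spatial, self.kernel))

    def forward(self, x, training=False):
        nd = self.nd
        batch, *spatial, cin = x.shape
        if cin != self.cin:
            raise ValueError(f"{self.name}: expected {self.cin} channels, got {cin}")
        out_sp = self.out_spatial(spatial)
        if min(out_sp) < 1:
            raise ValueError(f"{self.name}: spatial dims {spatial} too small for kernel {self.kernel}")
        v = sliding_window_view(x, self.kernel, axis=tuple(range(1, 1 + nd)))
        # v axes: (B, *out_sp, C_in, *kernel) -> (B, *out_sp, *kernel, C_in)
        v = np.moveaxis(v, 1 + nd, -1)
        cols = np.ascontiguousarray(v).reshape(-1, int(np.prod(self.kernel)) * self.cin)
        out = cols @ self.W.reshape(-1, self.cout)
        if self.b is not None:
            out += self.b
        if training:
            self._cache = (cols, x.shape, out_sp)
        return out.reshape(batch, *out_sp, self.cout).astype(np.float32, copy=False)

    def backward(self, dout):
        cols, x_shape, out_sp = self._cache
        batch = x_shape[0]
        dout_mat = dout.reshape(-1, self.cout)
        self.dW = (cols.T @ dout_mat).reshape(self.W.shape)
        if self.b is not None:
            self.db = dout_mat.sum(axis=0)
        dcols = (dout_mat @ self.W.reshape(-1, self.cout).T).reshape(
            (batch,) + out_sp + self.kernel + (self.cin,)
        )
        dx = np.zeros(x_shape, dtype=np.float32)
        lead = (slice(None),) * (1 + self.nd)
        for kidx in np.ndindex(*self.kernel):
            sl = tuple(slice(i, i + o) for i, o in zip(kidx, out_sp))
            dx[(slice(None),) + sl + (slice(None),)] += dcols[lead + kidx + (slice(None),)]
        return dx

    def param_arrays(self):
        out = [(f"{self.name}.W", self.W, True)]
        if self.b is not None:
            out.append((f"{self.name}.b", self.b, True))
        return out

    def grads(self):
        g = {f"{self.name}.W": self.dW}
        if self.b is not None:
            g[f"{self.name}.b"] = self.db
        return g


class DepthwiseConv3D(Layer):
    """Per-channel 3x3x3 spatial convolution, depth multiplier 1, no bias."""

    def __init__(self, channels, kernel_size, rng, name="depthwise_conv3d"):
        self.kernel = (kernel_size,) * 3 if np.isscalar(kernel_size) else tuple(kernel_size)
        self.channels = channels
        k = int(np.prod(self.kernel))
        self.W = glorot_uniform(rng, self.kernel + (channels,), k, k)
        self.name = name
        self._cache = None
        self.dW = None

    def forward(self, x, training=False):
        batch, *spatial, c = x.shape
        if c != self.channels:
            raise ValueError(f"{self.name}: expected {self.channels} channels, got {c}")
        out_sp = tuple(s - k + 1 for s, k in zip(spatial, self.kernel))
        if min(out_sp) < 1:
            raise ValueError(f"{self.name}: spatial dims {spatial} too small")
        v = sliding_window_view(x, self.kernel, axis=(1, 2, 3))
        # v: (B, o1, o2, o3, C, k1, k2, k3)
        out = np.einsum("bpqrcijk,ijkc->bpqrc", v, self.W, optimize=True)
        if training:
            self._cache = (v, x.shape, out_sp)
        return out.astype(np.float32, copy=False)

    def backward(self, dout):
        v, x_shape, out_sp = self._cache
        self.dW = np.einsum("bpqrcijk,bpqrc->ijkc", v, dout, optimize=True)
        dx = np.zeros(x_shape, dtype=np.float32)
        for kidx in np.ndindex(*self.kernel):
            sl = tuple(slice(i, i + o) for i, o in zip(kidx, out_sp))
            dx[(slice(None),) + sl + (slice(None),)] += dout * self.W[kidx]
        return dx

    def param_arrays(self):
        return [(f"{self.name}.W", self.W, True)]

    def grads(self):
        return {f"{self.name}.W": self.dW}


class MaxPoolND(Layer):
    """Non-overlapping max pooling (window = stride); trailing odd voxels dropped."""

    def __init__(self, nd, pool_size=2, name=""):
        self.nd = nd
        self.pool = pool_size
        self.name = name or f"maxpool{nd}d"
        self._cache = None

    def forward(self, x, training=False):
        nd, p = self.nd, self.pool
        batch, *spatial, c = x.shape
        out_sp = tuple(s // p for s in spatial)
        if min(out_sp) < 1:
            raise ValueError(f"{self.name}: spatial dims {spatial} smaller than pool {p}")
        crop = x[(slice(None),) + tuple(slice(0, o * p) for o in out_sp) + (slice(None),)]
        shape = (batch,) + sum(((o, p) for o in out_sp), ()) + (c,)
        r = crop.reshape(shape)
        out_axes = (0,) + tuple(1 + 2 * i for i in range(nd)) + (1 + 2 * nd,)
        win_axes = tuple(2 + 2 * i for i in range(nd))
        t = r.transpose(out_axes + win_axes).reshape((batch,) + out_sp + (c, p**nd))
        arg = t.argmax(axis=-1)
        out = np.take_along_axis(t, arg[..., None], axis=-1)[..., 0]
        if training:
            self._cache = (arg, x.shape, out_sp, crop.shape, out_axes + win_axes)
        return out

    def backward(self, dout):
        arg, x_shape, out_sp, crop_shape, perm = self._cache
        nd, p = self.nd, self.pool
        batch, c = x_shape[0], x_shape[-1]
        dt = np.zeros((batch,) + out_sp + (c, p**nd), dtype=np.float32)
        np.put_along_axis(dt, arg[..., None], dout[..., None].astype(np.float32), axis=-1)
        dt = dt.reshape((batch,) + out_sp + (c,) + (p,) * nd)
        inv = tuple(np.argsort(perm))
        dcrop = dt.transpose(inv).reshape(crop_shape)
        dx = np.zeros(x_shape, dtype=np.float32)
        dx[(slice(None),) + tuple(slice(0, o * p) for o in out_sp) + (slice(None),)] = dcrop
        return dx


class BatchNorm(Layer):
    """Batch normalization over all axes except the last (feature) axis.

    Carries 2 trainable parameters (scale, shift) and 2 running statistics
    (mean, variance) per feature; all four count toward the model's
    parameter total.
    """

    def __init__(self, n_features, momentum=0.9, eps=1e-5, name="batchnorm"):
        self.gamma = np.ones(n_features, dtype=np.float32)
        self.beta = np.zeros(n_features, dtype=np.float32)
        self.running_mean = np.zeros(n_features, dtype=np.float32)
        self.running_var = np.ones(n_features, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self.name = name
        self._cache = None
        self.dgamma = None
        self.dbeta = None

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean *= self.momentum
            self.running_mean += (1 - self.momentum) * mu
            self.running_var *= self.momentum
            self.running_var += (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        if training:
            n = x.size // x.shape[-1]
            self._cache = (xhat, inv_std, n, axes)
        return (self.gamma * xhat + self.beta).astype(np.float32, copy=False)

    def backward(self, dout):
        xhat, inv_std, n, axes = self._cache
        self.dgamma = (dout * xhat).sum(axis=axes)
        self.dbeta = dout.sum(axis=axes)
        dxhat = dout * self.gamma
        dx = (
            dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)
        ) * inv_std
        return dx.astype(np.float32, copy=False)

    def param_arrays(self):
        return [
            (f"{self.name}.gamma", self.gamma, True),
            (f"{self.name}.beta", self.beta, True),
            (f"{self.name}.running_mean", self.running_mean, False),
            (f"{self.name}.running_var", self.running_var, False),
        ]

    def grads(self):
        return {f"{self.name}.gamma": self.dgamma, f"{self.name}.beta": self.dbeta}


class LeakyReLU(Layer):
    def __init__(self, slope=0.3, name="leaky_relu"):
        self.slope = slope
        self.name = name
        self._mask = None

    def forward(self, x, training=False):
        mask = x >= 0
        if training:
            self._mask = mask
        return np.where(mask, x, self.slope * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.slope * dout)


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, rate, rng, name="dropout"):
        self.rate = rate
        self.rng = rng
        self.name = name
        self._mask = None

    def forward(self, x, training=False):
        if not training or self.rate <= 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class Flatten(Layer):
    def __init__(self, name="flatten"):
        self.name = name
        self._shape = None

    def forward(self, x, training=False):
        if training:
            self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng, name="dense"):
        self.W = glorot_uniform(rng, (in_features, out_features), in_features, out_features)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.name = name
        self._x = None
        self.dW = None
        self.db = None

    def forward(self, x, training=False):
        if training:
            self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.dW = self._x.T @ dout
        self.db = dout.sum(axis=0)
        return dout @ self.W.T

    def param_arrays(self):
        return [(f"{self.name}.W", self.W, True), (f"{self.name}.b", self.b, True)]

    def grads(self):
        return {f"{self.name}.W": self.dW, f"{self.name}.b": self.db}


class Softmax(Layer):
    """Softmax over the last axis with the exact Jacobian in backward."""

    def __init__(self, name="softmax"):
        self.name = name
        self._p = None

    def forward(self, x, training=False):
        p = softmax(x, axis=-1)
        if training:
            self._p = p
        return p

    def backward(self, dout):
        p = self._p
        return (p * (dout - (dout * p).sum(axis=-1, keepdims=True))).astype(np.float32)
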