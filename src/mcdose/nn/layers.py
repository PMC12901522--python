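"""NumPy building blocks for the 3D U-net.

Each layer implements ``forward(x, training)`` and ``backward(dy)``; arrays
have shape (batch, channels, x, y, z).  Weights are stored in float32 but
the layers follow the input dtype, so gradient checks can run in float64.  Convolutions are
evaluated as 27 (or k^3) shifted matrix products so that the heavy lifting
runs through BLAS; transposed convolutions use kernel == stride (the pool
factors), which makes them non-overlapping block expansions.

Gradients are exact (verified against central differences in the test
suite), so training behaviour is fully deterministic given the seed.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = [
    "Parameter",
    "Conv3d",
    "ConvTranspose3d",
    "MaxPool3d",
    "BatchNorm3d",
    "ReLU",
]


class Parameter:
    """A named trainable array with its gradient."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv3d(Layer):
    """Same-padded 3D convolution with odd kernel (3x3x3 or 1x1x1)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: tuple[int, int, int] = (3, 3, 3),
        rng: np.random.Generator | None = None,
        name: str = "conv",
    ):
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = tuple(kernel)
        if any(k % 2 == 0 for k in self.kernel):
            raise ValueError("kernel dimensions must be odd for same padding")
        fan_in = in_channels * int(np.prod(self.kernel))
        # He (fan-in) initialization for ReLU networks
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            f"{name}.weight",
            rng.normal(0.0, std, (out_channels, in_channels, *self.kernel)).astype(
                np.float32
            ),
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels, dtype=np.float32))
        self._xp: np.ndarray | None = None

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def _pads(self):
        return tuple((k - 1) // 2 for k in self.kernel)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, X, Y, Z = x.shape
        px, py, pz = self._pads()
        xp = np.pad(x, ((0, 0), (0, 0), (px, px), (py, py), (pz, pz)))
        self._xp = xp if training else None
        self._in_shape = x.shape
        W = self.weight.value
        if x.dtype != W.dtype:
            W = W.astype(x.dtype)
        out = np.zeros((n, self.out_channels, X * Y * Z), dtype=x.dtype)
        for i, j, k in itertools.product(*(range(s) for s in self.kernel)):
            xs = xp[:, :, i : i + X, j : j + Y, k : k + Z].reshape(n, c, -1)
            out += np.matmul(W[:, :, i, j, k], xs)
        out = out.reshape(n, self.out_channels, X, Y, Z)
        out += self.bias.value[None, :, None, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._xp is None:
            raise RuntimeError("backward called without a training-mode forward")
        n, c, X, Y, Z = self._in_shape
        xp = self._xp
        dyf = dy.reshape(n, self.out_channels, -1)
        self.bias.grad[:] = dy.sum(axis=(0, 2, 3, 4))
        dW = self.weight.grad
        dxp = np.zeros_like(xp)
        W = self.weight.value
        if xp.dtype != W.dtype:
            W = W.astype(xp.dtype)
        for i, j, k in itertools.product(*(range(s) for s in self.kernel)):
            xs = xp[:, :, i : i + X, j : j + Y, k : k + Z].reshape(n, c, -1)
            dW[:, :, i, j, k] = np.tensordot(dyf, xs, axes=([0, 2], [0, 2]))
            dxs = np.matmul(W[:, :, i, j, k].T, dyf).reshape(n, c, X, Y, Z)
            dxp[:, :, i : i + X, j : j + Y, k : k + Z] += dxs
        px, py, pz = self._pads()
        sl = lambda p, m: slice(p, p + m)  # noqa: E731
        dx = dxp[:, :, sl(px, X), sl(py, Y), sl(pz, Z)]
        self._xp = None
        return np.ascontiguousarray(dx)


class ConvTranspose3d(Layer):
    """Learned upsampling with kernel == stride (non-overlapping blocks)."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        stride: tuple[int, int, int],
        rng: np.random.Generator | None = None,
        name: str = "upconv",
    ):
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.stride = tuple(stride)
        fan_in = in_channels
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            f"{name}.weight",
            rng.normal(0.0, std, (in_channels, out_channels, *self.stride)).astype(
                np.float32
            ),
        )
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels, dtype=np.float32))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, X, Y, Z = x.shape
        si, sj, sk = self.stride
        self._x = x if training else None
        self._in_shape = x.shape
        # (N,X,Y,Z,O,i,j,k) <- (N,C,X,Y,Z) . (C,O,i,j,k)
        t = np.tensordot(x, self.weight.value, axes=([1], [0]))
        t = t.transpose(0, 4, 1, 5, 2, 6, 3, 7)  # N,O,X,i,Y,j,Z,k
        out = t.reshape(n, self.out_channels, X * si, Y * sj, Z * sk).copy()
        out += self.bias.value[None, :, None, None, None]
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._x is None:
            raise RuntimeError("backward called without a training-mode forward")
        n, c, X, Y, Z = self._in_shape
        si, sj, sk = self.stride
        self.bias.grad[:] = dy.sum(axis=(0, 2, 3, 4))
        dyr = dy.reshape(n, self.out_channels, X, si, Y, sj, Z, sk)
        dyr = dyr.transpose(0, 2, 4, 6, 1, 3, 5, 7)  # N,X,Y,Z,O,i,j,k
        dx = np.tensordot(dyr, self.weight.value, axes=([4, 5, 6, 7], [1, 2, 3, 4]))
        self.weight.grad[:] = np.tensordot(
            self._x, dyr, axes=([0, 2, 3, 4], [0, 1, 2, 3])
        )
        self._x = None
        return np.ascontiguousarray(dx.transpose(0, 4, 1, 2, 3))


class MaxPool3d(Layer):
    """Non-overlapping max pooling with stride == kernel."""

    def __init__(self, pool: tuple[int, int, int]):
        self.pool = tuple(pool)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, X, Y, Z = x.shape
        px, py, pz = self.pool
        if X % px or Y % py or Z % pz:
            raise ValueError(f"shape {(X, Y, Z)} not divisible by pool {self.pool}")
        xr = x.reshape(n, c, X // px, px, Y // py, py, Z // pz, pz)
        xr = xr.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, X // px, Y // py, Z // pz, px * py * pz
        )
        idx = xr.argmax(axis=-1)
        out = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
        if training:
            self._idx = idx
            self._in_shape = x.shape
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, X, Y, Z = self._in_shape
        px, py, pz = self.pool
        flat = np.zeros((n, c, X // px, Y // py, Z // pz, px * py * pz), dtype=dy.dtype)
        np.put_along_axis(flat, self._idx[..., None], dy[..., None], axis=-1)
        flat = flat.reshape(n, c, X // px, Y // py, Z // pz, px, py, pz)
        flat = flat.transpose(0, 1, 2, 5, 3, 6, 4, 7)
        return np.ascontiguousarray(flat.reshape(n, c, X, Y, Z))


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (batch, x, y, z)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn"):
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels, dtype=np.float32))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            ).astype(np.float32)
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            ).astype(np.float32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None, None]) * inv_std[
            None, :, None, None, None
        ]
        if training:
            self._xhat = xhat
            self._inv_std = inv_std
        return self.gamma.value[None, :, None, None, None] * xhat + self.beta.value[
            None, :, None, None, None
        ]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        xhat, inv_std = self._xhat, self._inv_std
        m = dy.shape[0] * dy.shape[2] * dy.shape[3] * dy.shape[4]
        self.beta.grad[:] = dy.sum(axis=axes)
        self.gamma.grad[:] = (dy * xhat).sum(axis=axes)
        g = self.gamma.value[None, :, None, None, None]
        s1 = dy.sum(axis=axes)[None, :, None, None, None]
        s2 = (dy * xhat).sum(axis=axes)[None, :, None, None, None]
        dx = (g * inv_std[None, :, None, None, None] / m) * (m * dy - s1 - xhat * s2)
        self._xhat = None
        return dx.astype(dy.dtype)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if training:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask
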