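"""3D U-net denoiser: configuration, closed-form parameter count, network.

The architecture is the standard encoder/decoder U-net with skip
connections at every resolution level: two same-padded 3x3x3 convolutions
(+ ReLU, optionally batch-normalized) per level, max-pooling of 3x3x1
between the first two levels (VMAT arcs are coplanar and dose gradients
along z are comparatively flat, so z resolution is kept at the top) and
2x2x2 below, learned transposed-convolution upsampling whose stride
inverts the corresponding pool, concatenation skips, and a final 1x1x1
convolution to a single dose channel.  "Four layers" counts the pooling
steps; with the default doubling channel ladder (32, 64, 128, 256, 512)
the network has 22,578,241 trainable parameters, i.e. 2.2578e7 at
five-significant-digit precision.

The five candidate configurations (z-input size 32/64/96, with/without CT
channel, with/without batch normalization) are all constructible via
:func:`candidate_configs`; the selected production model is candidate 2
(z=64, two channels, no batch normalization).
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from .layers import BatchNorm3d, Conv3d, ConvTranspose3d, MaxPool3d, Parameter, ReLU

__all__ = [
    "UNetConfig",
    "LayerDescriptor",
    "NetworkSpec",
    "network_spec",
    "count_parameters",
    "build_network",
    "UNet3D",
    "candidate_configs",
    "selected_config",
]

#: Default channel widths: the standard doubling ladder.
DEFAULT_WIDTHS = (32, 64, 128, 256, 512)


@dataclasses.dataclass(frozen=True)
class UNetConfig:
    """Full architecture hyperparameters.

    ``levels`` is the number of pooling steps; the network has
    ``levels + 1`` resolution levels and needs ``levels + 1`` channel
    widths.  ``xy_size`` and ``z_size`` are the input footprint the
    network is built for.
    """

    in_channels: int = 2
    out_channels: int = 1
    xy_size: int = 192
    z_size: int = 64
    levels: int = 4
    channel_widths: tuple[int, ...] = DEFAULT_WIDTHS
    kernel: tuple[int, int, int] = (3, 3, 3)
    first_pool: tuple[int, int, int] = (3, 3, 1)
    deeper_pool: tuple[int, int, int] = (2, 2, 2)
    batch_norm: bool = False

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("need at least 2 pooling steps")
        if len(self.channel_widths) != self.levels + 1:
            raise ValueError(
                f"need {self.levels + 1} channel widths, got {len(self.channel_widths)}"
            )
        if any(w <= 0 for w in self.channel_widths):
            raise ValueError("channel widths must be positive")
        if self.in_channels not in (1, 2):
            raise ValueError("in_channels must be 1 or 2")
        self.validate_shape()

    def pools(self) -> list[tuple[int, int, int]]:
        return [self.first_pool] + [self.deeper_pool] * (self.levels - 1)

    def validate_shape(self) -> None:
        """Check xy/z divisibility through every pooling level."""
        dims = {"x": self.xy_size, "y": self.xy_size, "z": self.z_size}
        for level, pool in enumerate(self.pools()):
            for ax, p in zip("xyz", pool):
                if dims[ax] % p:
                    raise ValueError(
                        f"axis {ax} size {dims[ax]} not divisible by pool {p} "
                        f"at level {level}"
                    )
                dims[ax] //= p

    def replace(self, **kwargs) -> "UNetConfig":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def tiny(
        cls,
        xy_size: int = 48,
        z_size: int = 16,
        channel_widths: tuple[int, ...] = (8, 16, 32, 64, 128),
    ) -> "UNetConfig":
        """A small configuration for desk-scale experiments and tests."""
        return cls(xy_size=xy_size, z_size=z_size, channel_widths=channel_widths)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "UNetConfig":
        d = dict(d)
        for key in ("channel_widths", "kernel", "first_pool", "deeper_pool"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclasses.dataclass(frozen=True)
class LayerDescriptor:
    """One parameterized operation of the network, for closed-form counting."""

    kind: str  # "conv" | "upconv" | "batch_norm"
    in_channels: int
    out_channels: int
    kernel: tuple[int, int, int]

    @property
    def n_parameters(self) -> int:
        if self.kind in ("conv", "upconv"):
            return (
                self.in_channels * self.out_channels * int(np.prod(self.kernel))
                + self.out_channels
            )
        if self.kind == "batch_norm":
            return 2 * self.out_channels
        raise ValueError(f"unknown layer kind {self.kind}")


@dataclasses.dataclass
class NetworkSpec:
    """Ordered layer descriptors plus the closed-form total parameter count."""

    layers: list[LayerDescriptor]
    total_parameters: int

    def fingerprint(self) -> str:
        """JSON architecture fingerprint for cross-version verification."""
        return json.dumps(
            {
                "layers": [dataclasses.asdict(l) for l in self.layers],
                "total_parameters": self.total_parameters,
            }
        )


def network_spec(config: UNetConfig) -> NetworkSpec:
    """Enumerate all parameterized layers of a configuration.

    This is pure arithmetic on the configuration -- no arrays are
    allocated -- and serves as the independent cross-check of the
    instantiated network's parameter count.
    """
    layers: list[LayerDescriptor] = []
    w = config.channel_widths
    k = config.kernel
    pools = config.pools()

    def block(c_in: int, c_out: int) -> None:
        layers.append(LayerDescriptor("conv", c_in, c_out, k))
        if config.batch_norm:
            layers.append(LayerDescriptor("batch_norm", c_out, c_out, (1, 1, 1)))
        layers.append(LayerDescriptor("conv", c_out, c_out, k))
        if config.batch_norm:
            layers.append(LayerDescriptor("batch_norm", c_out, c_out, (1, 1, 1)))

    prev = config.in_channels
    for wi in w:
        block(prev, wi)
        prev = wi
    for level in range(config.levels - 1, -1, -1):
        layers.append(LayerDescriptor("upconv", w[level + 1], w[level], pools[level]))
        block(2 * w[level], w[level])
    layers.append(
        LayerDescriptor("conv", w[0], config.out_channels, (1, 1, 1))
    )
    total = sum(l.n_parameters for l in layers)
    return NetworkSpec(layers=layers, total_parameters=total)


def count_parameters(config: UNetConfig) -> int:
    """Closed-form trainable-parameter count of a configuration."""
    return network_spec(config).total_parameters


class _ConvBlock:
    """Two convolutions with optional batch norm and ReLU nonlinearities."""

    def __init__(self, c_in, c_out, kernel, batch_norm, rng, name):
        self.layers: list = []
        for idx, (ci, co) in enumerate([(c_in, c_out), (c_out, c_out)]):
            self.layers.append(Conv3d(ci, co, kernel, rng, f"{name}.conv{idx}"))
            if batch_norm:
                self.layers.append(BatchNorm3d(co, name=f"{name}.bn{idx}"))
            self.layers.append(ReLU())

    def forward(self, x, training=False):
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]


class UNet3D:
    """The trainable denoising network.

    Input: float32 tensor of shape ``(batch, in_channels, xy, xy, z)``
    (scaled dose, and optionally scaled CT); output has the same spatial
    shape with one channel.  Construction is deterministic given ``seed``.
    """

    def __init__(self, config: UNetConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        w = config.channel_widths
        pools = config.pools()
        self.enc_blocks = []
        prev = config.in_channels
        for lv, wi in enumerate(w):
            self.enc_blocks.append(
                _ConvBlock(prev, wi, config.kernel, config.batch_norm, rng, f"enc{lv}")
            )
            prev = wi
        self.pools = [MaxPool3d(p) for p in pools]
        self.upconvs = []
        self.dec_blocks = []
        for lv in range(config.levels - 1, -1, -1):
            self.upconvs.append(
                ConvTranspose3d(w[lv + 1], w[lv], pools[lv], rng, f"up{lv}")
            )
            self.dec_blocks.append(
                _ConvBlock(
                    2 * w[lv], w[lv], config.kernel, config.batch_norm, rng, f"dec{lv}"
                )
            )
        self.final = Conv3d(w[0], config.out_channels, (1, 1, 1), rng, "final")

    # -- inference / training ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != self.config.in_channels:
            raise ValueError(
                f"expected (N, {self.config.in_channels}, x, y, z) input, "
                f"got {x.shape}"
            )
        skips = []
        for lv, block in enumerate(self.enc_blocks[:-1]):
            x = block.forward(x, training)
            skips.append(x)
            x = self.pools[lv].forward(x, training)
        x = self.enc_blocks[-1].forward(x, training)
        self._skip_channels = []
        for up, block, skip in zip(self.upconvs, self.dec_blocks, reversed(skips)):
            x = up.forward(x, training)
            self._skip_channels.append(skip.shape[1])
            x = np.concatenate([skip, x], axis=1)
            x = block.forward(x, training)
        return self.final.forward(x, training)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x, training=False)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.final.backward(dy)
        skip_grads = []
        for up, block, ch in zip(
            reversed(self.upconvs), reversed(self.dec_blocks),
            reversed(self._skip_channels),
        ):
            dy = block.backward(dy)
            skip_grads.append(dy[:, :ch])
            dy = up.backward(np.ascontiguousarray(dy[:, ch:]))
        skip_grads.reverse()  # now deepest skip first
        dy = self.enc_blocks[-1].backward(dy)
        for lv in range(len(self.pools) - 1, -1, -1):
            dy = self.pools[lv].backward(dy)
            dy = dy + skip_grads[len(self.pools) - 1 - lv]
            dy = self.enc_blocks[lv].backward(dy)
        return dy

    # -- bookkeeping ---------------------------------------------------------
    def parameters(self) -> list[Parameter]:
        params = []
        for block in self.enc_blocks:
            params += block.parameters()
        for up, block in zip(self.upconvs, self.dec_blocks):
            params += up.parameters()
            params += block.parameters()
        params += self.final.parameters()
        return params

    @property
    def num_parameters(self) -> int:
        """Framework-introspected trainable parameter count."""
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.value for p in self.parameters()}
        for block in self._all_blocks():
            for layer in block.layers:
                if isinstance(layer, BatchNorm3d):
                    state[f"{layer.gamma.name}.running_mean"] = layer.running_mean
                    state[f"{layer.gamma.name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.value = np.array(state[p.name], dtype=np.float32)
        for block in self._all_blocks():
            for layer in block.layers:
                if isinstance(layer, BatchNorm3d):
                    layer.running_mean = np.array(
                        state[f"{layer.gamma.name}.running_mean"], dtype=np.float32
                    )
                    layer.running_var = np.array(
                        state[f"{layer.gamma.name}.running_var"], dtype=np.float32
                    )

    def _all_blocks(self):
        return [*self.enc_blocks, *self.dec_blocks]

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, config: UNetConfig) -> "UNet3D":
        net = cls(config, seed=0)
        with np.load(path) as data:
            net.load_state_dict(dict(data))
        return net


def build_network(config: UNetConfig, seed: int = 0) -> UNet3D:
    """Instantiate the U-net for a (validated) configuration."""
    return UNet3D(config, seed=seed)


def selected_config() -> UNetConfig:
    """The production configuration: two channels, z=64, no batch norm."""
    return UNetConfig(in_channels=2, z_size=64, batch_norm=False)


def candidate_configs() -> dict[int, UNetConfig]:
    """The five candidate models (z-size, CT channel, batch normalization)."""
    return {
        1: UNetConfig(in_channels=2, z_size=32, batch_norm=False),
        2: selected_config(),
        3: UNetConfig(in_channels=2, z_size=96, batch_norm=False),
        4: UNetConfig(in_channels=1, z_size=64, batch_norm=False),
        5: UNetConfig(in_channels=2, z_size=64, batch_norm=True),
    }
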