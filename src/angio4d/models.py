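"""The U-Net family for 4D MRA vessel segmentation.

Four variants, named after the dimensionality of their input:

* ``unet2d`` — plain U-Net on 2D tMIP slices (3 encoder/decoder stages,
  base width 64 doubling to a 512-channel bottleneck);
* ``unet3d`` — the same plan with 3D kernels on volumetric (X, Y, Z) patches;
* ``st3d``  — spatio-temporal U-Net on a full (X, Y, T) slice: the first
  max-pool and the last up-sampling act on XY only, temporal kernel sizes
  are 3,3,5 through the encoder, 7 at the bottleneck, and 5,3,3 through the
  decoder; an unpadded (1, 1, T) convolution collapses the time axis before
  the sigmoid head, so the output is a 2D segmented slice;
* ``st4d``  — three weight-shared ``st3d`` arms applied to three adjacent
  slices; their pre-collapse spatio-temporal features are concatenated with
  the (time-replicated) tMIP of the input, fused by a small refinement
  module (plain, residual, dense, or residual-dense; three convolutions
  each), time-collapsed and passed to the sigmoid head.  A deep-supervision
  head on the middle arm is exposed as a second output for training.

Everywhere: stride-1 zero-padded ("same") convolutions, instance
normalization after each convolution and before the ReLU, max-pool
down-sampling, transposed-convolution up-sampling with kernel = stride.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autodiff as ad
from .nn import Adam  # noqa: F401  (re-exported for convenience)
from .nn.autodiff import Tensor
from .nn.layers import Conv, ConvBlock, InstanceNorm, MaxPool, Module, UpConv

__all__ = [
    "ArchConfig",
    "ModelSummary",
    "build_unet2d",
    "build_unet3d",
    "build_st3d",
    "build_st4d",
    "build_model",
    "count_parameters",
    "REFINEMENTS",
]

REFINEMENTS = ("cnn", "residual", "dense", "resdense")

#: sigmoid-head bias prior: vessels occupy ~1-5% of voxels, so the head starts
#: near that class prior instead of at 0.5 — standard practice for sparse
#: foregrounds, and it removes the early plateau where the network first has
#: to learn "mostly background" before it can learn vessels
HEAD_BIAS_PRIOR = -3.0


def _prior_head(conv: "Conv") -> "Conv":
    conv.b.data[:] = HEAD_BIAS_PRIOR
    return conv


@dataclass
class ArchConfig:
    variant: str = "st4d"
    base_channels: int = 32
    n_stages: int = 3
    refinement: str = "resdense"
    n_frames: int = 24
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("unet2d", "unet3d", "st3d", "st4d"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.refinement not in REFINEMENTS:
            raise ValueError(f"unknown refinement {self.refinement!r}; choose from {REFINEMENTS}")
        if self.n_stages != 3:
            raise ValueError("the architecture family is defined with 3 encoder/decoder stages")


@dataclass
class ModelSummary:
    """Trainable-parameter accounting with a per-layer breakdown."""

    total: int
    per_layer: list[tuple[str, tuple, int]] = field(default_factory=list)

    def table(self) -> str:
        lines = [f"{name:60s} {str(shape):24s} {count:>10d}" for name, shape, count in self.per_layer]
        lines.append(f"{'TOTAL':60s} {'':24s} {self.total:>10d}")
        return "\n".join(lines)


def count_parameters(model: Module) -> ModelSummary:
    """Exact count of trainable scalars; weight-shared modules are counted once."""
    per_layer = [(name, tuple(p.data.shape), int(p.data.size)) for name, p in model.named_parameters()]
    return ModelSummary(total=sum(c for _, _, c in per_layer), per_layer=per_layer)


def _check_divisible(shape, axes, factor=8, what="X,Y"):
    for ax in axes:
        if shape[ax] % factor:
            raise ValueError(
                f"input {what} dims must be divisible by {factor} "
                f"(three 2x down-samplings); got shape {tuple(shape)}"
            )


class _SpatialUNet(Module):
    """Shared implementation of the 2D and 3D spatial U-Nets."""

    def __init__(self, ndim: int, base: int, rng: np.random.Generator):
        self.ndim = ndim
        k = (3,) * ndim
        f = (2,) * ndim
        b = base
        self.enc = [
            [ConvBlock(1, b, k, rng), ConvBlock(b, b, k, rng)],
            [ConvBlock(b, 2 * b, k, rng), ConvBlock(2 * b, 2 * b, k, rng)],
            [ConvBlock(2 * b, 4 * b, k, rng), ConvBlock(4 * b, 4 * b, k, rng)],
        ]
        self.pool = MaxPool(f)
        self.bottleneck = [ConvBlock(4 * b, 8 * b, k, rng), ConvBlock(8 * b, 8 * b, k, rng)]
        self.up = [
            UpConv(8 * b, 4 * b, f, rng),
            UpConv(4 * b, 2 * b, f, rng),
            UpConv(2 * b, b, f, rng),
        ]
        self.dec = [
            [ConvBlock(8 * b, 4 * b, k, rng), ConvBlock(4 * b, 4 * b, k, rng)],
            [ConvBlock(4 * b, 2 * b, k, rng), ConvBlock(2 * b, 2 * b, k, rng)],
            [ConvBlock(2 * b, b, k, rng), ConvBlock(b, b, k, rng)],
        ]
        self.head = _prior_head(Conv(b, 1, (1,) * ndim, rng))

    def __call__(self, x) -> Tensor:
        x = x if isinstance(x, Tensor) else ad.tensor(x)
        _check_divisible(x.shape, range(2, 2 + self.ndim), what="spatial")
        skips = []
        h = x
        for blocks in self.enc:
            for blk in blocks:
                h = blk(h)
            skips.append(h)
            h = self.pool(h)
        for blk in self.bottleneck:
            h = blk(h)
        for up, blocks, skip in zip(self.up, self.dec, reversed(skips)):
            h = ad.concat([up(h), skip], axis=1)
            for blk in blocks:
                h = blk(h)
        return ad.sigmoid(self.head(h))


class ST3D(Module):
    """Spatio-temporal U-Net on one (X, Y, T) slice; outputs a 2D slice.

    ``arm_features`` exposes the pre-collapse spatio-temporal feature map so
    the 4DST variant can tap the arms before the temporal collapse.
    """

    # temporal kernels: encoder stages, bottleneck, decoder stages
    TIME_KERNELS_ENC = (3, 3, 5)
    TIME_KERNEL_BOTTLENECK = 7
    TIME_KERNELS_DEC = (5, 3, 3)
    # XY-only pooling first/last, full pooling in between
    POOL_PLAN = ((2, 2, 1), (2, 2, 2), (2, 2, 2))

    def __init__(self, base: int, n_frames: int, rng: np.random.Generator):
        b = base
        self.n_frames = int(n_frames)
        self.pre_norm = InstanceNorm(1)
        ch_in = (1, b, 2 * b)
        self.enc = [
            [
                ConvBlock(ch_in[i], b * 2**i, (3, 3, self.TIME_KERNELS_ENC[i]), rng),
                ConvBlock(b * 2**i, b * 2**i, (3, 3, self.TIME_KERNELS_ENC[i]), rng),
            ]
            for i in range(3)
        ]
        self.pools = [MaxPool(f) for f in self.POOL_PLAN]
        kb = (3, 3, self.TIME_KERNEL_BOTTLENECK)
        self.bottleneck = [ConvBlock(4 * b, 8 * b, kb, rng), ConvBlock(8 * b, 8 * b, kb, rng)]
        self.up = [
            UpConv(8 * b, 4 * b, self.POOL_PLAN[2], rng),
            UpConv(4 * b, 2 * b, self.POOL_PLAN[1], rng),
            UpConv(2 * b, b, self.POOL_PLAN[0], rng),
        ]
        self.dec = [
            [
                ConvBlock(8 * b, 4 * b, (3, 3, self.TIME_KERNELS_DEC[0]), rng),
                ConvBlock(4 * b, 4 * b, (3, 3, self.TIME_KERNELS_DEC[0]), rng),
            ],
            [
                ConvBlock(4 * b, 2 * b, (3, 3, self.TIME_KERNELS_DEC[1]), rng),
                ConvBlock(2 * b, 2 * b, (3, 3, self.TIME_KERNELS_DEC[1]), rng),
            ],
            [
                ConvBlock(2 * b, b, (3, 3, self.TIME_KERNELS_DEC[2]), rng),
                ConvBlock(b, b, (3, 3, self.TIME_KERNELS_DEC[2]), rng),
            ],
        ]
        self.collapse = Conv(b, b, (1, 1, self.n_frames), rng, padding="valid")
        self.collapse_norm = InstanceNorm(b)
        self.head = _prior_head(Conv(b, 1, (1, 1), rng))

    def _check_input(self, x: Tensor) -> None:
        if x.shape[-1] != self.n_frames:
            raise ValueError(
                f"this model collapses a {self.n_frames}-frame time axis; got T={x.shape[-1]}"
            )
        _check_divisible(x.shape, (2, 3), what="X,Y")

    def arm_features(self, x) -> Tensor:
        """Pre-collapse feature map (N, base, X, Y, T)."""
        x = x if isinstance(x, Tensor) else ad.tensor(x)
        self._check_input(x)
        h = self.pre_norm(x)
        skips = []
        for blocks, pool in zip(self.enc, self.pools):
            for blk in blocks:
                h = blk(h)
            skips.append(h)
            h = pool(h)
        for blk in self.bottleneck:
            h = blk(h)
        for up, blocks, skip in zip(self.up, self.dec, reversed(skips)):
            h = ad.concat([up(h), skip], axis=1)
            for blk in blocks:
                h = blk(h)
        return h

    def collapse_and_head(self, feats: Tensor) -> Tensor:
        h = ad.relu(self.collapse_norm(self.collapse(feats)))
        h = ad.reshape(h, h.shape[:-1])  # drop the singleton time axis
        return ad.sigmoid(self.head(h))

    def __call__(self, x) -> Tensor:
        return self.collapse_and_head(self.arm_features(x))


class _Refinement(Module):
    """Three-convolution fusion block in one of four topologies."""

    def __init__(self, topology: str, c_in: int, width: int, rng: np.random.Generator):
        if topology not in REFINEMENTS:
            raise ValueError(f"unknown refinement {topology!r}; choose from {REFINEMENTS}")
        self.topology = topology
        k = (3, 3, 3)
        if topology in ("cnn", "residual"):
            self.blocks = [
                ConvBlock(c_in, width, k, rng),
                ConvBlock(width, width, k, rng),
                ConvBlock(width, width, k, rng),
            ]
        else:  # dense topologies concatenate all previous outputs
            self.blocks = [
                ConvBlock(c_in, width, k, rng),
                ConvBlock(c_in + width, width, k, rng),
                ConvBlock(c_in + 2 * width, width, k, rng),
            ]

    def __call__(self, x: Tensor) -> Tensor:
        if self.topology == "cnn":
            y = self.blocks[0](x)
            y = self.blocks[1](y)
            return self.blocks[2](y)
        if self.topology == "residual":
            y1 = self.blocks[0](x)
            y2 = self.blocks[1](y1)
            return self.blocks[2](y2) + y1
        y1 = self.blocks[0](x)
        y2 = self.blocks[1](ad.concat([x, y1], axis=1))
        y3 = self.blocks[2](ad.concat([x, y1, y2], axis=1))
        if self.topology == "dense":
            return y3
        return y3 + y1  # resdense


class ST4D(Module):
    """Three weight-shared ST3D arms + refinement over three adjacent slices.

    Input ``(N, 1, X, Y, 3, T)``; outputs ``(main, deep_supervision)``, both
    2D probability maps for the *center* slice.
    """

    def __init__(self, base: int, n_frames: int, refinement: str, rng: np.random.Generator):
        b = base
        self.arm = ST3D(b, n_frames, rng)  # single shared weight set
        self.tmip_norm = InstanceNorm(1)  # the raw tMIP is on the input scale
        self.refine = _Refinement(refinement, 3 * b + 1, b, rng)
        self.collapse = Conv(b, b, (1, 1, n_frames), rng, padding="valid")
        self.collapse_norm = InstanceNorm(b)
        self.head = _prior_head(Conv(b, 1, (1, 1), rng))
        # deep-supervision head on the middle arm (its own collapse + sigmoid)
        self.ds_collapse = Conv(b, b, (1, 1, n_frames), rng, padding="valid")
        self.ds_norm = InstanceNorm(b)
        self.ds_head = _prior_head(Conv(b, 1, (1, 1), rng))

    def __call__(self, x) -> tuple[Tensor, Tensor]:
        data = x.data if isinstance(x, Tensor) else np.asarray(x, dtype=np.float32)
        if data.ndim != 6 or data.shape[4] != 3:
            raise ValueError(f"expected (N,1,X,Y,3,T) input, got shape {data.shape}")
        n = data.shape[0]
        # weight sharing lets the three arms run as one batched forward pass
        stacked = np.concatenate([data[:, :, :, :, z, :] for z in range(3)], axis=0)
        all_feats = self.arm.arm_features(stacked)  # (3N, base, X, Y, T)
        feats = [ad.narrow(all_feats, 0, z * n, n) for z in range(3)]

        # tMIP of the 3-slice input, replicated along the time axis as a skip
        # (normalized so it concatenates on the same scale as the arm features)
        tmip = data.max(axis=(4, 5))  # (N, 1, X, Y)
        tmip_rep = np.broadcast_to(tmip[..., None], feats[1].shape[:1] + (1,) + feats[1].shape[2:])
        tmip_t = self.tmip_norm(ad.tensor(np.ascontiguousarray(tmip_rep)))
        fused = ad.concat(feats + [tmip_t], axis=1)

        h = self.refine(fused)
        h = ad.relu(self.collapse_norm(self.collapse(h)))
        h = ad.reshape(h, h.shape[:-1])
        main = ad.sigmoid(self.head(h))

        d = ad.relu(self.ds_norm(self.ds_collapse(feats[1])))
        d = ad.reshape(d, d.shape[:-1])
        deep = ad.sigmoid(self.ds_head(d))
        return main, deep


def build_unet2d(base_channels: int = 64, seed: int = 0) -> _SpatialUNet:
    """2D U-Net on tMIP slices; default width plan 64 -> 512."""
    return _SpatialUNet(2, base_channels, np.random.default_rng(seed))


def build_unet3d(base_channels: int = 64, seed: int = 0) -> _SpatialUNet:
    """3D U-Net on volumetric patches (X, Y, Z all divisible by 8)."""
    return _SpatialUNet(3, base_channels, np.random.default_rng(seed))


def build_st3d(base_channels: int = 32, n_frames: int = 24, seed: int = 0) -> ST3D:
    return ST3D(base_channels, n_frames, np.random.default_rng(seed))


def build_st4d(
    refinement: str = "resdense", base_channels: int = 32, n_frames: int = 24, seed: int = 0
) -> ST4D:
    return ST4D(base_channels, n_frames, refinement, np.random.default_rng(seed))


def build_model(config: ArchConfig):
    """Build any variant from a declarative configuration."""
    if config.variant == "unet2d":
        return build_unet2d(config.base_channels or 64, seed=config.seed)
    if config.variant == "unet3d":
        return build_unet3d(config.base_channels or 64, seed=config.seed)
    if config.variant == "st3d":
        return build_st3d(config.base_channels, config.n_frames, seed=config.seed)
    return build_st4d(config.refinement, config.base_channels, config.n_frames, seed=config.seed)


def save_weights(model: Module, path) -> None:
    np.savez(path, **model.state_dict())


def load_weights(model: Module, path) -> None:
    with np.load(path) as data:
        model.load_state_dict({k: data[k] for k in data.files})
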