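"""Layer wrappers holding parameters, plus a small module base class."""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["Module", "Conv", "UpConv", "MaxPool", "InstanceNorm", "ConvBlock"]


class Module:
    """Base: anything with named parameters, discovered recursively."""

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []

        def visit(key: str, val) -> None:
            if isinstance(val, Tensor):
                if val.requires_grad:
                    out.append((key, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=f"{key}."))
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    visit(f"{key}.{i}", item)

        for name, val in vars(self).items():
            visit(f"{prefix}{name}", val)
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(int(p.data.size) for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        if set(own) != set(state):
            missing = set(own) ^ set(state)
            raise KeyError(f"state dict keys mismatch: {sorted(missing)}")
        for k, p in own.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()


class Conv(Module):
    """Stride-1 N-D convolution with bias; He-normal initialized."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, ...], rng: np.random.Generator,
                 padding="same"):
        fan_in = c_in * int(np.prod(kernel))
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, *kernel))
        self.w = ad.parameter(w)
        self.b = ad.parameter(np.zeros(c_out))
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return ad.conv_nd(x, self.w, self.b, padding=self.padding)


class UpConv(Module):
    """Transposed convolution with kernel = stride (2x learned upsampling)."""

    def __init__(self, c_in: int, c_out: int, factors: tuple[int, ...], rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / c_in), size=(c_in, c_out, *factors))
        self.w = ad.parameter(w)
        self.b = ad.parameter(np.zeros(c_out))
        self.factors = tuple(factors)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.upconv_nd(x, self.w, self.b, self.factors)


class MaxPool(Module):
    def __init__(self, factors: tuple[int, ...]):
        self.factors = tuple(factors)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.maxpool_nd(x, self.factors)


class InstanceNorm(Module):
    """Instance normalization with learnable per-channel scale and shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.gamma = ad.parameter(np.ones(channels))
        self.beta = ad.parameter(np.zeros(channels))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return ad.instance_norm(x, self.gamma, self.beta, self.eps)


class ConvBlock(Module):
    """convolution -> instance normalization -> ReLU (the pre-activation order
    used throughout the network family)."""

    def __init__(self, c_in: int, c_out: int, kernel: tuple[int, ...], rng: np.random.Generator,
                 padding="same"):
        self.conv = Conv(c_in, c_out, kernel, rng, padding=padding)
        self.norm = InstanceNorm(c_out)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.relu(self.norm(self.conv(x)))
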