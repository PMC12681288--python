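"""Layer modules built on the numpy autodiff engine."""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "InstanceNorm3d",
    "LeakyReLU",
    "Dropout",
    "MaxPool3d",
    "TrilinearUpsample",
    "Sequential",
    "ConvBlock",
]

DTYPE = np.float32


class Module:
    """Base class: parameter discovery, train/eval mode, named state."""

    def __init__(self):
        self.training = True

    def modules(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item
                        yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, v in self.__dict__.items():
            if isinstance(v, Parameter):
                yield f"{prefix}{name}", v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{prefix}{name}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True):
        self.training = mode
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for name, p in params.items():
            arr = np.asarray(state[name], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _uniform_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv3d(Module):
    """3x3x3 (or 1x1x1) convolution, stride 1, 'same' zero padding."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel**3
        self.weight = Parameter(
            _uniform_init(rng, (out_channels, in_channels, kernel, kernel, kernel), fan_in)
        )
        self.bias = Parameter(_uniform_init(rng, (out_channels,), fan_in))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv3d(x, self.weight, self.bias)


class ConvTranspose3d(Module):
    """Transpose convolution with kernel == stride (default 2)."""

    def __init__(
        self, in_channels: int, out_channels: int, rng: np.random.Generator, kernel: int = 2
    ):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = in_channels * kernel**3
        self.weight = Parameter(
            _uniform_init(rng, (in_channels, out_channels, kernel, kernel, kernel), fan_in)
        )
        self.bias = Parameter(_uniform_init(rng, (out_channels,), fan_in))

    def forward(self, x: Tensor) -> Tensor:
        return ag.conv_transpose3d(x, self.weight, self.bias)


class InstanceNorm3d(Module):
    """Per-channel spatial normalization without learned affine parameters."""

    def forward(self, x: Tensor) -> Tensor:
        return ag.instance_norm(x)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return ag.leaky_relu(x, self.slope)


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        return ag.dropout(x, self.p, self.rng, self.training)


class MaxPool3d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return ag.maxpool2(x)


class TrilinearUpsample(Module):
    """Parameter-free trilinear interpolation to a target spatial shape."""

    def forward(self, x: Tensor, out_shape) -> Tensor:
        return ag.upsample_trilinear(x, tuple(out_shape))


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ConvBlock(Module):
    """Two 3x3x3 convolutions, each followed by instance norm, leaky ReLU, dropout."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        dropout: float,
        rng: np.random.Generator,
        slope: float = 0.2,
    ):
        super().__init__()
        self.block = Sequential(
            Conv3d(in_channels, out_channels, 3, rng),
            InstanceNorm3d(),
            LeakyReLU(slope),
            Dropout(dropout, rng),
            Conv3d(out_channels, out_channels, 3, rng),
            InstanceNorm3d(),
            LeakyReLU(slope),
            Dropout(dropout, rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.block(x)
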