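"""3D U-Net and Half U-Net regularizers.

The U-Net doubles channels and halves resolution per encoder stage and
mirrors this in a learned decoder with skip concatenations.  The Half U-Net
keeps a constant channel width in the encoder and strips the decoder down to
parameter-free upsampling plus a sum, with learned operators only in the
final stage.

Both networks optionally accept same-resolution features cached by the
regularizer of the previous cascade (the dense-cascade interconnections) and
return their own features for the next cascade.
"""

from __future__ import annotations

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .layers import (
    Conv3d,
    ConvBlock,
    ConvTranspose3d,
    MaxPool3d,
    Module,
    TrilinearUpsample,
)

__all__ = [
    "UNet3D",
    "HalfUNet3D",
    "pool_pad_widths",
    "pad_to_pool_grid",
    "crop_from_pool_grid",
    "normalize_two_channel",
    "denormalize_two_channel",
]


# ---------------------------------------------------------------------------
# pool-grid padding
# ---------------------------------------------------------------------------


def pool_pad_widths(spatial_shape, stages: int):
    """Symmetric zero-pad widths taking each dim to a multiple of 2**(stages-1)."""
    m = 2 ** (stages - 1)
    widths = []
    for n in spatial_shape:
        target = -(-n // m) * m
        extra = target - n
        widths.append((extra // 2, extra - extra // 2))
    return tuple(widths)


def pad_to_pool_grid(volume: np.ndarray, stages: int):
    """Pad the spatial dims of a (C, X, Y, Z) array for ``stages``-level pooling.

    Returns the padded array and the crop record that inverts the padding.
    """
    volume = np.asarray(volume)
    if volume.ndim != 4:
        raise ValueError(f"expected (C, X, Y, Z), got shape {volume.shape}")
    pads = pool_pad_widths(volume.shape[1:], stages)
    return np.pad(volume, ((0, 0), *pads)), pads


def crop_from_pool_grid(volume: np.ndarray, pads) -> np.ndarray:
    """Invert :func:`pad_to_pool_grid` using its crop record."""
    sl = tuple(slice(lo, volume.shape[i + 1] - hi) for i, (lo, hi) in enumerate(pads))
    return volume[(slice(None), *sl)]


# ---------------------------------------------------------------------------
# two-channel normalization (array-level API; tensor ops live in autograd)
# ---------------------------------------------------------------------------


def normalize_two_channel(volume: np.ndarray):
    """Normalize jointly over both channels to mean 0, SD 1.

    A constant volume takes the sentinel path: output is all zeros and the
    reported SD is 1, so denormalization restores the input.
    """
    volume = np.asarray(volume)
    m = float(volume.mean())
    s = float(volume.std())
    if s == 0.0:
        return volume - m, m, 1.0
    return (volume - m) / s, m, s


def denormalize_two_channel(volume: np.ndarray, mean: float, sd: float) -> np.ndarray:
    return volume * sd + mean


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------


class UNet3D(Module):
    """Encoder-decoder with channel doubling and learned transpose-conv upsampling.

    ``interconnect=True`` widens every decoder block's first convolution to
    accept the matching decoder feature of the previous cascade (3c instead
    of 2c input channels).
    """

    def __init__(
        self,
        in_channels: int,
        stages: int,
        base_channels: int,
        dropout: float,
        rng: np.random.Generator,
        out_channels: int = 2,
        interconnect: bool = False,
    ):
        super().__init__()
        if stages < 2:
            raise ValueError("stages must be >= 2")
        self.stages = stages
        self.interconnect = interconnect
        ch = base_channels

        self.enc_blocks = []
        c_in = in_channels
        for i in range(stages):
            c_out = ch * 2**i
            self.enc_blocks.append(ConvBlock(c_in, c_out, dropout, rng))
            c_in = c_out
        self.pool = MaxPool3d()

        self.up_convs = []
        self.dec_blocks = []
        for i in range(stages - 1, 0, -1):
            c_hi, c_lo = ch * 2**i, ch * 2 ** (i - 1)
            self.up_convs.append(ConvTranspose3d(c_hi, c_lo, rng))
            dec_in = (3 if interconnect else 2) * c_lo
            self.dec_blocks.append(ConvBlock(dec_in, c_lo, dropout, rng))
        self.final = Conv3d(ch, out_channels, 1, rng)

    def forward(self, x: Tensor, prev_cache=None):
        if any(n % 2 ** (self.stages - 1) for n in x.shape[1:]):
            raise ValueError(f"input {x.shape[1:]} not padded to the pool grid")
        if self.interconnect and prev_cache is None:
            raise ValueError("interconnected U-Net needs the previous cascade's cache")
        skips = []
        for i, block in enumerate(self.enc_blocks):
            x = block(x)
            if i < self.stages - 1:
                skips.append(x)
                x = self.pool(x)
        cache = []
        for j, (up, block) in enumerate(zip(self.up_convs, self.dec_blocks)):
            x = up(x)
            parts = [x, skips[-(j + 1)]]
            if self.interconnect:
                parts.append(prev_cache[j])
            x = block(ag.concat(parts))
            cache.append(x)
        return self.final(x), cache


class _FactorUpsample(Module):
    """Single-shot transpose convolution with kernel = stride = 2**level."""

    def __init__(self, channels: int, factor: int, rng: np.random.Generator):
        super().__init__()
        self.up = ConvTranspose3d(channels, channels, rng, kernel=factor)

    def forward(self, x: Tensor, out_shape) -> Tensor:
        return self.up(x)


class HalfUNet3D(Module):
    """Constant-width encoder with an upsample-and-sum decoder.

    All learned decoder operators live in the final stage: after summing the
    upsampled per-level features, a two-convolution block and a 1x1x1 output
    convolution are applied.  ``interconnect=True`` concatenates the previous
    cascade's pre-final-block sum to the current one, widening the final
    block's first convolution to 2*ch input channels.
    """

    def __init__(
        self,
        in_channels: int,
        stages: int,
        base_channels: int,
        dropout: float,
        rng: np.random.Generator,
        out_channels: int = 2,
        interconnect: bool = False,
        upsampling: str = "trilinear",
    ):
        super().__init__()
        if stages < 2:
            raise ValueError("stages must be >= 2")
        if upsampling not in ("trilinear", "transpose_conv"):
            raise ValueError(f"unknown upsampling mode {upsampling!r}")
        self.stages = stages
        self.interconnect = interconnect
        ch = base_channels

        self.enc_blocks = [ConvBlock(in_channels, ch, dropout, rng)]
        for _ in range(stages - 1):
            self.enc_blocks.append(ConvBlock(ch, ch, dropout, rng))
        self.pool = MaxPool3d()
        if upsampling == "trilinear":
            self.upsamplers = [TrilinearUpsample() for _ in range(stages - 1)]
        else:
            self.upsamplers = [
                _FactorUpsample(ch, 2 ** (i + 1), rng) for i in range(stages - 1)
            ]
        self.final_block = ConvBlock((2 if interconnect else 1) * ch, ch, dropout, rng)
        self.final = Conv3d(ch, out_channels, 1, rng)

    def forward(self, x: Tensor, prev_cache=None):
        if any(n % 2 ** (self.stages - 1) for n in x.shape[1:]):
            raise ValueError(f"input {x.shape[1:]} not padded to the pool grid")
        if self.interconnect and prev_cache is None:
            raise ValueError("interconnected Half U-Net needs the previous cascade's cache")
        full_shape = x.shape[1:]
        feats = []
        for i, block in enumerate(self.enc_blocks):
            x = block(x)
            feats.append(x)
            if i < self.stages - 1:
                x = self.pool(x)
        parts = [feats[0]]
        for i, up in enumerate(self.upsamplers):
            parts.append(up(feats[i + 1], full_shape))
        total = ag.add_n(parts)
        cache = total
        if self.interconnect:
            total = ag.concat([prev_cache, total])
        return self.final(self.final_block(total)), cache
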