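"""Unrolled cascades: VarNet, HalfVarNet, DIRCN, HalfDIRCN.

Each cascade performs

    k_{it+1} = k_it - mu_it * D (k_it - k_us) + F R_it(F^H k_it)

where R_it is the cascade's regularizer (a 3D U-Net or Half U-Net) wrapped
in whole-tensor normalization and pool-grid padding.  The dense variants
feed the channel concatenation of all previous image iterates into R_it and
interconnect same-resolution features of consecutive regularizers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ..kspace import SamplingMask
from . import autograd as ag
from .autograd import Parameter, Tensor
from .layers import DTYPE, Module
from .unet import HalfUNet3D, UNet3D, pool_pad_widths

__all__ = ["NetworkConfig", "CascadeTrace", "UnrolledNetwork", "varnet_apply", "dircn_apply"]

VARIANTS = ("varnet", "halfvarnet", "dircn", "halfdircn")


@dataclass
class NetworkConfig:
    """Architecture hyperparameters; defaults follow the training recipe
    (32 base channels, five stages i.e. four poolings, dropout 0.25,
    trilinear upsampling in the Half U-Net)."""

    variant: str = "varnet"
    cascades: int = 8
    base_channels: int = 32
    stages: int = 5
    dropout: float = 0.25
    upsampling: str = "trilinear"
    in_channels: int = 2

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.cascades < 1:
            raise ValueError("cascades must be >= 1")
        if self.stages < 2:
            raise ValueError("stages must be >= 2")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must lie in [0, 1)")
        if self.upsampling not in ("trilinear", "transpose_conv"):
            raise ValueError(f"unknown upsampling mode {self.upsampling!r}")

    @property
    def is_half(self) -> bool:
        return self.variant in ("halfvarnet", "halfdircn")

    @property
    def is_dense(self) -> bool:
        return self.variant in ("dircn", "halfdircn")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class CascadeTrace:
    """Intermediate state of the unrolled iteration.

    ``image_history`` holds the two-channel image iterates F^H k_1 .. F^H k_it;
    ``decoder_cache`` the previous regularizer's per-stage features (dense
    variants only); ``mu_list`` the learned per-cascade step scalars.
    """

    image_history: list[np.ndarray]
    decoder_cache: list[np.ndarray] | None
    mu_list: list[float]

    def __post_init__(self) -> None:
        if self.decoder_cache is not None and not self.image_history:
            raise ValueError("decoder cache cannot precede the first iterate")


def _complex_to_channels(k: np.ndarray) -> np.ndarray:
    return np.stack([k.real, k.imag]).astype(DTYPE)


def _channels_to_complex(x: np.ndarray) -> np.ndarray:
    return x[0] + 1j * x[1]


class UnrolledNetwork(Module):
    """Cascaded data-consistency + learned-regularizer reconstruction network."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(seed)
        self.regularizers = []
        for it in range(config.cascades):
            in_ch = config.in_channels * (it + 1) if config.is_dense else config.in_channels
            interconnect = config.is_dense and it > 0
            if config.is_half:
                reg = HalfUNet3D(
                    in_ch,
                    config.stages,
                    config.base_channels,
                    config.dropout,
                    rng,
                    out_channels=config.in_channels,
                    interconnect=interconnect,
                    upsampling=config.upsampling,
                )
            else:
                reg = UNet3D(
                    in_ch,
                    config.stages,
                    config.base_channels,
                    config.dropout,
                    rng,
                    out_channels=config.in_channels,
                    interconnect=interconnect,
                )
            self.regularizers.append(reg)
        # one learned gradient-step scalar per cascade, initialized to 1
        self.mus = [Parameter(np.ones((), dtype=DTYPE)) for _ in range(config.cascades)]

    # -- regularizer wrapper ------------------------------------------------

    def _regularize(self, it: int, net_in: Tensor, img: Tensor, prev_cache):
        pads = pool_pad_widths(net_in.shape[1:], self.config.stages)
        y, _, _ = ag.normalize_whole(net_in)
        y = ag.pad_spatial(y, pads)
        out, cache = self.regularizers[it](y, prev_cache)
        out = ag.crop_spatial(out, pads)
        out = ag.denormalize_scale(out, net_in)
        if self.config.is_dense:
            out = ag.add(out, img)  # identity residual from the current iterate
        return out, cache

    # -- unrolled forward ---------------------------------------------------

    def forward(
        self,
        k_us,
        mask: SamplingMask,
        return_kspace: bool = False,
        return_trace: bool = False,
    ):
        """Reconstruct from zero-filled undersampled k-space.

        ``k_us`` may be a complex (Nx, Ny, Nz) array or a two-channel
        (2, Nx, Ny, Nz) array.  Returns the two-channel image tensor (plus
        the final k-space tensor and/or a :class:`CascadeTrace` when
        requested).
        """
        k_arr = np.asarray(k_us.data if hasattr(k_us, "data") else k_us)
        if np.iscomplexobj(k_arr):
            k_arr = _complex_to_channels(k_arr)
        k_arr = k_arr.astype(DTYPE)
        if k_arr.ndim != 4 or k_arr.shape[0] != 2:
            raise ValueError(f"expected (2, Nx, Ny, Nz) k-space, got {k_arr.shape}")
        if k_arr.shape[2:] != mask.shape:
            raise ValueError(f"mask plane {mask.shape} does not match k-space {k_arr.shape}")
        maskb = mask.plane.astype(DTYPE)[None, None, :, :]

        k = Tensor(k_arr)
        k_ref = Tensor(k_arr)
        history: list[Tensor] = []
        cache = None
        for it in range(self.config.cascades):
            img = ag.ifft2ch(k)
            history.append(img)
            net_in = ag.concat(history) if self.config.is_dense else img
            reg_out, new_cache = self._regularize(
                it, net_in, img, cache if (self.config.is_dense and it > 0) else None
            )
            cache = new_cache
            model_k = ag.fft2ch(reg_out)
            dc = ag.scale(ag.mul_const(ag.sub(k, k_ref), maskb), self.mus[it])
            k = ag.add(ag.sub(k, dc), model_k)
        img = ag.ifft2ch(k)
        out = [img]
        if return_kspace:
            out.append(k)
        if return_trace:
            cache_data = None
            if self.config.is_dense and cache is not None:
                cached = cache if isinstance(cache, list) else [cache]
                cache_data = [c.data for c in cached]
            out.append(
                CascadeTrace(
                    image_history=[h.data for h in history],
                    decoder_cache=cache_data,
                    mu_list=[float(m.data) for m in self.mus],
                )
            )
        return out[0] if len(out) == 1 else tuple(out)

    def reconstruct(self, k_us, mask: SamplingMask) -> np.ndarray:
        """Inference helper: complex image volume as a plain array."""
        was_training = self.training
        self.eval()
        try:
            img = self.forward(k_us, mask)
        finally:
            self.train(was_training)
        return _channels_to_complex(img.data)


def _apply(variants: tuple[str, ...], k_us, mask, config: NetworkConfig, weights=None, seed=0):
    if config.variant not in variants:
        raise ValueError(f"expected variant in {variants}, got {config.variant!r}")
    net = UnrolledNetwork(config, seed=seed)
    if weights is not None:
        net.load_state_dict(weights)
    return net.reconstruct(k_us, mask)


def varnet_apply(k_us, mask, config: NetworkConfig, weights=None, seed: int = 0) -> np.ndarray:
    """Run a (Half)VarNet reconstruction; returns a complex image volume."""
    return _apply(("varnet", "halfvarnet"), k_us, mask, config, weights, seed)


def dircn_apply(k_us, mask, config: NetworkConfig, weights=None, seed: int = 0) -> np.ndarray:
    """Run a (Half)DIRCN reconstruction; returns a complex image volume."""
    return _apply(("dircn", "halfdircn"), k_us, mask, config, weights, seed)
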