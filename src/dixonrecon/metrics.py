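"""Reconstruction, fat-fraction, and segmentation-agreement metrics.

All FF-map metrics operate in percent units with peak 100 and evaluate
foreground voxels only (background removed).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .dixon import FFMap

__all__ = [
    "mse_metric",
    "psnr_metric",
    "ssim_metric",
    "ff_quadratic_error",
    "ff_abs_difference",
    "dice_coefficient",
    "sens_spec",
    "bland_altman",
    "mean_stderr",
]


def _common_foreground(ref: FFMap, rec: FFMap) -> np.ndarray:
    if ref.values.shape != rec.values.shape:
        raise ValueError("FF map shapes differ")
    if not np.array_equal(ref.foreground, rec.foreground):
        raise ValueError("FF maps must share the same foreground mask")
    fg = ref.foreground
    if not fg.any():
        raise ValueError("empty foreground")
    return fg


def mse_metric(ref: FFMap, rec: FFMap) -> float:
    """Mean squared FF difference over foreground voxels (percent^2)."""
    fg = _common_foreground(ref, rec)
    d = ref.values[fg] - rec.values[fg]
    return float(np.mean(d * d))


def psnr_metric(ref: FFMap, rec: FFMap, peak: float = 100.0) -> float:
    """10*log10(peak^2 / MSE) in dB; infinite for identical maps."""
    m = mse_metric(ref, rec)
    if m == 0:
        return float("inf")
    return float(10.0 * np.log10(peak**2 / m))


def ssim_metric(
    ref: FFMap, rec: FFMap, window: int = 7, data_range: float = 100.0
) -> float:
    """Mean local SSIM over foreground-centered windows.

    Uniform (unweighted) window, standard stabilizers C1=(0.01 R)^2 and
    C2=(0.03 R)^2 with sample (ddof=1) local variances; windows are
    restricted to centers whose window lies fully inside the volume, the
    same interior crop a reference implementation applies.
    """
    fg = _common_foreground(ref, rec)
    x = ref.values.astype(np.float64)
    y = rec.values.astype(np.float64)
    if any(window > n for n in x.shape):
        raise ValueError(f"window {window} exceeds volume shape {x.shape}")

    def filt(a):
        return ndimage.uniform_filter(a, size=window)

    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    ux, uy = filt(x), filt(y)
    n = window ** x.ndim
    cov_norm = n / (n - 1)
    vx = cov_norm * (filt(x * x) - ux * ux)
    vy = cov_norm * (filt(y * y) - uy * uy)
    vxy = cov_norm * (filt(x * y) - ux * uy)
    ssim_map = ((2 * ux * uy + c1) * (2 * vxy + c2)) / (
        (ux**2 + uy**2 + c1) * (vx + vy + c2)
    )
    pad = (window - 1) // 2
    interior = np.zeros_like(fg)
    interior[(slice(pad, -pad),) * fg.ndim] = True
    support = fg & interior
    if not support.any():
        raise ValueError("foreground vanishes after the window crop")
    return float(ssim_map[support].mean())


def ff_quadratic_error(ff_ref: float, ff_rec: float) -> float:
    """Relative quadratic FF error in percent: 100*((rec-ref)/ref)^2."""
    if ff_ref <= 0:
        raise ValueError("reference FF must be positive")
    return float(100.0 * ((ff_rec - ff_ref) / ff_ref) ** 2)


def ff_abs_difference(ff_ref: float, ff_rec: float) -> float:
    return float(abs(ff_rec - ff_ref))


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """2|A n B| / (|A| + |B|); two empty masks agree perfectly (1)."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def sens_spec(pred: np.ndarray, truth: np.ndarray) -> tuple[float, float]:
    """(sensitivity, specificity); NaN where the denominator is empty."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    tp = np.logical_and(pred, truth).sum()
    tn = np.logical_and(~pred, ~truth).sum()
    fn = np.logical_and(~pred, truth).sum()
    fp = np.logical_and(pred, ~truth).sum()
    sens = tp / (tp + fn) if (tp + fn) else float("nan")
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return float(sens), float(spec)


def bland_altman(ref_values, rec_values) -> tuple[float, float, float]:
    """Bias and 95% limits of agreement: bias +- 1.96*SD of differences."""
    ref = np.asarray(ref_values, dtype=np.float64)
    rec = np.asarray(rec_values, dtype=np.float64)
    if ref.shape != rec.shape:
        raise ValueError("value lists differ in length")
    if ref.size < 2:
        raise ValueError("need at least two paired values")
    d = rec - ref
    bias = float(d.mean())
    sd = float(d.std())
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def mean_stderr(values) -> tuple[float, float]:
    """Aggregate per-volume metrics as mean +- standard error."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("no values to aggregate")
    if v.size == 1:
        return float(v[0]), 0.0
    return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))
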