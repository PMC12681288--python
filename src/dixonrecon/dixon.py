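"""Three-point Dixon water-fat separation and fat-fraction maps.

The first three echoes follow an out-of-phase / in-phase / out-of-phase
pattern: with echo spacing dTE the fat-water chemical shift advances by pi
per echo.  The direct three-point scheme below removes the smooth B0 phase
(half the phase accrued between the two out-of-phase echoes) and resolves
the dominant species with a sign term, without phase unwrapping.  It is
exact on noiseless voxels as long as the off-resonance phase per dTE stays
within +-pi/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .kspace import AcquisitionSpec

__all__ = [
    "EchoStack",
    "FFMap",
    "ROILabelMap",
    "three_point_dixon",
    "background_mask",
    "roi_mean_ff",
]

THIGH_MUSCLES = (
    "ADD",  # adductor
    "SM",  # semimembranosus
    "ST",  # semitendinosus
    "BF",  # biceps femoris
    "VI",  # vastus intermedius
    "GRA",  # gracilis
    "SAR",  # sartorius
    "VM",  # vastus medialis
    "RF",  # rectus femoris
    "VL",  # vastus lateralis
)


@dataclass
class EchoStack:
    """Ordered complex image-domain echoes with their echo times (ms)."""

    echoes: np.ndarray  # (n_echoes, Nx, Ny, Nz) complex
    TE_list: tuple[float, ...]

    def __post_init__(self) -> None:
        self.echoes = np.asarray(self.echoes)
        if self.echoes.ndim != 4:
            raise ValueError(f"echoes must be (n, Nx, Ny, Nz), got {self.echoes.shape}")
        if len(self.TE_list) != self.echoes.shape[0]:
            raise ValueError("TE_list length must match the number of echoes")
        if self.echoes.shape[0] < 3:
            raise ValueError("Dixon processing needs at least three echoes")
        te = np.asarray(self.TE_list)
        steps = np.diff(te)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-3):
            raise ValueError("echo times must increase with a constant step")

    @property
    def n_echoes(self) -> int:
        return self.echoes.shape[0]


@dataclass
class FFMap:
    """Per-voxel fat fraction in percent with a foreground support mask."""

    values: np.ndarray
    foreground: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.foreground = np.asarray(self.foreground).astype(bool)
        if self.values.shape != self.foreground.shape:
            raise ValueError("values and foreground shapes differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("FF map contains non-finite values")
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("FF values must lie in [0, 100] percent")

    def masked(self) -> "FFMap":
        """Zero out background voxels."""
        return FFMap(np.where(self.foreground, self.values, 0.0), self.foreground)


@dataclass
class ROILabelMap:
    """Integer label volume; 0 is background, 1..n are muscles."""

    labels: np.ndarray
    label_names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integers")

    def region(self, label: int) -> np.ndarray:
        return self.labels == label


def three_point_dixon(
    stack: EchoStack, foreground: np.ndarray | None = None, eps_rel: float = 1e-6
) -> FFMap:
    """Fat-fraction map (percent) from the first three echoes.

    Per voxel with echo signals S1, S2, S3:

        phi = arg(S3 * conj(S1)) / 2          (B0 phase per echo, mod pi)
        c   = Re{S1 * conj(S2) * e^{i phi}}   (dominant-species discriminant)
        W   = (|S2| + sign(c)|S1|) / 2
        F   = (|S2| - sign(c)|S1|) / 2
        FF  = 100 * F / (W + F), clamped to [0, 100]

    Voxels with (numerically) vanishing in-phase signal, |S2| <= eps_rel *
    max|S2|, are indeterminate and get FF = 50.
    """
    s1, s2, s3 = stack.echoes[0], stack.echoes[1], stack.echoes[2]
    phi = np.angle(s3 * np.conj(s1)) / 2.0
    c = np.real(s1 * np.conj(s2) * np.exp(1j * phi))
    s = np.where(c >= 0, 1.0, -1.0)
    mag2 = np.abs(s2)
    water = (mag2 + s * np.abs(s1)) / 2.0
    fat = (mag2 - s * np.abs(s1)) / 2.0
    total = water + fat  # == |S2|
    thr = eps_rel * mag2.max()
    ok = total > thr
    with np.errstate(divide="ignore", invalid="ignore"):
        ff = np.where(ok, 100.0 * fat / np.where(ok, total, 1.0), 50.0)
    ff = np.clip(ff, 0.0, 100.0)
    if foreground is None:
        foreground = background_mask(np.abs(s1))
    return FFMap(np.where(foreground, ff, 0.0), foreground)


def background_mask(echo1_magnitude: np.ndarray) -> np.ndarray:
    """Foreground support from the first-echo magnitude.

    Otsu threshold, per-slice hole filling, then largest connected
    component.  All-zero input yields an empty foreground; a constant
    positive volume is all foreground.
    """
    mag = np.asarray(echo1_magnitude, dtype=np.float64)
    if np.any(mag < 0):
        raise ValueError("magnitudes must be non-negative")
    if mag.max() == 0:
        return np.zeros(mag.shape, dtype=bool)
    if mag.min() == mag.max():
        return np.ones(mag.shape, dtype=bool)
    thr = threshold_otsu(mag)
    fg = mag > thr
    for z in range(fg.shape[2]):
        fg[:, :, z] = ndimage.binary_fill_holes(fg[:, :, z])
    labels, n = ndimage.label(fg)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
        fg = labels == (1 + int(np.argmax(sizes)))
    return fg


def roi_mean_ff(ff: FFMap, rois: ROILabelMap, label: int) -> float:
    """Mean fat fraction (percent) over one labeled muscle."""
    if ff.values.shape != rois.labels.shape:
        raise ValueError("FF map and label map shapes differ")
    region = rois.region(label)
    if not region.any():
        raise ValueError(f"ROI label {label} is empty")
    return float(ff.values[region].mean())


def default_acquisition() -> AcquisitionSpec:
    return AcquisitionSpec()
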