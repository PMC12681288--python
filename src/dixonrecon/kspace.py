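"""Fourier operators, undersampling masks, and the data-consistency residual.

All Fourier transforms are centered (DC at the array center) and orthonormal,
so ``fft3c`` is unitary and its adjoint equals its inverse.  Undersampling
lives on the (ky, kz) phase-encode plane and is broadcast along the fully
sampled readout axis kx.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AcquisitionSpec",
    "KSpaceVolume",
    "SamplingMask",
    "fft3c",
    "ifft3c",
    "generate_vd_poisson_mask",
    "apply_mask_zero_fill",
    "dc_residual",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AcquisitionSpec:
    """3D GRE Dixon acquisition protocol.

    The default instance is the thigh protocol: TR 22 ms, 8 echoes with
    TE from 2.38 ms to 19.06 ms in 2.38 ms steps, 5 degree flip angle,
    matrix 128 x 128 x 36 at 1.72 x 1.72 x 5.00 mm^3.
    """

    TR: float = 22.0
    TE_list: tuple[float, ...] = tuple(round(2.38 * n, 2) for n in range(1, 9))
    flip_angle: float = 5.0
    matrix: tuple[int, int, int] = (128, 128, 36)
    resolution: tuple[float, float, float] = (1.72, 1.72, 5.00)

    def __post_init__(self) -> None:
        te = np.asarray(self.TE_list, dtype=float)
        if te.size < 2:
            raise ValueError("TE_list needs at least two echoes")
        steps = np.diff(te)
        if np.any(steps <= 0):
            raise ValueError("TE_list must be strictly increasing")
        if not np.allclose(steps, steps[0], atol=1e-6):
            raise ValueError("TE_list must have a constant echo spacing")

    @property
    def delta_te(self) -> float:
        """Echo spacing in ms."""
        return float(self.TE_list[1] - self.TE_list[0])

    @property
    def n_echoes(self) -> int:
        return len(self.TE_list)


@dataclass
class KSpaceVolume:
    """Single-coil complex k-space of one echo, shape (Nx, Ny, Nz)."""

    data: np.ndarray
    echo_index: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"k-space volume must be 3D, got shape {self.data.shape}")
        if not np.iscomplexobj(self.data):
            self.data = self.data.astype(np.complex128)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("k-space volume contains non-finite entries")
        if self.echo_index < 1:
            raise ValueError("echo_index must be >= 1")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class SamplingMask:
    """Binary sampling pattern on the (ky, kz) phase-encode plane."""

    plane: np.ndarray
    accel_nominal: float
    center_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.plane = np.ascontiguousarray(np.asarray(self.plane, dtype=np.uint8))
        if self.plane.ndim != 2:
            raise ValueError("mask plane must be 2D (ky, kz)")
        if not np.isin(self.plane, (0, 1)).all():
            raise ValueError("mask entries must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.plane.shape

    @property
    def accel_empirical(self) -> float:
        n_sampled = int(self.plane.sum())
        if n_sampled == 0:
            raise ValueError("empty mask has no defined acceleration")
        return self.plane.size / n_sampled

    def broadcast(self, nx: int) -> np.ndarray:
        """Expand lazily to an (nx, ny, nz) float array view."""
        return np.broadcast_to(self.plane[None, :, :], (nx, *self.plane.shape))


# ---------------------------------------------------------------------------
# Fourier operators
# ---------------------------------------------------------------------------


def fft3c(image: np.ndarray) -> np.ndarray:
    """Centered orthonormal 3D FFT (image -> k-space)."""
    image = np.asarray(image)
    if image.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {image.shape}")
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(image), norm="ortho"))


def ifft3c(kspace: np.ndarray) -> np.ndarray:
    """Centered orthonormal 3D inverse FFT (k-space -> image)."""
    kspace = np.asarray(kspace)
    if kspace.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {kspace.shape}")
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(kspace), norm="ortho"))


# ---------------------------------------------------------------------------
# Variable-density Poisson-disc masks
# ---------------------------------------------------------------------------


def _plane_coordinates(ny: int, nz: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized elliptical coordinates: (uy, uz) in [-1, 1] per axis."""
    cy, cz = ny // 2, nz // 2
    uy = (np.arange(ny) - cy) / (ny / 2.0)
    uz = (np.arange(nz) - cz) / (nz / 2.0)
    return np.meshgrid(uy, uz, indexing="ij")


def _center_ellipse(ny: int, nz: int, center_fraction: float) -> np.ndarray:
    """Boolean plane: fully sampled central ellipse of area center_fraction*ny*nz."""
    uy, uz = _plane_coordinates(ny, nz)
    # ellipse with per-axis semi-axes s*(ny/2), s*(nz/2) has area s^2*pi*ny*nz/4
    s2 = 4.0 * center_fraction / np.pi
    return uy**2 + uz**2 <= s2


def _dart_throw(
    ny: int,
    nz: int,
    r0: float,
    alpha: float,
    center: np.ndarray,
    seed: int,
) -> np.ndarray:
    """One dart-throwing pass at base exclusion radius r0.

    A candidate p is accepted when no accepted point q satisfies
    dist(p, q) < min(r(p), r(q)) with r(rho) = r0 * (1 + alpha*rho) and rho the
    normalized elliptical distance of the point from the plane center.
    """
    uy, uz = _plane_coordinates(ny, nz)
    rho = np.sqrt(uy**2 + uz**2)
    radii = r0 * (1.0 + alpha * rho)

    rng = np.random.default_rng(seed)
    order = rng.permutation(ny * nz)

    ys, zs = np.unravel_index(order, (ny, nz))
    acc_y = np.empty(ny * nz, dtype=np.float64)
    acc_z = np.empty(ny * nz, dtype=np.float64)
    acc_r = np.empty(ny * nz, dtype=np.float64)
    n_acc = 0
    mask = center.astype(np.uint8).copy()
    for y, z in zip(ys, zs):
        if center[y, z]:
            continue
        r_p = radii[y, z]
        if n_acc:
            dy = acc_y[:n_acc] - y
            dz = acc_z[:n_acc] - z
            d2 = dy * dy + dz * dz
            rmin = np.minimum(acc_r[:n_acc], r_p)
            if np.any(d2 < rmin * rmin):
                continue
        acc_y[n_acc] = y
        acc_z[n_acc] = z
        acc_r[n_acc] = r_p
        n_acc += 1
        mask[y, z] = 1
    return mask


def generate_vd_poisson_mask(
    ny: int,
    nz: int,
    accel: float,
    center_fraction: float = 0.04,
    seed: int = 0,
    alpha: float = 2.5,
    tol: float = 0.02,
) -> SamplingMask:
    """Variable-density Poisson-disc mask with a fully sampled elliptical center.

    The base exclusion radius is calibrated by bisection until the empirical
    acceleration ny*nz/sum(mask) is within ``tol`` (relative) of ``accel``.
    Deterministic for a fixed seed.
    """
    if accel < 1:
        raise ValueError("acceleration must be >= 1")
    if not 0 < center_fraction <= 1:
        raise ValueError("center_fraction must lie in (0, 1]")
    if center_fraction * accel > 1:
        raise ValueError(
            f"fully sampled center ({center_fraction:.2%}) alone exceeds the "
            f"sampling budget of acceleration {accel}"
        )
    if accel == 1:
        plane = np.ones((ny, nz), dtype=np.uint8)
        return SamplingMask(plane, accel, center_fraction, seed)

    center = _center_ellipse(ny, nz, center_fraction)
    target = ny * nz / accel

    def count(r0: float) -> tuple[int, np.ndarray]:
        m = _dart_throw(ny, nz, r0, alpha, center, seed)
        return int(m.sum()), m

    # bracket: points decrease monotonically (stochastically) with r0
    lo, hi = 1e-3, 2.0 * max(ny, nz)
    n_hi, m_hi = count(hi)
    if n_hi > target:  # even maximal spacing samples too much: cannot reach accel
        raise ValueError(f"cannot reach acceleration {accel} with center_fraction {center_fraction}")
    best = m_hi
    best_err = abs(n_hi - target)
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        n_mid, m_mid = count(mid)
        err = abs(n_mid - target)
        if err < best_err:
            best, best_err = m_mid, err
        if err / target <= tol:
            break
        if n_mid > target:
            lo = mid
        else:
            hi = mid
    return SamplingMask(best, accel, center_fraction, seed)


# ---------------------------------------------------------------------------
# Masking and data consistency
# ---------------------------------------------------------------------------


def _as_array(k) -> np.ndarray:
    return k.data if isinstance(k, KSpaceVolume) else np.asarray(k)


def apply_mask_zero_fill(k, mask: SamplingMask) -> KSpaceVolume:
    """Zero-fill non-acquired k-space points: returns k * D.

    D is the (ky, kz) plane broadcast along kx.  Idempotent.
    """
    data = _as_array(k)
    if data.shape[1:] != mask.shape:
        raise ValueError(f"mask plane {mask.shape} does not match k-space {data.shape}")
    echo = k.echo_index if isinstance(k, KSpaceVolume) else 1
    return KSpaceVolume(data * mask.broadcast(data.shape[0]), echo_index=echo)


def dc_residual(k_it, k_us, mask: SamplingMask, mu: float) -> np.ndarray:
    """Data-consistency residual mu * D o (k_it - k_us); zero off the mask."""
    a = _as_array(k_it)
    b = _as_array(k_us)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.shape[1:] != mask.shape:
        raise ValueError(f"mask plane {mask.shape} does not match k-space {a.shape}")
    return mu * mask.broadcast(a.shape[0]) * (a - b)
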