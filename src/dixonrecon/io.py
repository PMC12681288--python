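"""HDF5 k-space containers, NIfTI volumes, and checkpoint files.

HDF5 layout
-----------
* ``kspace``      (echo, kx, ky, kz) complex64 — fully sampled
* ``kspace_us``   (echo, kx, ky, kz) complex64 — zero-filled undersampled
* ``mask``        (ky, kz) uint8
* ``ff_truth`` / ``labels`` optional ground-truth volumes
* attrs: TE_list (ms), TR, flip_angle, resolution, accel, center_fraction,
  mask seed
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .kspace import AcquisitionSpec, SamplingMask

__all__ = [
    "save_kspace_dataset",
    "load_kspace_dataset",
    "save_nifti",
    "load_nifti",
    "save_checkpoint",
    "load_checkpoint",
]


def save_kspace_dataset(
    path,
    k_full: np.ndarray,
    k_us: np.ndarray,
    mask: SamplingMask,
    te_list,
    acq: AcquisitionSpec | None = None,
    ff_truth=None,
    labels=None,
):
    path = Path(path)
    try:
        with h5py.File(path, "w") as f:
            f.create_dataset("kspace", data=np.asarray(k_full, dtype=np.complex64))
            f.create_dataset("kspace_us", data=np.asarray(k_us, dtype=np.complex64))
            f.create_dataset("mask", data=mask.plane)
            f.attrs["TE_list"] = np.asarray(te_list, dtype=float)
            f.attrs["accel"] = mask.accel_nominal
            f.attrs["center_fraction"] = mask.center_fraction
            f.attrs["mask_seed"] = mask.seed
            if acq is not None:
                f.attrs["TR"] = acq.TR
                f.attrs["flip_angle"] = acq.flip_angle
                f.attrs["resolution"] = np.asarray(acq.resolution, dtype=float)
            if ff_truth is not None:
                f.create_dataset("ff_truth", data=np.asarray(ff_truth.values, dtype=np.float32))
                f.create_dataset("ff_foreground", data=ff_truth.foreground.astype(np.uint8))
            if labels is not None:
                f.create_dataset("labels", data=np.asarray(labels, dtype=np.int16))
    except OSError as exc:
        raise OSError(f"failed to write k-space dataset at {path}: {exc}") from exc
    return path


def load_kspace_dataset(path) -> dict:
    path = Path(path)
    try:
        with h5py.File(path, "r") as f:
            out = {
                "kspace": f["kspace"][...],
                "kspace_us": f["kspace_us"][...],
                "mask": SamplingMask(
                    f["mask"][...],
                    float(f.attrs.get("accel", 1.0)),
                    float(f.attrs.get("center_fraction", 1.0)),
                    int(f.attrs.get("mask_seed", 0)),
                ),
                "TE_list": tuple(float(t) for t in f.attrs["TE_list"]),
            }
            for key in ("ff_truth", "ff_foreground", "labels"):
                if key in f:
                    out[key] = f[key][...]
    except OSError as exc:
        raise OSError(f"failed to read k-space dataset at {path}: {exc}") from exc
    return out


def save_nifti(path, volume: np.ndarray, dtype=np.float32) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume).astype(dtype), affine=np.eye(4))
    nib.save(img, str(path))
    return path


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj)


def save_checkpoint(path, state: dict[str, np.ndarray], config: dict, extra: dict | None = None,
                    optimizer_state: dict[str, np.ndarray] | None = None) -> Path:
    """Single-file checkpoint: parameters, config echo, optimizer state."""
    path = Path(path)
    payload = {f"param/{k}": v for k, v in state.items()}
    if optimizer_state:
        payload.update({f"opt/{k}": v for k, v in optimizer_state.items()})
    payload["config_json"] = np.bytes_(json.dumps(config))
    payload["extra_json"] = np.bytes_(json.dumps(extra or {}))
    np.savez(path, **payload)
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as z:
        config = json.loads(bytes(z["config_json"]).decode())
        extra = json.loads(bytes(z["extra_json"]).decode())
        state = {k[6:]: z[k] for k in z.files if k.startswith("param/")}
        opt = {k[4:]: z[k] for k in z.files if k.startswith("opt/")}
    return state, config, extra, opt
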