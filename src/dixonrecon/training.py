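"""Training loop, loss, model selection, and test-set evaluation.

Training follows the published recipe scaled to desk size: Adam with
learning rate 1e-3, image-domain MSE loss between the inverse Fourier
transform of the predicted k-space and the fully sampled reference image,
and model selection by lowest validation loss.  Each echo of an acquisition
is an independent training sample, but all echoes of one acquisition stay
in the same split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .dixon import EchoStack, FFMap, ROILabelMap, background_mask, roi_mean_ff, three_point_dixon
from .kspace import SamplingMask, fft3c, ifft3c
from .metrics import (
    bland_altman,
    ff_abs_difference,
    ff_quadratic_error,
    mean_stderr,
    mse_metric,
    psnr_metric,
    ssim_metric,
)
from .networks import NetworkConfig, UnrolledNetwork
from .networks import autograd as ag
from .networks.layers import DTYPE

__all__ = [
    "TrainConfig",
    "Sample",
    "image_domain_mse_loss",
    "train_unrolled",
    "select_best_checkpoint",
    "evaluate_reconstruction",
    "Adam",
]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 4
    max_epochs: int = 500
    seed: int = 0
    accel: float = 4.0
    log_every: int = 1


@dataclass
class Sample:
    """One training unit: a single echo's k-space and its mask."""

    k_us: np.ndarray  # complex (Nx, Ny, Nz), zero-filled
    k_full: np.ndarray  # complex (Nx, Ny, Nz)
    mask: SamplingMask
    volume_id: int = 0
    echo_index: int = 1

    @property
    def target_image(self) -> np.ndarray:
        return np.stack(
            [ifft3c(self.k_full).real, ifft3c(self.k_full).imag]
        ).astype(DTYPE)


def samples_from_dataset(data: dict, volume_id: int = 0, echoes=None) -> list[Sample]:
    """Split one multi-echo acquisition echo by echo."""
    n = data["kspace"].shape[0]
    idx = range(n) if echoes is None else echoes
    return [
        Sample(data["kspace_us"][e], data["kspace"][e], data["mask"], volume_id, e + 1)
        for e in idx
    ]


def image_domain_mse_loss(pred_k: ag.Tensor, ref_image: np.ndarray) -> ag.Tensor:
    """MSE between ifft(pred_k) and the reference image, both two-channel."""
    ref = np.asarray(ref_image)
    if np.iscomplexobj(ref):
        ref = np.stack([ref.real, ref.imag])
    img = ag.ifft2ch(pred_k)
    if img.shape != ref.shape:
        raise ValueError(f"shape mismatch: {img.shape} vs {ref.shape}")
    return ag.mse(img, ag.Tensor(ref.astype(img.data.dtype)))


class Adam:
    """Standard Adam over a parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"m{i}"] = m
            out[f"v{i}"] = v
        return out


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_loss: float
    state: dict[str, np.ndarray]


def _epoch_pass(net, samples, optimizer, rng, batch_size):
    """One training epoch; returns the mean per-sample loss."""
    order = rng.permutation(len(samples))
    losses = []
    i = 0
    while i < len(order):
        batch = order[i : i + batch_size]
        optimizer.zero_grad()
        for j in batch:
            s = samples[j]
            _, pred_k = net.forward(s.k_us, s.mask, return_kspace=True)
            loss = image_domain_mse_loss(pred_k, s.target_image)
            loss.backward(np.asarray(1.0 / len(batch), dtype=DTYPE))
            losses.append(float(loss.data))
        optimizer.step()
        i += batch_size
    return float(np.mean(losses))


def _validation_loss(net, samples) -> float:
    net.eval()
    losses = []
    for s in samples:
        _, pred_k = net.forward(s.k_us, s.mask, return_kspace=True)
        losses.append(float(image_domain_mse_loss(pred_k, s.target_image).data))
    net.train()
    return float(np.mean(losses))


def train_unrolled(
    net_config: NetworkConfig,
    train_config: TrainConfig,
    train_set: list[Sample],
    val_set: list[Sample],
    callback=None,
) -> tuple[UnrolledNetwork, list[EpochRecord]]:
    """Train an unrolled network; returns the net and per-epoch history."""
    if not train_set:
        raise ValueError("empty training set")
    net = UnrolledNetwork(net_config, seed=train_config.seed)
    net.train()
    optimizer = Adam(net.parameters(), lr=train_config.lr)
    rng = np.random.default_rng(train_config.seed)
    history: list[EpochRecord] = []
    for epoch in range(1, train_config.max_epochs + 1):
        train_loss = _epoch_pass(net, train_set, optimizer, rng, train_config.batch_size)
        if not np.isfinite(train_loss):
            raise FloatingPointError(
                f"training diverged at epoch {epoch} (loss {train_loss}); "
                "lower the learning rate or check input scaling"
            )
        val_loss = _validation_loss(net, val_set) if val_set else train_loss
        history.append(EpochRecord(epoch, train_loss, val_loss, net.state_dict()))
        if callback is not None:
            callback(history[-1])
    net.last_optimizer_state = optimizer.state_dict()  # persisted with checkpoints
    return net, history


def select_best_checkpoint(history: list[EpochRecord]) -> EpochRecord:
    """Lowest validation loss; ties resolve to the earliest epoch."""
    if not history:
        raise ValueError("empty history")
    best = history[0]
    for rec in history[1:]:
        if rec.val_loss < best.val_loss:
            best = rec
    return best


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


def _ff_from_echoes(echoes: np.ndarray, te_list, foreground) -> FFMap:
    return three_point_dixon(EchoStack(echoes, tuple(te_list)), foreground=foreground).masked()


def reconstruct_volume(net: UnrolledNetwork | None, data: dict, echoes=None) -> np.ndarray:
    """Reconstruct each echo of an acquisition (zero-filled when net is None)."""
    n = data["kspace"].shape[0]
    idx = list(range(n) if echoes is None else echoes)
    out = np.empty((len(idx), *data["kspace"].shape[1:]), dtype=np.complex128)
    for j, e in enumerate(idx):
        if net is None:
            out[j] = ifft3c(data["kspace_us"][e])
        else:
            out[j] = net.reconstruct(data["kspace_us"][e], data["mask"])
    return out


def evaluate_reconstruction(
    net: UnrolledNetwork | None,
    test_set: list[dict],
    rois: list[ROILabelMap] | None = None,
) -> dict:
    """Per-volume FF-map metrics against the fully sampled reference.

    Reconstructs the first three echoes of every test acquisition, computes
    reference and reconstructed FF maps (background removed), and reports
    MSE/SSIM/PSNR plus per-muscle FF errors and a Bland-Altman summary,
    aggregated as mean +- standard error.
    """
    per_volume = {"mse": [], "ssim": [], "psnr": []}
    ref_muscle_ff, rec_muscle_ff = [], []
    quad_errors, abs_diffs = [], []
    for vi, data in enumerate(test_set):
        if data["kspace"].shape[0] < 3:
            raise ValueError("test volumes need at least three echoes")
        te3 = data["TE_list"][:3]
        ref_echoes = np.stack([ifft3c(k) for k in data["kspace"][:3]])
        rec_echoes = reconstruct_volume(net, data, echoes=range(3))
        fg = background_mask(np.abs(ref_echoes[0]))
        ff_ref = _ff_from_echoes(ref_echoes, te3, fg)
        ff_rec = _ff_from_echoes(rec_echoes, te3, fg)
        per_volume["mse"].append(mse_metric(ff_ref, ff_rec))
        per_volume["ssim"].append(ssim_metric(ff_ref, ff_rec))
        per_volume["psnr"].append(psnr_metric(ff_ref, ff_rec))
        if rois is not None:
            roi_map = rois[vi]
            for label in np.unique(roi_map.labels):
                if label == 0:
                    continue
                fr = roi_mean_ff(ff_ref, roi_map, int(label))
                fc = roi_mean_ff(ff_rec, roi_map, int(label))
                ref_muscle_ff.append(fr)
                rec_muscle_ff.append(fc)
                if fr > 0:
                    quad_errors.append(ff_quadratic_error(fr, fc))
                abs_diffs.append(ff_abs_difference(fr, fc))
    report = {
        "per_volume": per_volume,
        "mse": mean_stderr(per_volume["mse"]),
        "ssim": mean_stderr(per_volume["ssim"]),
        "psnr": mean_stderr([p for p in per_volume["psnr"] if np.isfinite(p)] or [np.inf]),
    }
    if rois is not None:
        report["ff_quadratic_error"] = mean_stderr(quad_errors)
        report["ff_abs_difference"] = mean_stderr(abs_diffs)
        if len(ref_muscle_ff) >= 2:
            report["bland_altman"] = bland_altman(ref_muscle_ff, rec_muscle_ff)
    return report
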