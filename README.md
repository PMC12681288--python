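# dixonrecon

Memory-efficient unrolled neural networks for the reconstruction of
undersampled 3D Dixon MRI, with three-point fat-fraction (FF)
quantification and a full evaluation pipeline.  Four cascade architectures
are implemented — VarNet, HalfVarNet, DIRCN, and HalfDIRCN — where each
cascade applies a data-consistency update and a learned regularizer
(a 3D U-Net or a 3D Half U-Net) to the current k-space iterate:

```
k[it+1] = k[it] - mu[it] * D (k[it] - k_us) + F R_it(F^H k[it])
```

The dense variants (DIRCN/HalfDIRCN) additionally feed the channel
concatenation of all previous image iterates into each regularizer and
interconnect same-resolution decoder features of consecutive cascades.

Everything runs on plain numpy: the networks are built on a small
reverse-mode autodiff engine (`dixonrecon.networks.autograd`) whose every
operation is validated against central finite differences, so training and
inference need no GPU and no deep-learning framework.  A synthetic thigh
phantom generator (water/fat compartments, ten-muscle geometry, B0
off-resonance, eight-echo GRE simulation) makes the whole pipeline testable
without any external data.

## Layout

| module | contents |
| --- | --- |
| `dixonrecon.kspace` | centered orthonormal FFTs, variable-density Poisson-disc masks, zero-filling, data-consistency residual |
| `dixonrecon.networks` | autodiff engine, 3D U-Net / Half U-Net, the four unrolled cascade models |
| `dixonrecon.complexity` | analytic parameter / forward-FLOP / checkpoint-size accounting |
| `dixonrecon.dixon` | three-point Dixon FF maps, background masking, per-muscle FF |
| `dixonrecon.metrics` | MSE/SSIM/PSNR on FF maps, FF errors, Dice/sensitivity/specificity, Bland-Altman |
| `dixonrecon.phantom` | synthetic thigh Dixon phantoms and acquisition simulation |
| `dixonrecon.training` | Adam training loop, image-domain MSE loss, model selection, evaluation |
| `dixonrecon.io` | HDF5 k-space containers, NIfTI volumes, checkpoints |

## CLI

```sh
dixonrecon mask --ny 128 --nz 36 --accel 4 --center-frac 0.04 --seed 0 --out mask.npy
dixonrecon audit                      # complexity table for the six studied models
dixonrecon simulate --spec spec.yaml --accel 4 --seed 0 --out data.h5
dixonrecon ff --echoes data.h5 --out ff.nii.gz --rois labels.nii.gz --report ff.tsv
dixonrecon train --net net.yaml --train train.yaml --data datadir/ --out runs/
dixonrecon reconstruct --ckpt runs/best.ckpt.npz --in data.h5 --out recon.h5
dixonrecon evaluate --ckpt runs/best.ckpt.npz --data testdir/ --report report.tsv
```

`net.yaml` holds a `NetworkConfig` (variant, cascades, base_channels,
stages, dropout, upsampling); `train.yaml` a `TrainConfig` (lr, batch_size,
max_epochs, seed).

## Conventions

* FFTs are centered and orthonormal; undersampling lives on the (ky, kz)
  phase-encode plane and is broadcast along the readout.
* FF maps are in percent, clamped to [0, 100]; metrics use peak 100 and
  foreground (background-removed) voxels only.
* FLOPs: 2 per multiply-accumulate on the pool-padded grid, transpose
  convolutions counted over their output grid, pointwise operations at a
  few FLOPs per element, Fourier/data-consistency excluded.
* Checkpoint size: 4-byte weights plus two 4-byte Adam moment buffers.
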