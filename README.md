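# lambda-bscan

Speckle-reduced swept-source OCT B-scan reconstruction **directly from
wavelength-domain interference fringes**, for OCT researchers and
engineers who want to skip the classical calibration/k-resampling step —
plus everything needed to study the approach at desk scale: a
physics-based interferogram simulator, the classical k-linearization
baseline, and the full loss/metric suite.

## The problem

Fourier-domain OCT encodes depth in spectral fringes
`I_D(k) ∝ S(k) Σ_i √(r_r r_Si) cos(k (d_r − d_Si))`.  The inverse DFT
recovers the depth profile only if the spectrum is sampled uniformly in
wavenumber `k = 2π/λ`; real swept lasers sample uniformly in wavelength
(or sinusoidally in time, for FDML sources), which blurs the
reconstruction increasingly with depth.  Classically this is fixed by
resampling each spectrum onto a uniform k grid.  Coherent detection also
imposes speckle, classically reduced by averaging consecutive B-scans.

This package instead learns the reconstruction with two sequential
attention-gated residual encoder–decoder networks:

* **SD-CNN** (2D): maps the blurred image obtained by direct inverse-DFT
  of the non-linear spectrum — with a wavenumber layer `k(s) =
  2π/(λ_min + s(λ_max−λ_min)/(N−1))` stacked as a second channel — to a
  speckle-reduced image, minimizing L1 against 7-scan-averaged ground
  truth.
* **FD-CNN** (1D, per A-scan): refines the DFT amplitude of the SD
  output with the focal frequency loss
  `FFL = mean(w·|F_k − F_λ|²), w = |F_k − F_λ|^α, α = 1`, then the
  refined amplitude is recombined with the SD phase and inverse-DFT'd.

Evaluation uses MSE, PSNR, SSIM, `CNR_i = 10·log10(|μ_i−μ_b|/√(σ_i²+σ_b²))`
and the structural-correlation score `β_s` (normalized correlation of
mean-subtracted images).

## Worked example

Train the desk-scale configuration (200 simulated 64×64 B-scan pairs,
tiny networks, a few minutes on one CPU core) and evaluate on the held-out
test split:

```python
from lambda_bscan.octsim import generate_dataset
from lambda_bscan.pipeline import train_sd_cnn, train_fd_cnn, infer, evaluate
from lambda_bscan.presets import (desk_dataset_config, desk_train_config,
                                  DESK_NET_2D, DESK_NET_1D)

ds = generate_dataset(desk_dataset_config(seed=1))
cfg = desk_train_config(seed=1)
sd, hist, stats, kgrid = train_sd_cnn(ds, cfg, DESK_NET_2D)
fd, _, amp_scale = train_fd_cnn(sd, ds, cfg, DESK_NET_1D, stats=stats)

test = ds.split("test")
gts = [it.ground_truth.pixels for it in test]
finals = [infer(it.raw, sd, fd, stats, amp_scale=amp_scale).pixels
          for it in test]
print(evaluate(finals, gts).tail(1))        # overall row
print(evaluate([it.degraded.pixels for it in test], gts).tail(1))
```

At seed 1 this prints an overall PSNR of **25.1 dB** for the
reconstruction versus **18.3 dB** for the degraded input (a +6.8 dB
gain), with β_s ≈ 0.95 against the ground truth compared to ≈ 0.78 for a
single classically resampled frame — i.e. the learned reconstruction is
both sharper than the blurred input and markedly less speckled than the
classical single-frame output.

A `lambda-bscan` CLI wraps the same steps
(`simulate | preprocess | baseline | train-sd | train-fd | infer |
evaluate | ablate`), each taking `--config cfg.yaml --seed INT --out DIR`.

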