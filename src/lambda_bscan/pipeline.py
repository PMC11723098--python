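"""Sequential training and end-to-end inference.

Training is two-stage: the spatial-domain network (SD-CNN) is trained
first with an L1 loss against speckle-reduced ground truth; the
Fourier-domain network (FD-CNN) is then trained with the SD-CNN frozen,
consuming per-A-scan DFT amplitudes of SD outputs and minimizing the
focal frequency loss against DFT amplitudes of the ground truth.

Inference chains: preprocess -> attach wavenumber layer -> patchify ->
SD-CNN -> unpatchify -> per-A-scan DFT -> FD-CNN on amplitude -> recombine
with the SD output's phase -> inverse DFT -> magnitude.

Standardization statistics are computed once over the training split
(degraded and ground-truth images pooled) and stored with the weights;
inference reuses them.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Adam, Tensor
from .losses_metrics import RegionSet, beta_s, cnr, mse, psnr, ssim
from .networks import (EncoderDecoder, NetConfig, SpectrumPair, build_fd_cnn,
                       build_sd_cnn, model_state, set_model_state)
from .octsim import PairedDataset, RawFringeFrame
from .preprocess import (BScanImage, StandardizationStats, apply_hann,
                         attach_k_layer, compute_k_grid, destandardize,
                         fringes_to_image, patchify, standardize,
                         subtract_background, unpatchify)

__all__ = ["TrainConfig", "compute_stats", "train_sd_cnn", "train_fd_cnn",
           "infer", "evaluate", "run_ablation", "sd_forward_image"]


@dataclass
class TrainConfig:
    """Optimization settings.  Defaults follow the full-scale recipe
    (Adam, learning rate 1e-4, 200 epochs for the SD-CNN and 400 for the
    FD-CNN, 70/20/10 split, 7-scan-averaged ground truth); smoke-scale
    runs override the epoch counts."""

    optimizer: str = "adam"
    lr: float = 1e-4
    epochs_sd: int = 200
    epochs_fd: int = 400
    batch_size: int = 8           # SD patches per step
    batch_size_fd: int = 64       # FD A-scan columns per step
    seed: int = 0
    split: Tuple[int, int, int] = (70, 20, 10)
    n_avg_gt: int = 7
    n_patches: int = 4

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")
        if not self.lr > 0:
            raise ValueError("lr must be positive")
        if self.epochs_sd < 1 or self.epochs_fd < 1:
            raise ValueError("epoch counts must be >= 1")
        if sum(self.split) != 100:
            raise ValueError("split percentages must sum to 100")


def compute_stats(dataset: PairedDataset) -> StandardizationStats:
    """Pooled mean/std of the training split (degraded + ground truth)."""
    vals = np.concatenate([
        np.concatenate([it.degraded.pixels.ravel(),
                        it.ground_truth.pixels.ravel()])
        for it in dataset.split("train")])
    std = float(vals.std())
    if std == 0:
        raise ValueError("training split is constant; cannot standardize")
    return StandardizationStats(mean=float(vals.mean()), std=std)


def _dataset_kgrid(dataset: PairedDataset):
    it = dataset.items[0]
    rows = it.degraded.pixels.shape[0]
    sweep = it.raw.sweep
    return compute_k_grid(sweep.lambda_min, sweep.lambda_max, rows)


def _sd_pairs(dataset: PairedDataset, split: str,
              stats: StandardizationStats, kgrid, n_patches: int):
    """(input, target) patch pairs as channels-first arrays."""
    xs, ys = [], []
    for it in dataset.split(split):
        tensor = attach_k_layer(it.degraded, kgrid)
        tensor[:, :, 0] = standardize(tensor[:, :, 0], stats)
        target = standardize(it.ground_truth.pixels, stats)
        for xp, yp in zip(patchify(tensor, n_patches),
                          patchify(target[:, :, None], n_patches)):
            xs.append(xp.transpose(2, 0, 1))
            ys.append(yp.transpose(2, 0, 1))
    return np.stack(xs), np.stack(ys)


def _run_epoch(model, opt, loss_fn, x, y, batch_size, rng=None):
    """One pass over (x, y); returns the mean loss.  With ``rng`` the order
    is shuffled and gradients are applied (training); without, it is a
    plain evaluation pass."""
    n = len(x)
    order = rng.permutation(n) if rng is not None else np.arange(n)
    total = 0.0
    for lo in range(0, n, batch_size):
        idx = order[lo:lo + batch_size]
        out = model(Tensor(x[idx]))
        loss = loss_fn(out, Tensor(y[idx]))
        if not np.isfinite(loss.data):
            raise RuntimeError("training diverged (non-finite loss)")
        if rng is not None:
            opt.zero_grad()
            loss.backward()
            opt.step()
        total += float(loss.data) * len(idx)
    return total / n


def _fit(model, x_tr, y_tr, x_val, y_val, loss_fn, cfg: TrainConfig,
         epochs: int, batch_size: int):
    """history["val"][0] is the untrained model's validation loss, so the
    recorded learning curve starts at initialization."""
    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    has_val = len(x_val) > 0
    model.eval()
    val0 = (_run_epoch(model, opt, loss_fn, x_val, y_val, batch_size)
            if has_val
            else _run_epoch(model, opt, loss_fn, x_tr, y_tr, batch_size))
    history = {"train": [], "val": [val0]}
    best_val, best_state = np.inf, None
    for _ in range(epochs):
        model.train()
        tr = _run_epoch(model, opt, loss_fn, x_tr, y_tr, batch_size, rng)
        model.eval()
        val = (_run_epoch(model, opt, loss_fn, x_val, y_val, batch_size)
               if has_val else tr)
        history["train"].append(tr)
        history["val"].append(val)
        if val < best_val:
            best_val, best_state = val, model_state(model)
    if best_state is not None:
        set_model_state(model, best_state)
    model.eval()
    return history


def train_sd_cnn(dataset: PairedDataset, cfg: TrainConfig,
                 net_cfg: Optional[NetConfig] = None):
    """Train the spatial-domain network; returns
    (model, history, stats, kgrid)."""
    stats = compute_stats(dataset)
    kgrid = _dataset_kgrid(dataset)
    x_tr, y_tr = _sd_pairs(dataset, "train", stats, kgrid, cfg.n_patches)
    x_val, y_val = ((np.empty((0,) + x_tr.shape[1:]),) * 2
                    if not dataset.split("val")
                    else _sd_pairs(dataset, "val", stats, kgrid, cfg.n_patches))
    model = build_sd_cnn(net_cfg, seed=cfg.seed)
    history = _fit(model, x_tr, y_tr, x_val, y_val, ad.mean_abs, cfg,
                   cfg.epochs_sd, cfg.batch_size)
    return model, history, stats, kgrid


def sd_forward_image(sd_model, degraded: BScanImage,
                     stats: StandardizationStats, kgrid,
                     n_patches: int = 4) -> BScanImage:
    """Run the SD-CNN on one degraded B-scan; returns the magnitude image."""
    tensor = attach_k_layer(degraded, kgrid)
    tensor[:, :, 0] = standardize(tensor[:, :, 0], stats)
    batch = np.stack([p.transpose(2, 0, 1)
                      for p in patchify(tensor, n_patches)])
    out = sd_model.predict(batch)                       # (P, 1, h, w)
    full = unpatchify([o.transpose(1, 2, 0) for o in out])[:, :, 0]
    pixels = np.abs(destandardize(full, stats))
    return BScanImage(pixels=pixels, depth_pitch=degraded.depth_pitch,
                      provenance="sd_output")


def _amp_pairs(dataset: PairedDataset, split: str, sd_model, stats, kgrid,
               n_patches: int, fd_input: str = "sd"):
    """Per-A-scan DFT amplitude (input, target) column batches.

    ``fd_input`` selects what feeds the FD-CNN: "sd" (SD-CNN outputs, the
    sequential recipe) or "degraded" (raw degraded images, the FD-only
    ablation arm).
    """
    xs, ys = [], []
    for it in dataset.split(split):
        if fd_input == "sd":
            src = sd_forward_image(sd_model, it.degraded, stats, kgrid,
                                   n_patches).pixels
        else:
            src = it.degraded.pixels
        amp_in = SpectrumPair.from_image(src).amplitude
        amp_gt = SpectrumPair.from_image(it.ground_truth.pixels).amplitude
        xs.append(amp_in.T[:, None, :])                 # (cols, 1, rows)
        ys.append(amp_gt.T[:, None, :])
    return np.concatenate(xs), np.concatenate(ys)


def _state_digest(model) -> str:
    h = hashlib.sha256()
    for key, arr in sorted(model_state(model).items()):
        h.update(key.encode())
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()


def _fuse_columns(fd_model, amp: np.ndarray, phase: np.ndarray,
                  amp_scale: float) -> np.ndarray:
    """FD-CNN on the amplitude columns of one image, recombined with the
    given phase; returns the magnitude image."""
    batch = amp.T[:, None, :] / amp_scale
    refined = fd_model.predict(batch)[:, 0, :].T * amp_scale
    return np.abs(np.fft.ifft(refined * np.exp(1j * phase), axis=0))


def train_fd_cnn(sd_model, dataset: PairedDataset, cfg: TrainConfig,
                 net_cfg: Optional[NetConfig] = None,
                 stats: Optional[StandardizationStats] = None,
                 fd_input: str = "sd"):
    """Train the Fourier-domain network with the SD-CNN frozen.

    The focal frequency loss on amplitudes drives the optimization; the
    returned checkpoint is the epoch whose amplitude/phase-fused output
    scores the best mean PSNR on the validation split (the task metric).
    The identity initialization is the epoch-0 candidate, so the selected
    refinement never degrades the validation reconstruction.

    Returns (model, history, amp_scale); ``history`` carries per-epoch
    training/validation FFL plus the fused validation PSNR curve.
    ``amp_scale`` is the mean ground-truth amplitude of the training
    split; amplitudes are divided by it inside the network so the
    optimization runs at unit scale.  Raises if the frozen SD weights are
    mutated.
    """
    stats = stats or compute_stats(dataset)
    kgrid = _dataset_kgrid(dataset)
    digest_before = _state_digest(sd_model) if fd_input == "sd" else None
    x_tr, y_tr = _amp_pairs(dataset, "train", sd_model, stats, kgrid,
                            cfg.n_patches, fd_input)
    val_items = dataset.split("val")
    x_val, y_val = ((np.empty((0,) + x_tr.shape[1:]),) * 2 if not val_items
                    else _amp_pairs(dataset, "val", sd_model, stats, kgrid,
                                    cfg.n_patches, fd_input))
    amp_scale = float(np.mean(y_tr))
    if amp_scale <= 0:
        raise ValueError("degenerate (all-zero) ground-truth amplitudes")

    # fixed fusion context for the per-epoch validation PSNR
    val_spectra, val_gts = [], []
    for it in val_items:
        src = (sd_forward_image(sd_model, it.degraded, stats, kgrid,
                                cfg.n_patches).pixels
               if fd_input == "sd" else it.degraded.pixels)
        sp = SpectrumPair.from_image(src)
        val_spectra.append(sp)
        val_gts.append(it.ground_truth.pixels)
    max_val = max((g.max() for g in val_gts), default=1.0)

    model = build_fd_cnn(net_cfg, seed=cfg.seed + 1)

    def fused_val_psnr():
        if not val_spectra:
            return np.nan
        return float(np.mean([
            psnr(_fuse_columns(model, sp.amplitude, sp.phase, amp_scale),
                 gt, max_val)
            for sp, gt in zip(val_spectra, val_gts)]))

    opt = Adam(model.parameters(), lr=cfg.lr)
    rng = np.random.default_rng(cfg.seed)
    xs, ys = x_tr / amp_scale, y_tr / amp_scale
    xv, yv = x_val / amp_scale, y_val / amp_scale
    model.eval()
    history = {"train": [], "val": [], "val_psnr": []}
    history["val"].append(_run_epoch(model, opt, ad.mean_abs_cubed,
                                     *( (xv, yv) if len(xv) else (xs, ys) ),
                                     cfg.batch_size_fd))
    history["val_psnr"].append(fused_val_psnr())
    best_psnr, best_state = history["val_psnr"][0], model_state(model)
    for _ in range(cfg.epochs_fd):
        model.train()
        tr = _run_epoch(model, opt, ad.mean_abs_cubed, xs, ys,
                        cfg.batch_size_fd, rng)
        model.eval()
        val = (_run_epoch(model, opt, ad.mean_abs_cubed, xv, yv,
                          cfg.batch_size_fd) if len(xv) else tr)
        vp = fused_val_psnr()
        history["train"].append(tr)
        history["val"].append(val)
        history["val_psnr"].append(vp)
        if val_items:
            if vp > best_psnr:
                best_psnr, best_state = vp, model_state(model)
        else:
            best_state = model_state(model)  # no val split: keep last
    set_model_state(model, best_state)
    model.eval()
    if digest_before is not None and _state_digest(sd_model) != digest_before:
        raise RuntimeError("frozen SD-CNN weights were mutated "
                           "during FD training")
    return model, history, amp_scale


def _check_finite(arr, stage: str):
    if not np.all(np.isfinite(arr)):
        raise RuntimeError(f"non-finite values after stage {stage!r}")


def infer(frame: RawFringeFrame, sd_model, fd_model,
          stats: StandardizationStats, *, amp_scale: float = 1.0,
          n_patches: int = 4, hann: bool = True,
          background: Optional[str] = None,
          return_sd: bool = False):
    """End-to-end reconstruction of one raw wavelength-domain frame.

    ``fd_model=None`` makes the Fourier stage the identity on amplitude,
    in which case the output equals the SD output exactly.
    """
    if background is not None:
        frame = subtract_background(frame, background)
    if hann:
        frame = apply_hann(frame)
    degraded = fringes_to_image(frame)
    _check_finite(degraded.pixels, "fringes_to_image")
    rows = degraded.pixels.shape[0]
    kgrid = compute_k_grid(frame.sweep.lambda_min, frame.sweep.lambda_max,
                           rows)
    sd_img = sd_forward_image(sd_model, degraded, stats, kgrid, n_patches)
    _check_finite(sd_img.pixels, "sd_cnn")
    sp = SpectrumPair.from_image(sd_img.pixels)
    if fd_model is None:
        amp = sp.amplitude
    else:
        batch = sp.amplitude.T[:, None, :] / amp_scale   # (cols, 1, rows)
        amp = fd_model.predict(batch)[:, 0, :].T * amp_scale
        _check_finite(amp, "fd_cnn")
    fused = SpectrumPair(amplitude=amp, phase=sp.phase)
    final = np.abs(np.fft.ifft(fused.amplitude * np.exp(1j * fused.phase),
                               axis=0))
    _check_finite(final, "idft_fusion")
    out = BScanImage(pixels=final, depth_pitch=degraded.depth_pitch,
                     provenance="final_output")
    return (out, sd_img) if return_sd else out


def _pixels(obj) -> np.ndarray:
    return obj.pixels if isinstance(obj, BScanImage) else np.asarray(obj, float)


def evaluate(outputs, ground_truths, regions: Optional[RegionSet] = None
             ) -> pd.DataFrame:
    """Per-image and overall metric table (PSNR, SSIM, MSE, beta_s; CNR per
    foreground region when ROIs are given).

    Inputs are parallel dicts (matched by key) or sequences (matched by
    position) of B-scans.  PSNR/SSIM use the ground-truth maximum over the
    evaluation set as the dynamic range.
    """
    if isinstance(outputs, dict):
        ids = sorted(outputs)
        missing = [i for i in ids if i not in ground_truths]
        if missing:
            raise ValueError(f"missing ground truth for ids {missing}")
        pairs = [(i, _pixels(outputs[i]), _pixels(ground_truths[i]))
                 for i in ids]
    else:
        if len(outputs) != len(ground_truths):
            raise ValueError("missing ground truth: length mismatch")
        pairs = [(i, _pixels(o), _pixels(g))
                 for i, (o, g) in enumerate(zip(outputs, ground_truths))]
    max_val = max(g.max() for _, _, g in pairs)
    rows = []
    for i, out, gt in pairs:
        row = {"image_id": i, "mse": mse(out, gt),
               "psnr": psnr(out, gt, max_val),
               "ssim": ssim(out, gt, data_range=max_val),
               "beta_s": beta_s(out, gt)}
        if regions is not None:
            for r, val in enumerate(cnr(out, regions)):
                row[f"cnr_{r}"] = val
        rows.append(row)
    overall = {"image_id": "overall"}
    for key in rows[0]:
        if key != "image_id":
            overall[key] = float(np.mean([r[key] for r in rows]))
    return pd.DataFrame(rows + [overall])


def run_ablation(dataset: PairedDataset, cfg: TrainConfig,
                 net_cfg_sd: Optional[NetConfig] = None,
                 net_cfg_fd: Optional[NetConfig] = None) -> pd.DataFrame:
    """Train and evaluate {SD only, FD only, SD+FD} on the same splits and
    seeds; returns mean/std PSNR and SSIM per configuration on the test
    split.  The FD-only arm consumes DFT amplitudes of the degraded input
    directly (and reuses the degraded input's phase at inference)."""
    sd_model, _, stats, kgrid = train_sd_cnn(dataset, cfg, net_cfg_sd)
    fd_model, _, amp_scale = train_fd_cnn(sd_model, dataset, cfg, net_cfg_fd,
                                          stats=stats)
    fdo_model, _, fdo_scale = train_fd_cnn(sd_model, dataset, cfg, net_cfg_fd,
                                           stats=stats, fd_input="degraded")
    test = dataset.split("test")
    gts = [it.ground_truth for it in test]

    def fd_only_image(it):
        sp = SpectrumPair.from_image(it.degraded.pixels)
        batch = sp.amplitude.T[:, None, :] / fdo_scale
        amp = fdo_model.predict(batch)[:, 0, :].T * fdo_scale
        return np.abs(np.fft.ifft(amp * np.exp(1j * sp.phase), axis=0))

    arms = {
        "sd_only": [sd_forward_image(sd_model, it.degraded, stats, kgrid,
                                     cfg.n_patches) for it in test],
        "fd_only": [fd_only_image(it) for it in test],
        "sd_fd": [infer(it.raw, sd_model, fd_model, stats,
                        amp_scale=amp_scale, n_patches=cfg.n_patches,
                        hann=bool(dataset.config.get("hann", True)),
                        background=("mean-a-scan" if dataset.config.get(
                            "background", "none") == "mean_ascan" else None))
                  for it in test],
    }
    rows = []
    for name, outs in arms.items():
        table = evaluate(outs, gts)
        per_image = table[table.image_id != "overall"]
        rows.append({
            "configuration": name,
            "psnr_avg": float(per_image.psnr.mean()),
            "psnr_std": float(per_image.psnr.std(ddof=0)),
            "ssim_avg": float(per_image.ssim.mean()),
            "ssim_std": float(per_image.ssim.std(ddof=0)),
        })
    return pd.DataFrame(rows)
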