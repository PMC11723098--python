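"""Desk-scale study presets.

The desk-scale configuration is the package's standard demonstration
setting: 200 simulated B-scans of 128 spectral samples x 64 A-scans
(64 x 64 images after mirror-half removal), wavelength-linear sweeps over
1260-1360 nm, fully developed speckle from ~2 scatterers per depth pixel,
mild additive noise, 7-scan-averaged ground truth, 70/20/10 split, and
tiny-preset networks trained for 12 (SD) / 8 (FD) epochs at learning rate
1e-3.  It is sized so the full two-stage training runs in minutes on one
CPU core while preserving every qualitative feature of the full-scale
recipe (whose defaults live in :class:`~lambda_bscan.pipeline.TrainConfig`).
"""

from __future__ import annotations

from .networks import NetConfig
from .pipeline import TrainConfig

__all__ = ["desk_dataset_config", "desk_holdout_config",
           "desk_train_config", "DESK_NET_2D", "DESK_NET_1D"]

DESK_NET_2D = NetConfig.preset("tiny")
DESK_NET_1D = NetConfig.preset("tiny", conv_dim="1D", in_channels=1,
                               out_channels=1,
                               output_activation="residual_relu")


def desk_dataset_config(seed: int = 1) -> dict:
    return {
        "sweep_kind": "lambda_linear",
        "n_samples": 128,
        "a_scans": 64,
        "n_items": 200,
        "density": 2.0,
        "noise_sigma": 0.02,
        "n_avg": 7,
        "split": (70, 20, 10),
        "seed": seed,
    }


def desk_holdout_config(seed: int = 1) -> dict:
    """A held-out phantom family for cross-validation: a fixed two-layer
    geometry never drawn by the random layered generator's seed stream."""
    cfg = desk_dataset_config(seed + 90001)
    cfg.update({
        "n_items": 10,
        "split": (0, 0, 100),
        "geometry": [
            {"d0": 150.0, "d1": 450.0, "reflectivity": 0.35},
            {"d0": 650.0, "d1": 800.0, "reflectivity": 0.2},
        ],
    })
    return cfg


def desk_train_config(seed: int = 1) -> TrainConfig:
    return TrainConfig(lr=1e-3, epochs_sd=12, epochs_fd=8, batch_size=16,
                       seed=seed, n_patches=4)
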