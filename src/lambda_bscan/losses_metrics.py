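"""Training losses and image-quality metrics.

Losses: mean absolute error (L1, spatial-domain network) and the focal
frequency loss restricted to DFT amplitudes (Fourier-domain network),

    FFL = (1/MN) sum_{u,v} w(u,v) |F_k(u,v) - F_lambda(u,v)|^2,
    w(u,v) = |F_k(u,v) - F_lambda(u,v)|^alpha,

which for the focusing exponent alpha = 1 used here reduces to the mean
cubed absolute difference.

Metrics: MSE, PSNR, SSIM (canonical Gaussian 11x11 window), the
contrast-to-noise ratio between foreground and background ROIs

    CNR_i = 10 log10( |mu_i - mu_b| / sqrt(sigma_i^2 + sigma_b^2) )  [dB],

and the smoothness/structure score beta_s: the normalized correlation of
the mean-subtracted output and reference images (1 = perfect structural
agreement).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from skimage.metrics import structural_similarity

__all__ = ["RegionSet", "l1_loss", "ffl_amp", "mse", "psnr", "ssim",
           "cnr", "beta_s"]


@dataclass(frozen=True)
class RegionSet:
    """Rectangular ROIs for CNR: (r0, r1, c0, c1) half-open, 0-based."""

    foreground: Tuple[Tuple[int, int, int, int], ...]
    background: Tuple[int, int, int, int]

    def validate(self, shape: Tuple[int, int]) -> None:
        for roi in (*self.foreground, self.background):
            r0, r1, c0, c1 = roi
            if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
                raise ValueError(f"ROI {roi} outside image bounds {shape}")


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def l1_loss(hr: np.ndarray, lr: np.ndarray) -> float:
    """Mean absolute error between two images."""
    hr, lr = np.asarray(hr, float), np.asarray(lr, float)
    _check_shapes(hr, lr)
    return float(np.mean(np.abs(hr - lr)))


def ffl_amp(f_k: np.ndarray, f_lambda: np.ndarray, alpha: float = 1.0) -> float:
    """Focal frequency loss on amplitude spectra (see module docstring)."""
    f_k, f_lambda = np.asarray(f_k, float), np.asarray(f_lambda, float)
    _check_shapes(f_k, f_lambda)
    d = np.abs(f_k - f_lambda)
    return float(np.mean(d ** alpha * d ** 2))


def mse(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    _check_shapes(a, b)
    return float(np.mean((a - b) ** 2))


def psnr(a: np.ndarray, b: np.ndarray, max_val: float) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    err = mse(a, b)
    if err == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_val ** 2 / err))


def ssim(a: np.ndarray, b: np.ndarray, data_range: float = None) -> float:
    """Structural similarity with the canonical 11x11 Gaussian window
    (sigma 1.5, K1=0.01, K2=0.03).  Constant identical images score 1."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    _check_shapes(a, b)
    if data_range is None:
        data_range = max(a.max(), b.max()) - min(a.min(), b.min())
    if data_range == 0:
        return 1.0 if np.array_equal(a, b) else 0.0
    # canonical window is 11; clamp to the largest odd size that fits
    win = min(11, min(a.shape))
    win -= 1 - win % 2
    return float(structural_similarity(
        a, b, data_range=data_range, gaussian_weights=True, sigma=1.5,
        win_size=win, use_sample_covariance=False))


def cnr(image: np.ndarray, regions: RegionSet) -> List[float]:
    """Contrast-to-noise ratio (dB) of each foreground ROI against the
    background ROI.  Equal means give -inf; zero joint variance with
    distinct means gives +inf."""
    image = np.asarray(image, float)
    regions.validate(image.shape)
    r0, r1, c0, c1 = regions.background
    bg = image[r0:r1, c0:c1]
    mu_b, var_b = bg.mean(), bg.var()
    out = []
    for fr0, fr1, fc0, fc1 in regions.foreground:
        fg = image[fr0:fr1, fc0:fc1]
        num = abs(fg.mean() - mu_b)
        den = np.sqrt(fg.var() + var_b)
        if num == 0.0:
            out.append(float("-inf"))
        elif den == 0.0:
            out.append(float("inf"))
        else:
            out.append(float(10.0 * np.log10(num / den)))
    return out


def beta_s(i_out: np.ndarray, i_in: np.ndarray) -> float:
    """Normalized correlation of mean-subtracted images, in [-1, 1]."""
    i_out, i_in = np.asarray(i_out, float), np.asarray(i_in, float)
    _check_shapes(i_out, i_in)
    a = i_out - i_out.mean()
    b = i_in - i_in.mean()
    denom = np.sqrt(np.sum(a * a) * np.sum(b * b))
    if denom == 0.0:
        raise ValueError("beta_s undefined for a constant image")
    return float(np.sum(a * b) / denom)
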