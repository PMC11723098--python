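"""Raw fringe frame -> network-ready input: background subtraction, Hann
spectral shaping, inverse DFT with mirror-half removal, wavenumber-layer
attachment, patching, and standardization.

DFT convention, used everywhere in the package: unnormalized forward
(``numpy.fft.fft``), 1/N inverse (``numpy.fft.ifft``), applied along the
spectral/depth axis (axis 0) only.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np

from .octsim import RawFringeFrame, depth_pitch_um

__all__ = [
    "KGrid", "BScanImage", "StandardizationStats",
    "compute_k_grid", "subtract_background", "apply_hann",
    "fringes_to_image", "attach_k_layer", "patchify", "unpatchify",
    "standardize", "destandardize", "wiener_khinchin_residual",
]


@dataclass(frozen=True)
class KGrid:
    """Non-uniform wavenumber samples of a wavelength-linear sweep.

    k(s) = 2 pi / (lambda_min + s (lambda_max - lambda_min)/(N-1)),
    s = 0..N-1: strictly decreasing, because wavelength increases with s.
    """

    k_values: np.ndarray  # rad/nm
    lambda_min: float
    lambda_max: float
    n_samples: int

    def __post_init__(self):
        k = np.asarray(self.k_values, dtype=float)
        object.__setattr__(self, "k_values", k)
        if len(k) != self.n_samples:
            raise ValueError("k_values length must equal n_samples")
        if np.any(np.diff(k) >= 0):
            raise ValueError("k_values must be strictly decreasing")


@dataclass
class BScanImage:
    """Real-valued depth x lateral magnitude image."""

    pixels: np.ndarray
    depth_pitch: float = 1.0  # um of optical path difference per pixel
    provenance: str = "degraded"

    _PROVENANCES = ("degraded", "baseline", "ground_truth", "sd_output",
                    "final_output")

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("B-scan pixels must be 2D (depth x lateral)")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("B-scan pixels must be finite")
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if np.any(self.pixels < 0):
            raise ValueError("magnitude image must be non-negative")


@dataclass(frozen=True)
class StandardizationStats:
    """Mean/std computed over the training split."""

    mean: float
    std: float

    def __post_init__(self):
        if not self.std > 0:
            raise ValueError("std must be positive")


def compute_k_grid(lambda_min: float, lambda_max: float,
                   n_samples: int) -> KGrid:
    """Wavenumbers of a wavelength-linear sweep at each sample index."""
    if not lambda_min < lambda_max:
        raise ValueError("require lambda_min < lambda_max")
    if n_samples < 2:
        raise ValueError("need n_samples >= 2")
    s = np.arange(n_samples)
    lam = lambda_min + s * (lambda_max - lambda_min) / (n_samples - 1)
    return KGrid(k_values=2 * np.pi / lam, lambda_min=lambda_min,
                 lambda_max=lambda_max, n_samples=n_samples)


def subtract_background(frame: RawFringeFrame,
                        background: Union[str, np.ndarray, None]
                        ) -> RawFringeFrame:
    """Remove fixed-pattern background from every column.

    ``background`` is a per-row vector, the string ``"mean-a-scan"`` (the
    row-wise mean across all columns — the standard FD-OCT estimator), or
    ``None`` for identity.
    """
    if background is None:
        return RawFringeFrame(frame.data.copy(), frame.sweep, frame.source)
    if isinstance(background, str):
        if background != "mean-a-scan":
            raise ValueError(f"unknown background estimator {background!r}")
        bg = frame.data.mean(axis=1)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (frame.sweep.n_samples,):
            raise ValueError("background length must equal n_samples")
    return RawFringeFrame(frame.data - bg[:, None], frame.sweep, frame.source)


def apply_hann(frame: RawFringeFrame) -> RawFringeFrame:
    """Multiply each column by the symmetric N-point Hann window
    w[s] = 0.5 (1 - cos(2 pi s / (N-1)))."""
    n = frame.sweep.n_samples
    w = 0.5 * (1.0 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))
    return RawFringeFrame(frame.data * w[:, None], frame.sweep, frame.source)


def fringes_to_image(frame: RawFringeFrame) -> BScanImage:
    """Per-column inverse DFT of the N-point real spectrum; keep the
    magnitude of the first N/2 depth bins (the mirror half is redundant
    for a real spectrum).  Requires even N."""
    n = frame.sweep.n_samples
    if n % 2:
        raise ValueError("mirror-half removal requires an even sample count")
    depth = np.fft.ifft(frame.data, axis=0)
    mag = np.abs(depth[: n // 2, :])
    return BScanImage(pixels=mag, depth_pitch=depth_pitch_um(frame.sweep),
                      provenance="degraded")


def attach_k_layer(image: BScanImage, kgrid: KGrid,
                   normalize: bool = True) -> np.ndarray:
    """Stack the wavenumber column as a second channel.

    Channel 1 is the image; channel 2 is a depth-length column of k values
    replicated across every lateral position, informing the network of the
    sweep non-linearity.  If the grid is longer than the image depth it is
    decimated to the image depth (same wavelength range, same non-linearity
    profile).  With ``normalize`` the k column is shifted/scaled to zero
    mean and unit std (recorded choice; preserves monotonicity).
    """
    rows, cols = image.pixels.shape
    if kgrid.n_samples < rows:
        raise ValueError("k-grid shorter than the image depth")
    if kgrid.n_samples == rows:
        k = kgrid.k_values
    else:
        idx = np.round(np.linspace(0, kgrid.n_samples - 1, rows)).astype(int)
        k = kgrid.k_values[idx]
        if len(np.unique(idx)) != rows:
            raise ValueError("k-grid cannot be decimated to the image depth")
    if normalize:
        k = (k - k.mean()) / k.std()
    tensor = np.empty((rows, cols, 2))
    tensor[:, :, 0] = image.pixels
    tensor[:, :, 1] = k[:, None]
    return tensor


def patchify(tensor: np.ndarray, n_patches: int = 4) -> list:
    """Split along depth into ``n_patches`` equal, non-overlapping patches,
    ordered top to bottom."""
    rows = tensor.shape[0]
    if rows % n_patches:
        raise ValueError(f"depth {rows} not divisible into {n_patches} patches")
    return list(np.split(tensor, n_patches, axis=0))


def unpatchify(patches: Sequence[np.ndarray]) -> np.ndarray:
    """Exact inverse of :func:`patchify` (concatenation along depth)."""
    return np.concatenate(list(patches), axis=0)


def standardize(data: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    return (np.asarray(data, dtype=float) - stats.mean) / stats.std


def destandardize(data: np.ndarray, stats: StandardizationStats) -> np.ndarray:
    return np.asarray(data, dtype=float) * stats.std + stats.mean


def wiener_khinchin_residual(frame: RawFringeFrame) -> float:
    """Relative error between the inverse DFT of the power spectrum |I_D|^2
    and the circular autocorrelation of the depth signal ifft(I_D),
    per column.  Zero (to roundoff) under this package's DFT conventions —
    the discrete Wiener–Khinchin relation."""
    spec = frame.data
    z = np.fft.ifft(spec, axis=0)
    lhs = np.fft.ifft(np.abs(spec.astype(complex)) ** 2, axis=0)
    n = spec.shape[0]
    acf = np.empty_like(z)
    for m in range(n):
        acf[m] = np.sum(z * np.conj(np.roll(z, m, axis=0)), axis=0)
    denom = np.linalg.norm(acf)
    return float(np.linalg.norm(lhs - acf) / (denom if denom else 1.0))
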