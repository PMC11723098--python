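"""Classical k-linearization reconstruction and B-scan averaging.

This is the conventional FD-OCT processing path the learned reconstruction
is compared against: re-interpolate each spectrum from its non-uniform
wavenumber samples onto a uniform k grid, inverse-DFT, and (for the
speckle-reduced ground truth) average several reconstructions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.interpolate import CubicSpline, interp1d

from .octsim import RawFringeFrame
from .preprocess import BScanImage, KGrid, fringes_to_image

__all__ = ["ResampleSpec", "resample_to_k_linear", "reconstruct_baseline",
           "average_bscans"]


@dataclass(frozen=True)
class ResampleSpec:
    """Interpolation method and uniform target wavenumber grid.

    If ``target_grid`` is omitted, a uniform grid with the same endpoints
    and length as the source grid is used (no extrapolation possible).
    """

    method: str = "cubic_spline"  # {"linear", "cubic_spline"}
    target_grid: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.method not in ("linear", "cubic_spline"):
            raise ValueError(f"unknown resampling method {self.method!r}")
        if self.target_grid is not None:
            t = np.asarray(self.target_grid, dtype=float)
            steps = np.diff(t)
            if not np.allclose(steps, steps[0], rtol=1e-12, atol=0):
                raise ValueError("target grid must be uniform")
            object.__setattr__(self, "target_grid", t)

    def resolve_grid(self, kgrid: KGrid) -> np.ndarray:
        if self.target_grid is not None:
            return self.target_grid
        # descending, matching the source orientation (k falls as s grows)
        return np.linspace(kgrid.k_values[0], kgrid.k_values[-1],
                           kgrid.n_samples)


def resample_to_k_linear(frame: RawFringeFrame, kgrid: KGrid,
                         spec: ResampleSpec = ResampleSpec()
                         ) -> RawFringeFrame:
    """Re-interpolate every column from samples at ``kgrid.k_values`` onto
    the uniform target grid.  No extrapolation: the target must lie within
    the source k range.  Cubic splines use natural boundary conditions."""
    k_src = kgrid.k_values
    if len(k_src) != frame.sweep.n_samples:
        raise ValueError("k-grid length must match the frame sampling")
    k_tgt = spec.resolve_grid(kgrid)
    lo, hi = min(k_src[0], k_src[-1]), max(k_src[0], k_src[-1])
    if k_tgt.min() < lo - 1e-12 * hi or k_tgt.max() > hi + 1e-12 * hi:
        raise ValueError("target grid outside the source k-range")
    # interpolators want increasing abscissae; k decreases with s
    k_up = k_src[::-1]
    data_up = frame.data[::-1, :]
    if spec.method == "linear":
        f = interp1d(k_up, data_up, axis=0, kind="linear")
    else:
        f = CubicSpline(k_up, data_up, axis=0, bc_type="natural")
    out = f(k_tgt)
    return RawFringeFrame(data=out, sweep=frame.sweep, source=frame.source)


def reconstruct_baseline(frame: RawFringeFrame, kgrid: KGrid,
                         spec: ResampleSpec = ResampleSpec()) -> BScanImage:
    """Classical reconstruction: resample to uniform k, then inverse DFT.

    The single-frame, speckle-bearing comparator image.
    """
    img = fringes_to_image(resample_to_k_linear(frame, kgrid, spec))
    img.provenance = "baseline"
    return img


def average_bscans(images: Sequence[BScanImage], n: int = 7) -> BScanImage:
    """Pixelwise mean of the first ``n`` images: the speckle-reduced
    ground-truth construction (consecutive-scan averaging)."""
    if n > len(images):
        raise ValueError(f"asked for n={n} images, got {len(images)}")
    head = images[:n]
    shape = head[0].pixels.shape
    for im in head:
        if im.pixels.shape != shape:
            raise ValueError("all images must share a shape")
    mean = np.mean([im.pixels for im in head], axis=0)
    return BScanImage(pixels=mean, depth_pitch=head[0].depth_pitch,
                      provenance="ground_truth")
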