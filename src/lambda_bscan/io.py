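"""Persistence: raw fringe frames as HDF5 groups, B-scans as 32-bit TIFF.

A frame is stored as a dataset ``fringes`` with the sweep/source metadata
as attributes, so a file round-trips to an identical
:class:`~lambda_bscan.octsim.RawFringeFrame`.
"""

from __future__ import annotations

import h5py
import numpy as np
import tifffile

from .octsim import RawFringeFrame, SourceSpec, SweepModel
from .preprocess import BScanImage

__all__ = ["save_frame", "load_frame", "save_bscan", "load_bscan"]


def save_frame(path, frame: RawFringeFrame, group: str = "/") -> None:
    with h5py.File(path, "a") as f:
        g = f.require_group(group)
        if "fringes" in g:
            del g["fringes"]
        d = g.create_dataset("fringes", data=frame.data)
        d.attrs["lambda_min"] = frame.sweep.lambda_min
        d.attrs["lambda_max"] = frame.sweep.lambda_max
        d.attrs["n_samples"] = frame.sweep.n_samples
        d.attrs["sweep_kind"] = frame.sweep.kind
        d.attrs["f_t"] = frame.sweep.f_t
        d.attrs["lambda0"] = frame.source.lambda0
        d.attrs["delta_lambda"] = frame.source.delta_lambda
        d.attrs["shape"] = frame.source.shape
        d.attrs["rho"] = frame.source.rho


def load_frame(path, group: str = "/") -> RawFringeFrame:
    with h5py.File(path, "r") as f:
        d = f[group]["fringes"]
        sweep = SweepModel(kind=str(d.attrs["sweep_kind"]),
                           n_samples=int(d.attrs["n_samples"]),
                           lambda_min=float(d.attrs["lambda_min"]),
                           lambda_max=float(d.attrs["lambda_max"]),
                           f_t=float(d.attrs.get("f_t", 1.0)))
        source = SourceSpec(lambda0=float(d.attrs["lambda0"]),
                            delta_lambda=float(d.attrs["delta_lambda"]),
                            shape=str(d.attrs.get("shape", "gaussian")),
                            rho=float(d.attrs.get("rho", 1.0)))
        return RawFringeFrame(data=d[...], sweep=sweep, source=source)


def save_bscan(path, image: BScanImage) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32),
                     metadata={"depth_pitch_um": image.depth_pitch,
                               "provenance": image.provenance})


def load_bscan(path, provenance: str = "degraded",
               depth_pitch: float = 1.0) -> BScanImage:
    return BScanImage(pixels=np.asarray(tifffile.imread(path), dtype=float),
                      depth_pitch=depth_pitch, provenance=provenance)
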