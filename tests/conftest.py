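import numpy as np
import pytest

from lambda_bscan.octsim import (Phantom, SimOptions, SourceSpec, SweepModel,
                                 depth_pitch_um, make_speckle_phantom,
                                 simulate_fringes, unambiguous_depth_um)


@pytest.fixture(scope="session")
def source():
    return SourceSpec()  # 1310 nm centre, 100 nm FWHM, gaussian


@pytest.fixture(scope="session")
def flat_source():
    return SourceSpec(shape="flat")


@pytest.fixture(scope="session")
def sweep_klin():
    return SweepModel(kind="k_linear", n_samples=256,
                      lambda_min=1260.0, lambda_max=1360.0)


@pytest.fixture(scope="session")
def speckle_frame(source, sweep_klin):
    """One k-linear B-scan of a single uniform speckle layer, with the
    interior row range of the layer for statistics."""
    pitch = depth_pitch_um(sweep_klin)
    zmax = unambiguous_depth_um(sweep_klin)
    geo = [{"d0": 0.2 * zmax, "d1": 0.8 * zmax, "reflectivity": 0.3}]
    ph = make_speckle_phantom(geo, 3.0, a_scans=64, seed=11,
                              depth_pitch=pitch)
    frame = simulate_fringes(ph, source, sweep_klin)
    interior = (int(0.3 * zmax / pitch), int(0.7 * zmax / pitch))
    return frame, geo, interior
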