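"""Classical k-linearization baseline and B-scan averaging."""

import numpy as np
import pytest

from lambda_bscan.baseline import (ResampleSpec, average_bscans,
                                   reconstruct_baseline, resample_to_k_linear)
from lambda_bscan.octsim import (Phantom, RawFringeFrame, SourceSpec,
                                 SweepModel, depth_pitch_um,
                                 make_speckle_phantom, measure_psf_fwhm,
                                 simulate_fringes, unambiguous_depth_um)
from lambda_bscan.preprocess import BScanImage, compute_k_grid, fringes_to_image


@pytest.fixture(scope="module")
def lam_linear_setup(source):
    sweep = SweepModel(kind="lambda_linear", n_samples=512,
                       lambda_min=1185.0, lambda_max=1435.0)
    kgrid = compute_k_grid(1185.0, 1435.0, 512)
    return sweep, kgrid


class TestResample:
    def test_k_linear_input_is_fixed_point(self, flat_source):
        sw = SweepModel(kind="k_linear", n_samples=128, lambda_min=1260,
                        lambda_max=1360)
        frame = simulate_fringes(Phantom.single_reflector(4, 500.0),
                                 flat_source, sw)
        kg_affine = compute_k_grid(1260, 1360, 128)
        # the frame's own sampling is already uniform in k
        k_uniform = np.linspace(2 * np.pi / 1260, 2 * np.pi / 1360, 128)
        from lambda_bscan.preprocess import KGrid
        kg = KGrid(k_values=k_uniform, lambda_min=1260, lambda_max=1360,
                   n_samples=128)
        out = resample_to_k_linear(frame, kg, ResampleSpec("linear"))
        np.testing.assert_allclose(out.data, frame.data, atol=1e-10)

    def test_polynomial_exactness(self):
        """Linear interpolation reproduces degree-1 polynomials in k;
        natural cubic splines reproduce degree-1 (their curvature-free
        subset) and beat linear on smooth nonpolynomial spectra."""
        kg = compute_k_grid(1260, 1360, 64)
        k = kg.k_values
        sw = SweepModel(kind="lambda_linear", n_samples=64, lambda_min=1260,
                        lambda_max=1360)
        target = np.linspace(k[0], k[-1], 64)
        for coeffs in ([0.3, -2.0],):
            poly = np.polyval(coeffs, k)
            frame = RawFringeFrame(poly[:, None], sw, SourceSpec())
            for method in ("linear", "cubic_spline"):
                out = resample_to_k_linear(frame, kg, ResampleSpec(method))
                np.testing.assert_allclose(out.data[:, 0],
                                           np.polyval(coeffs, target),
                                           rtol=1e-9)
        smooth = np.sin(3e4 * k)
        frame = RawFringeFrame(smooth[:, None], sw, SourceSpec())
        errs = {m: np.max(np.abs(
            resample_to_k_linear(frame, kg, ResampleSpec(m)).data[:, 0]
            - np.sin(3e4 * target))) for m in ("linear", "cubic_spline")}
        assert errs["cubic_spline"] < errs["linear"]

    def test_no_extrapolation(self):
        kg = compute_k_grid(1260, 1360, 32)
        sw = SweepModel(kind="lambda_linear", n_samples=32, lambda_min=1260,
                        lambda_max=1360)
        frame = RawFringeFrame(np.zeros((32, 1)), sw, SourceSpec())
        bad = ResampleSpec("linear", target_grid=np.linspace(
            kg.k_values[0] * 1.01, kg.k_values[-1], 32))
        with pytest.raises(ValueError, match="outside"):
            resample_to_k_linear(frame, kg, bad)

    def test_resampling_restores_psf(self, source, lam_linear_setup):
        sweep, kgrid = lam_linear_setup
        sw_k = SweepModel(kind="k_linear", n_samples=512, lambda_min=1185.0,
                          lambda_max=1435.0)
        ph = Phantom.single_reflector(1, 1200.0)
        f_lam = simulate_fringes(ph, source, sweep)
        f_k = simulate_fringes(ph, source, sw_k)
        ref = measure_psf_fwhm(f_k)[0]
        blurred = measure_psf_fwhm(f_lam)[0]
        assert blurred > 2 * ref  # non-linearity visibly degrades
        restored = measure_psf_fwhm(resample_to_k_linear(
            f_lam, kgrid, ResampleSpec("cubic_spline")))[0]
        assert restored == pytest.approx(ref, rel=0.20)

    def test_spline_beats_linear_on_peak_amplitude(self, source,
                                                   lam_linear_setup):
        sweep, kgrid = lam_linear_setup
        ph = Phantom.single_reflector(1, 1500.0)  # deep: high non-linearity
        f_lam = simulate_fringes(ph, source, sweep)
        peaks = {}
        for method in ("linear", "cubic_spline"):
            img = reconstruct_baseline(f_lam, kgrid, ResampleSpec(method))
            peaks[method] = img.pixels[:, 0].max()
        assert peaks["cubic_spline"] >= peaks["linear"]


class TestReconstructBaseline:
    def test_k_linear_frame_matches_direct_idft(self, flat_source):
        sw = SweepModel(kind="k_linear", n_samples=128, lambda_min=1260,
                        lambda_max=1360)
        frame = simulate_fringes(Phantom.single_reflector(2, 700.0),
                                 flat_source, sw)
        from lambda_bscan.preprocess import KGrid
        kg = KGrid(k_values=np.linspace(2 * np.pi / 1260, 2 * np.pi / 1360,
                                        128),
                   lambda_min=1260, lambda_max=1360, n_samples=128)
        img = reconstruct_baseline(frame, kg, ResampleSpec("linear"))
        direct = fringes_to_image(frame)
        np.testing.assert_allclose(img.pixels, direct.pixels, atol=1e-8)
        assert img.provenance == "baseline"

    def test_peak_at_predicted_bin(self, source, lam_linear_setup):
        sweep, kgrid = lam_linear_setup
        pitch = depth_pitch_um(sweep)
        d = 1500.0
        frame = simulate_fringes(Phantom.single_reflector(1, d), source, sweep)
        img = reconstruct_baseline(frame, kgrid, ResampleSpec("cubic_spline"))
        assert np.argmax(img.pixels[:, 0]) == pytest.approx(d / pitch, abs=1)

    def test_zero_frame_gives_zero_image(self, lam_linear_setup):
        sweep, kgrid = lam_linear_setup
        frame = RawFringeFrame(np.zeros((512, 3)), sweep, SourceSpec())
        img = reconstruct_baseline(frame, kgrid)
        assert np.all(img.pixels == 0)

    def test_speckle_retained_in_baseline(self, source):
        sw_l = SweepModel(kind="lambda_linear", n_samples=256,
                          lambda_min=1260, lambda_max=1360)
        kg = compute_k_grid(1260, 1360, 256)
        zmax = unambiguous_depth_um(sw_l)
        pitch = depth_pitch_um(sw_l)
        geo = [{"d0": 0.2 * zmax, "d1": 0.8 * zmax, "reflectivity": 0.3}]
        ph = make_speckle_phantom(geo, 3.0, a_scans=64, seed=2,
                                  depth_pitch=pitch)
        img = reconstruct_baseline(simulate_fringes(ph, source, sw_l), kg)
        r0, r1 = int(0.3 * zmax / pitch), int(0.7 * zmax / pitch)
        layer = img.pixels[r0:r1]
        assert 0.4 <= layer.std() / layer.mean() <= 0.7


class TestAverageBScans:
    def test_identical_images_unchanged(self):
        img = BScanImage(np.abs(np.random.default_rng(0).normal(size=(8, 4))))
        avg = average_bscans([img] * 7)
        np.testing.assert_allclose(avg.pixels, img.pixels)
        assert avg.provenance == "ground_truth"

    def test_default_n_is_seven(self):
        imgs = [BScanImage(np.full((4, 4), float(i))) for i in range(9)]
        avg = average_bscans(imgs)
        assert avg.pixels[0, 0] == pytest.approx(np.mean(range(7)))

    def test_shape_mismatch_rejected(self):
        a = BScanImage(np.ones((4, 4)))
        b = BScanImage(np.ones((4, 5)))
        with pytest.raises(ValueError):
            average_bscans([a, b] + [a] * 5)

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError):
            average_bscans([BScanImage(np.ones((2, 2)))] * 3, n=7)
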