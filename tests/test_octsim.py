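"""Interferogram simulator: sweep grids, fringe physics, speckle phantoms."""

import numpy as np
import pytest

from lambda_bscan.octsim import (Phantom, SimOptions, SourceSpec, SweepModel,
                                 depth_pitch_um, generate_dataset,
                                 make_speckle_phantom, measure_psf_fwhm,
                                 sample_wavelength_grid, simulate_fringes,
                                 unambiguous_depth_um)
from lambda_bscan.octsim import _split_counts
from lambda_bscan.preprocess import fringes_to_image, wiener_khinchin_residual


class TestWavelengthGrid:
    def test_lambda_linear_is_affine_ramp(self):
        sw = SweepModel(kind="lambda_linear", n_samples=3, lambda_min=1.0,
                        lambda_max=2.0)
        np.testing.assert_allclose(sample_wavelength_grid(sw), [1.0, 1.5, 2.0])

    def test_k_linear_inverts_affine_k_grid(self):
        # k = [2pi/1, (2pi/1+2pi/2)/2, 2pi/2] -> lambda = [1, 4/3, 2]
        sw = SweepModel(kind="k_linear", n_samples=3, lambda_min=1.0,
                        lambda_max=2.0)
        np.testing.assert_allclose(sample_wavelength_grid(sw),
                                   [1.0, 4.0 / 3.0, 2.0])

    def test_fdml_spans_range_at_extremes(self):
        sw = SweepModel(kind="fdml_sinusoidal", n_samples=501,
                        lambda_min=1260.0, lambda_max=1360.0)
        lam = sample_wavelength_grid(sw)
        assert lam[0] == pytest.approx(1260.0)
        assert lam[-1] == pytest.approx(1360.0)
        assert np.all(np.diff(lam) > 0)

    def test_fdml_is_sinusoidal_not_linear(self):
        sw = SweepModel(kind="fdml_sinusoidal", n_samples=101,
                        lambda_min=1260.0, lambda_max=1360.0)
        lam = sample_wavelength_grid(sw)
        lin = np.linspace(1260.0, 1360.0, 101)
        assert np.max(np.abs(lam - lin)) > 1.0

    @pytest.mark.parametrize("kwargs", [
        dict(kind="bogus", n_samples=4, lambda_min=1.0, lambda_max=2.0),
        dict(kind="k_linear", n_samples=1, lambda_min=1.0, lambda_max=2.0),
        dict(kind="k_linear", n_samples=4, lambda_min=2.0, lambda_max=1.0),
    ])
    def test_invalid_sweep_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SweepModel(**kwargs)


class TestSimulateFringes:
    def test_empty_phantom_gives_zero_frame(self, flat_source):
        sw = SweepModel(kind="k_linear", n_samples=64, lambda_min=1260,
                        lambda_max=1360)
        ph = Phantom(a_scans=4, scatterers=[np.zeros((0, 2))] * 4)
        frame = simulate_fringes(ph, flat_source, sw)
        assert np.all(frame.data == 0)

    def test_single_reflector_cycle_count(self, flat_source):
        """Pure cosine: cycles over the k range = (k_max-k_min)|d|/2pi."""
        sw = SweepModel(kind="k_linear", n_samples=512, lambda_min=1260,
                        lambda_max=1360)
        d_um = 1000.0
        frame = simulate_fringes(Phantom.single_reflector(1, d_um),
                                 flat_source, sw)
        col = frame.data[:, 0]
        k_span = 2 * np.pi / 1260 - 2 * np.pi / 1360
        expected_cycles = k_span * d_um * 1e3 / (2 * np.pi)
        zero_crossings = np.sum(np.diff(np.sign(col)) != 0)
        assert zero_crossings / 2 == pytest.approx(expected_cycles, abs=1.0)

    def test_peak_bin_doubles_with_depth(self, flat_source):
        sw = SweepModel(kind="k_linear", n_samples=512, lambda_min=1260,
                        lambda_max=1360)
        bins = []
        for d in (800.0, 1600.0):
            frame = simulate_fringes(Phantom.single_reflector(1, d),
                                     flat_source, sw)
            z = np.abs(np.fft.ifft(frame.data[:, 0]))[:256]
            bins.append(int(np.argmax(z)))
        assert bins[1] == pytest.approx(2 * bins[0], abs=1)

    def test_linear_in_sqrt_reflectivity(self, flat_source):
        """Scaling every sqrt(r) by 2 (r by 4) scales the frame by 2."""
        sw = SweepModel(kind="k_linear", n_samples=128, lambda_min=1260,
                        lambda_max=1360)
        sc = [np.array([[500.0, 0.04], [900.0, 0.09]])] * 3
        sc4 = [s * np.array([1.0, 4.0]) for s in sc]
        f1 = simulate_fringes(Phantom(3, sc), flat_source, sw)
        f2 = simulate_fringes(Phantom(3, sc4), flat_source, sw)
        np.testing.assert_allclose(f2.data, 2 * f1.data, atol=1e-12)

    def test_depth_beyond_unambiguous_range_rejected(self, flat_source):
        sw = SweepModel(kind="k_linear", n_samples=64, lambda_min=1260,
                        lambda_max=1360)
        too_deep = unambiguous_depth_um(sw) * 1.01
        with pytest.raises(ValueError, match="unambiguous"):
            simulate_fringes(Phantom.single_reflector(1, too_deep),
                             flat_source, sw)

    def test_fixed_pattern_and_noise_deterministic(self, flat_source):
        sw = SweepModel(kind="k_linear", n_samples=64, lambda_min=1260,
                        lambda_max=1360)
        ph = Phantom.single_reflector(4, 500.0)
        fp = np.linspace(0, 1, 64)
        opts = SimOptions(noise_sigma=0.1, fixed_pattern=fp, seed=3)
        f1 = simulate_fringes(ph, flat_source, sw, opts)
        f2 = simulate_fringes(ph, flat_source, sw, opts)
        np.testing.assert_array_equal(f1.data, f2.data)

    def test_wiener_khinchin_relation(self, speckle_frame):
        """IDFT of the power spectrum equals the circular autocorrelation
        of the depth signal."""
        frame, _, _ = speckle_frame
        assert wiener_khinchin_residual(frame) < 1e-8


class TestSpeckle:
    def test_fully_developed_speckle_contrast(self, speckle_frame):
        """Within a uniform layer the magnitude contrast std/mean is close
        to the Rayleigh value sqrt(4/pi - 1) ~ 0.52."""
        frame, _, (r0, r1) = speckle_frame
        layer = fringes_to_image(frame).pixels[r0:r1]
        contrast = layer.std() / layer.mean()
        assert 0.4 <= contrast <= 0.7

    def test_scatterers_confined_to_layers(self):
        geo = [{"d0": 100.0, "d1": 200.0}, {"d0": 400.0, "d1": 500.0}]
        ph = make_speckle_phantom(geo, 5.0, a_scans=8, seed=0)
        for sc in ph.scatterers:
            d = sc[:, 0]
            assert np.all(((d >= 100) & (d <= 200)) | ((d >= 400) & (d <= 500)))

    def test_same_seed_same_phantom(self):
        geo = [{"d0": 100.0, "d1": 300.0}]
        a = make_speckle_phantom(geo, 3.0, a_scans=4, seed=9)
        b = make_speckle_phantom(geo, 3.0, a_scans=4, seed=9)
        for sa, sb in zip(a.scatterers, b.scatterers):
            np.testing.assert_array_equal(sa, sb)

    def test_nonpositive_density_rejected(self):
        with pytest.raises(ValueError):
            make_speckle_phantom([{"d0": 0.0, "d1": 1.0}], 0.0, a_scans=2)


class TestDepthDependentBlur:
    def test_lambda_linear_psf_broadens_with_depth(self, source):
        """Without resampling, the non-linear k sampling chirps the fringe:
        the PSF FWHM grows with depth."""
        sw = SweepModel(kind="lambda_linear", n_samples=512,
                        lambda_min=1185.0, lambda_max=1435.0)
        depths = (300.0, 700.0, 1100.0, 1500.0)
        widths = [measure_psf_fwhm(simulate_fringes(
            Phantom.single_reflector(1, d), source, sw))[0] for d in depths]
        assert all(b >= a for a, b in zip(widths, widths[1:]))
        assert widths[-1] > widths[0]


class TestGenerateDataset:
    def test_average_of_one_equals_klinear_reconstruction(self, flat_source):
        ph = Phantom.single_reflector(16, 400.0)
        cfg = {"sweep_kind": "k_linear", "n_samples": 64, "phantoms": [ph],
               "n_avg": 1, "split": (100, 0, 0), "source": flat_source,
               "lambda_min": 1260.0, "lambda_max": 1360.0}
        ds = generate_dataset(cfg)
        item = ds.items[0]
        np.testing.assert_allclose(item.ground_truth.pixels,
                                   item.degraded.pixels, atol=1e-12)

    def test_split_percentages(self):
        assert _split_counts(3000, (70, 20, 10)) == (2100, 600, 300)
        with pytest.raises(ValueError):
            _split_counts(10, (70, 20, 20))

    def test_missing_config_keys_rejected(self):
        with pytest.raises(ValueError, match="sweep_kind"):
            generate_dataset({"n_samples": 64, "a_scans": 8})
        with pytest.raises(ValueError, match="image size"):
            generate_dataset({"sweep_kind": "k_linear"})

    def test_dataset_shapes_splits_and_determinism(self):
        cfg = {"sweep_kind": "lambda_linear", "n_samples": 64, "a_scans": 16,
               "n_items": 10, "density": 2.0, "seed": 5, "n_avg": 2,
               "split": (70, 20, 10)}
        ds1 = generate_dataset(cfg)
        ds2 = generate_dataset(cfg)
        assert len(ds1.items) == 10
        assert sum(it.split == "train" for it in ds1.items) == 7
        assert sum(it.split == "val" for it in ds1.items) == 2
        assert sum(it.split == "test" for it in ds1.items) == 1
        for a, b in zip(ds1.items, ds2.items):
            assert a.degraded.pixels.shape == (32, 16)
            np.testing.assert_array_equal(a.degraded.pixels, b.degraded.pixels)
            np.testing.assert_array_equal(a.ground_truth.pixels,
                                          b.ground_truth.pixels)
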