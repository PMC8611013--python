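"""Forward model: line integrals, bin counts, noise, binning, calibration."""

import numpy as np
import pytest

from pcct.geometry import (
    TINY_GEOMETRY,
    DetectorConfig,
    EnergyBinSet,
    ScannerGeometry,
    effective_pixel_at_iso,
)
from pcct.phantoms import DigitalPhantom
from pcct.projector import (
    CalibrationError,
    apply_binning,
    bin_sinogram,
    calibrate_thresholds,
    expected_bin_counts,
    load_sinogram,
    project_material_paths,
    sample_counts,
    save_sinogram,
    simulate_eid,
    simulate_filter_sweep,
)


def disc_phantom(radius_mm, grid_n=320, fov_mm=250.0, material="water",
                 value=1.0):
    px = fov_mm / grid_n
    c = (np.arange(grid_n) - (grid_n - 1) / 2.0) * px
    x, y = np.meshgrid(c, -c)
    frac = np.where(x**2 + y**2 <= radius_mm**2, value, 0.0)
    return DigitalPhantom("disc", px, {material: frac})


@pytest.fixture(scope="module")
def water_disc_paths():
    ph = disc_phantom(80.0)
    return project_material_paths(ph, TINY_GEOMETRY)


class TestPathProjection:
    def test_central_ray_equals_chord(self, water_disc_paths):
        """A ray through the center of an 80 mm disc sees a 16 cm chord."""
        p = water_disc_paths["water"]
        assert p.max() == pytest.approx(16.0, rel=0.01)

    def test_rays_missing_object_are_zero(self, water_disc_paths):
        p = water_disc_paths["water"]
        assert p[:, 0].max() == 0.0
        assert p[:, -1].max() == 0.0

    def test_linear_in_fraction(self):
        full = disc_phantom(50.0, grid_n=160)
        half = disc_phantom(50.0, grid_n=160, value=0.5)
        p_full = project_material_paths(full, TINY_GEOMETRY)["water"]
        p_half = project_material_paths(half, TINY_GEOMETRY)["water"]
        np.testing.assert_allclose(p_half, 0.5 * p_full, atol=1e-12)


class TestExpectedCounts:
    def test_air_scan_equals_binned_fluence(self, spectrum140):
        bins = EnergyBinSet()
        det = DetectorConfig()
        paths = {"water": np.zeros((4, 8))}
        counts = expected_bin_counts(paths, spectrum140, bins, det)
        from pcct.projector import air_bin_counts

        np.testing.assert_allclose(
            counts, np.broadcast_to(air_bin_counts(spectrum140, bins, det),
                                    counts.shape))

    def test_bin_additivity(self, spectrum140, water_disc_paths):
        """Three bins sum to a single wide 30-140 keV bin to 1e-9."""
        det = DetectorConfig()
        sub = {k: v[:8] for k, v in water_disc_paths.items()}
        three = expected_bin_counts(sub, spectrum140, EnergyBinSet(), det)
        wide = expected_bin_counts(sub, spectrum140,
                                   EnergyBinSet((30.0, 140.0)), det)
        np.testing.assert_allclose(three.sum(axis=-1), wide[..., 0],
                                   rtol=1e-9)

    def test_sharp_threshold_limit(self, spectrum140):
        """sigma→0 reproduces hard-threshold sums over the spectrum."""
        det0 = DetectorConfig(energy_sigma_keV=0.0)
        bins = EnergyBinSet()
        paths = {"water": np.zeros((1, 1))}
        counts = expected_bin_counts(paths, spectrum140, bins, det0)[0, 0]
        E = spectrum140.energies_keV
        f = spectrum140.fluence
        for b, (lo, hi) in enumerate(bins.edges):
            sel = (E >= lo) & (E < hi) if b < 2 else (E >= lo) & (E <= hi)
            assert counts[b] == pytest.approx(f[sel].sum(), rel=1e-12)

    def test_more_material_never_raises_counts(self, spectrum140):
        """Beer-Lambert monotonicity along a ray."""
        det = DetectorConfig()
        thin = {"water": np.full((2, 3), 5.0)}
        thick = {"water": np.full((2, 3), 7.0)}
        c_thin = expected_bin_counts(thin, spectrum140, EnergyBinSet(), det)
        c_thick = expected_bin_counts(thick, spectrum140, EnergyBinSet(), det)
        assert np.all(c_thick <= c_thin)

    def test_bins_outside_spectrum_rejected(self, spectrum140):
        with pytest.raises(ValueError, match="support"):
            expected_bin_counts({"water": np.zeros((1, 1))}, spectrum140,
                                EnergyBinSet((30.0, 180.0)), DetectorConfig())


class TestSampling:
    def test_zero_expectation_zero_counts(self):
        c = sample_counts(np.zeros((5, 5, 3)), DetectorConfig(), seed=1)
        assert c.max() == 0

    def test_low_bin_saturation_value(self):
        """14-bit counter clips at 2^14 - 1 = 16383."""
        det = DetectorConfig()
        assert det.saturation[0] == 16383
        big = np.full((1, 1, 3), 1e6)
        c = sample_counts(big, det, seed=0)
        np.testing.assert_array_equal(c[0, 0], det.saturation)

    def test_poisson_mean(self):
        """Sample mean over 10,000 draws at expectation 100."""
        c = sample_counts(np.full((10000, 1, 3), 100.0), DetectorConfig(),
                          seed=3)
        se = np.sqrt(100.0 / 10000)
        assert abs(c[..., 0].mean() - 100.0) < 3 * se

    def test_variance_over_mean_near_unity(self):
        """Poisson dispersion across seeds stays in [0.9, 1.1]."""
        expected = np.full((200, 4, 3), 80.0)
        draws = np.stack([sample_counts(expected, DetectorConfig(), seed=s)
                          for s in range(8)])
        vm = draws.var(axis=0).mean() / draws.mean()
        assert 0.9 < vm < 1.1

    def test_reproducible_given_seed(self):
        e = np.full((10, 10, 3), 55.0)
        a = sample_counts(e, DetectorConfig(), seed=42)
        b = sample_counts(e, DetectorConfig(), seed=42)
        np.testing.assert_array_equal(a, b)


class TestBinning:
    def test_standard_mode_yields_16_slices_and_384_columns(self):
        native = np.random.default_rng(0).poisson(
            50.0, size=(80, 2304, 3)).astype(float)
        binned = apply_binning(native, DetectorConfig())
        assert binned.shape == (16, 384, 3)

    def test_hr_mode_is_identity(self):
        native = np.arange(24.0).reshape(2, 4, 3)
        np.testing.assert_array_equal(
            apply_binning(native, DetectorConfig(binning_mode="hr")), native)

    def test_total_counts_conserved(self):
        native = np.random.default_rng(1).poisson(
            30.0, size=(10, 24, 3)).astype(float)
        binned = apply_binning(native, DetectorConfig())
        assert binned.sum() == pytest.approx(native.sum(), rel=1e-12)

    def test_nondivisible_dims_rejected(self):
        with pytest.raises(ValueError):
            apply_binning(np.zeros((7, 24, 3)), DetectorConfig())

    def test_sinogram_binning_conserves_columns_total(self):
        native = np.random.default_rng(2).uniform(0, 99, size=(6, 12, 3))
        det = DetectorConfig()
        binned = bin_sinogram(native, det)
        rf, _ = det.binning_factors
        assert binned.sum() == pytest.approx(rf * native.sum(), rel=1e-12)


class TestEffectivePixel:
    def test_standard_z_is_0640(self):
        g, d = ScannerGeometry(), DetectorConfig()
        assert effective_pixel_at_iso(g, d, "z") == pytest.approx(0.640,
                                                                  abs=5e-4)

    def test_hr_z_is_0128(self):
        g = ScannerGeometry()
        d = DetectorConfig(binning_mode="hr")
        assert effective_pixel_at_iso(g, d, "z") == pytest.approx(0.128,
                                                                  abs=5e-4)

    def test_hr_is_standard_over_five(self):
        g = ScannerGeometry()
        std = effective_pixel_at_iso(g, DetectorConfig(), "z")
        hr = effective_pixel_at_iso(g, DetectorConfig(binning_mode="hr"), "z")
        assert hr == pytest.approx(std / 5.0, rel=1e-12)

    def test_z_coverage_consistency(self):
        """Binned z pixel x slice count covers all native rows at iso."""
        g, d = ScannerGeometry(), DetectorConfig()
        z = effective_pixel_at_iso(g, d, "z")
        coverage = z * (g.n_rows // d.row_binning)
        native = g.row_pitch_mm * g.n_rows * g.sid_mm / g.sdd_mm
        assert coverage == pytest.approx(native, rel=1e-12)


class TestEID:
    def test_air_scan_is_energy_weighted_fluence(self, spectrum140):
        det = DetectorConfig(binning_mode="hr")
        signal, air = simulate_eid({"water": np.zeros((2, 2))}, spectrum140,
                                   det, seed=None)
        expected = (spectrum140.fluence * spectrum140.energies_keV).sum()
        assert air == pytest.approx(expected)
        np.testing.assert_allclose(signal, expected)

    def test_monoenergetic_signal_is_E_times_counts(self):
        from pcct.physics import TubeSpectrum

        E = np.array([59.0, 60.0, 61.0])
        f = np.array([0.0, 1000.0, 0.0])
        spec = TubeSpectrum(140.0, E, f)
        det = DetectorConfig(binning_mode="hr", energy_sigma_keV=0.0)
        paths = {"water": np.full((1, 1), 4.0)}
        signal, _ = simulate_eid(paths, spec, det, seed=None)
        counts = expected_bin_counts(paths, spec,
                                     EnergyBinSet((59.0, 61.0)), det)
        assert signal[0, 0] == pytest.approx(60.0 * counts[0, 0, 0])


class TestThresholdCalibration:
    dac = np.arange(35, 90, 0.25)

    def _sweeps(self, spectrum, det):
        return {
            "gadolinium": (self.dac, simulate_filter_sweep(
                spectrum, det, "gadolinium", 0.1, self.dac)),
            "tungsten": (self.dac, simulate_filter_sweep(
                spectrum, det, "tungsten", 0.05, self.dac)),
        }

    def test_identity_calibration(self, spectrum140):
        det = DetectorConfig(threshold_gain=1.0, threshold_offset_keV=0.0)
        res = calibrate_thresholds(self._sweeps(spectrum140, det))
        assert res.gain_keV_per_dac == pytest.approx(1.0, abs=0.02)
        assert abs(res.offset_keV) < 0.5
        assert res.edge_dac["gadolinium"] == pytest.approx(50.2, abs=0.5)
        assert res.edge_dac["tungsten"] == pytest.approx(69.5, abs=0.5)

    @pytest.mark.parametrize("gain,offset", [(0.95, 3.0), (1.05, -2.0)])
    def test_parameter_recovery(self, spectrum140, gain, offset):
        det = DetectorConfig(threshold_gain=gain,
                             threshold_offset_keV=offset)
        res = calibrate_thresholds(self._sweeps(spectrum140, det))
        assert res.gain_keV_per_dac == pytest.approx(gain, abs=0.02)
        assert res.offset_keV == pytest.approx(offset, abs=0.5)
        # located edges map to the true energies through the device map
        for m, d in res.edge_dac.items():
            assert gain * d + offset == pytest.approx(
                res.edge_keV_true[m], abs=0.5)

    def test_sweep_missing_edge_raises(self, spectrum140):
        det = DetectorConfig()
        bad = np.arange(75, 95, 0.25)
        sweeps = self._sweeps(spectrum140, det)
        sweeps["gadolinium"] = (bad, simulate_filter_sweep(
            spectrum140, det, "gadolinium", 0.1, bad))
        with pytest.raises(CalibrationError, match="gadolinium"):
            calibrate_thresholds(sweeps)


class TestPersistence:
    def test_hdf5_round_trip(self, tmp_path, spectrum140):
        from pcct.projector import acquire

        ph = disc_phantom(40.0, grid_n=160)
        sino = acquire(ph, TINY_GEOMETRY, spectrum140, EnergyBinSet(),
                       DetectorConfig(), seed=9)
        path = tmp_path / "sino.h5"
        save_sinogram(sino, path)
        back = load_sinogram(path)
        np.testing.assert_array_equal(back.counts, sino.counts)
        np.testing.assert_allclose(back.air_counts, sino.air_counts)
        assert back.geometry == sino.geometry
        assert back.bins == sino.bins
        assert back.seed == sino.seed
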