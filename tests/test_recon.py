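"""Log-normalization and fan-beam FBP: accuracy, linearity, HU closure."""

import numpy as np
import pytest

from pcct.geometry import TINY_GEOMETRY, DetectorConfig, EnergyBinSet
from pcct.phantoms import DigitalPhantom
from pcct.projector import BinnedSinogram, acquire, project_material_paths
from pcct.recon import (
    EPS_COUNTS,
    fbp_fan,
    log_normalize,
    reconstruct_all,
)


def water_disc(grid_n=320, radius_mm=80.0, fov_mm=250.0):
    px = fov_mm / grid_n
    c = (np.arange(grid_n) - (grid_n - 1) / 2.0) * px
    x, y = np.meshgrid(c, -c)
    frac = np.where(x**2 + y**2 <= radius_mm**2, 1.0, 0.0)
    return DigitalPhantom("disc", px, {"water": frac})


def central_roi(n, fov_mm=250.0, radius_mm=20.0):
    c = (np.arange(n) - (n - 1) / 2.0) * (fov_mm / n)
    x, y = np.meshgrid(c, -c)
    return x**2 + y**2 <= radius_mm**2


@pytest.fixture(scope="module")
def noiseless_water_sino(spectrum140):
    ph = water_disc()
    return acquire(ph, TINY_GEOMETRY, spectrum140, EnergyBinSet(),
                   DetectorConfig(), seed=0, noiseless=True)


class TestLogNormalize:
    def test_air_counts_give_zero(self, noiseless_water_sino):
        p = log_normalize(noiseless_water_sino, 0)
        assert p[:, 0] == pytest.approx(0.0, abs=1e-12)

    def test_central_ray_matches_spectral_oracle(self, spectrum140,
                                                 noiseless_water_sino):
        """-ln of the spectrum-weighted transmission through the 16 cm
        chord, computed by direct quadrature over the energy grid."""
        from pcct.materials import get_material
        from pcct.projector import bin_weights

        det = noiseless_water_sino.det
        bins = noiseless_water_sino.bins
        mu_w = get_material("water").mass_attenuation(
            spectrum140.energies_keV)
        W = bin_weights(spectrum140.energies_keV, bins, det.energy_sigma_keV)
        g = spectrum140.fluence[:, None] * W
        trans = np.exp(-mu_w * 16.0)
        for b in range(bins.n_bins):
            expected = -np.log((g[:, b] * trans).sum() / g[:, b].sum())
            p = log_normalize(noiseless_water_sino, b)
            assert p.max() == pytest.approx(expected, rel=0.01)

    def test_zero_counts_guarded(self, noiseless_water_sino):
        s = noiseless_water_sino
        zero = BinnedSinogram(np.zeros_like(s.counts), s.air_counts,
                              s.geometry, s.bins, s.det, 0)
        p = log_normalize(zero, "total")
        assert np.all(np.isfinite(p))
        assert p.max() == pytest.approx(
            -np.log(EPS_COUNTS / s.air_counts.sum(axis=-1).max()), rel=1e-6)


class TestFBP:
    def test_zero_sinogram_gives_zero_image(self):
        p = np.zeros((TINY_GEOMETRY.n_views, 64))
        img = fbp_fan(p, TINY_GEOMETRY, DetectorConfig(), out_n=64)
        np.testing.assert_allclose(img, 0.0)

    def test_linearity(self, noiseless_water_sino):
        p = log_normalize(noiseless_water_sino, "total")
        det = noiseless_water_sino.det
        a = fbp_fan(p, TINY_GEOMETRY, det, out_n=96)
        b = fbp_fan(2.5 * p, TINY_GEOMETRY, det, out_n=96)
        np.testing.assert_allclose(b, 2.5 * a, rtol=1e-10, atol=1e-12)

    def test_monoenergetic_disc_recovers_mu(self):
        """Known-mu sinogram reconstructs to that mu within 2%."""
        ph = water_disc()
        paths = project_material_paths(ph, TINY_GEOMETRY)["water"]
        mu0 = 0.2  # cm^-1
        det = DetectorConfig(binning_mode="hr")
        img = fbp_fan(mu0 * paths, TINY_GEOMETRY, det, out_n=160)
        roi = central_roi(160)
        assert img[roi].mean() == pytest.approx(mu0, rel=0.02)

    def test_too_few_views_rejected(self):
        with pytest.raises(ValueError, match="views"):
            fbp_fan(np.zeros((1, 64)), TINY_GEOMETRY, DetectorConfig(),
                    out_n=32)

    def test_hann_filter_smooths(self, noiseless_water_sino):
        p = log_normalize(noiseless_water_sino, "total")
        det = noiseless_water_sino.det
        sharp = fbp_fan(p, TINY_GEOMETRY, det, out_n=96)
        smooth = fbp_fan(p, TINY_GEOMETRY, det, out_n=96,
                         filter_name="hann")
        # apodization reduces high-frequency content (image gradient power)
        assert np.abs(np.diff(smooth, axis=1)).sum() \
            < np.abs(np.diff(sharp, axis=1)).sum()


class TestReconstructAll:
    def test_water_closure_all_channels(self, tiny_profile, tiny_water_cal,
                                        spectrum140):
        """Reconstructing the calibration phantom returns ~0 HU in water."""
        ph = water_disc()
        sino = acquire(ph, tiny_profile.geometry, spectrum140,
                       tiny_profile.bins, tiny_profile.det, seed=0,
                       noiseless=True)
        images = reconstruct_all(sino, tiny_water_cal,
                                 out_n=tiny_profile.recon_n)
        roi = central_roi(tiny_profile.recon_n)
        for name, img in images.items():
            assert abs(img.hu[roi].mean()) < 10.0, name

    def test_air_background_near_minus_1000(self, tiny_profile,
                                            tiny_water_cal, spectrum140):
        ph = water_disc()
        sino = acquire(ph, tiny_profile.geometry, spectrum140,
                       tiny_profile.bins, tiny_profile.det, seed=0,
                       noiseless=True)
        images = reconstruct_all(sino, tiny_water_cal,
                                 out_n=tiny_profile.recon_n)
        n = tiny_profile.recon_n
        c = (np.arange(n) - (n - 1) / 2.0) * (250.0 / n)
        x, y = np.meshgrid(c, -c)
        ring = (x**2 + y**2 >= 100.0**2) & (x**2 + y**2 <= 120.0**2)
        assert images["total"].hu[ring].mean() == pytest.approx(-1000.0,
                                                                abs=30.0)

    def test_missing_calibration_rejected(self, noiseless_water_sino):
        with pytest.raises(ValueError, match="calibration"):
            reconstruct_all(noiseless_water_sino, None)

    def test_noise_falls_with_dose(self, tiny_profile, tiny_water_cal):
        """Reconstructed ROI SD decreases monotonically over a 4-point
        exposure sweep (expectations scale linearly with mAs)."""
        from pcct.pipeline import expected_sinogram, sample_sinogram

        ph = water_disc()
        binned, air, _ = expected_sinogram(ph, tiny_profile)
        base_mas = tiny_profile.mAs
        roi = central_roi(tiny_profile.recon_n)
        sds = []
        for k in (0.1, 0.25, 0.5, 1.0):
            sino = sample_sinogram(binned * k, air * k, tiny_profile, 77)
            images = reconstruct_all(sino, tiny_water_cal,
                                     out_n=tiny_profile.recon_n)
            sds.append(images["total"].hu[roi].std())
        assert all(a > b for a, b in zip(sds, sds[1:])), sds


class TestImageIO:
    def test_nifti_and_tiff_round_trip_values(self, tmp_path):
        import nibabel as nib

        from pcct.recon import ReconImage, save_nifti, save_tiff

        img = ReconImage(np.linspace(-500, 1500, 64 * 64).reshape(64, 64),
                         pixel_mm=0.4, provenance="total")
        save_nifti(img, tmp_path / "t.nii.gz")
        back = np.asarray(nib.load(tmp_path / "t.nii.gz").dataobj)
        np.testing.assert_allclose(back, img.hu, atol=1e-3)
        save_tiff(img, tmp_path / "t.tif")
        import tifffile

        raw = tifffile.imread(tmp_path / "t.tif").astype(float) - 1024
        np.testing.assert_allclose(raw, img.hu, atol=1.0)
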