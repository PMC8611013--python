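"""Log-normalization and equiangular fan-beam filtered back-projection.

The chain is the classical short-scan-free (full rotation) equiangular
fan-beam FBP: weight projections by D·cos(gamma), convolve with the
equiangular ramp kernel (optionally Hann-apodized), back-project with the
1/L^2 distance weight.  A water-disc self-calibration fixes the effective
water attenuation of each energy channel so that water reconstructs to
0 HU per bin, per total-energy, and for the EID comparison mode.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pcct._kernels import backproject
from pcct.geometry import DetectorConfig, EnergyBinSet, ScannerGeometry
from pcct.phantoms import DigitalPhantom
from pcct.physics import TubeSpectrum, hu_from_mu
from pcct.projector import (
    BinnedSinogram,
    acquire,
    project_material_paths,
    simulate_eid,
)

__all__ = [
    "ReconImage",
    "WaterCalibration",
    "log_normalize",
    "fbp_fan",
    "water_calibration",
    "reconstruct_all",
    "reconstruct_eid",
    "save_nifti",
    "save_tiff",
    "save_png_preview",
]

#: zero-count guard in the log normalization
EPS_COUNTS = 0.5


@dataclass(frozen=True)
class ReconImage:
    """HU-calibrated 2-D image with provenance."""

    hu: np.ndarray = field(repr=False)
    pixel_mm: float = 0.4
    provenance: str = "total"
    filter_name: str = "ram-lak"
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not np.all(np.isfinite(self.hu)):
            raise ValueError("reconstructed image contains non-finite values")

    @property
    def grid_n(self) -> int:
        return self.hu.shape[0]


@dataclass(frozen=True)
class WaterCalibration:
    """Effective water attenuation (cm^-1) per channel."""

    mu_water_bins: np.ndarray
    mu_water_total: float
    mu_water_eid: float = np.nan


def log_normalize(sino: BinnedSinogram, channel) -> np.ndarray:
    """Line-integral sinogram p = −ln(max(counts, ε)/air) for one channel.

    ``channel`` is a bin index or "total" (counts summed over bins first —
    the total energy is the combined energy of all bins).
    """
    if channel == "total":
        counts = sino.counts.sum(axis=-1).astype(float)
        air = sino.air_counts.sum(axis=-1)
    else:
        counts = sino.counts[..., channel].astype(float)
        air = sino.air_counts[..., channel]
    if np.any(air <= 0):
        raise ValueError("air reference must be positive everywhere")
    return -np.log(np.maximum(counts, EPS_COUNTS) / air)


def _ramp_kernel(n_cols: int, dgamma: float, filter_name: str) -> np.ndarray:
    """Spatial-domain equiangular ramp kernel of length 2*n_cols-1."""
    n = np.arange(-(n_cols - 1), n_cols)
    g = np.zeros(n.shape)
    g[n == 0] = 1.0 / (8.0 * dgamma**2)
    odd = n % 2 == 1
    g[odd] = -0.5 / (np.pi * np.sin(n[odd] * dgamma)) ** 2
    if filter_name == "hann":
        # apodize in the frequency domain
        size = 1 << int(np.ceil(np.log2(2 * len(g))))
        G = np.fft.rfft(g, size)
        f = np.arange(G.shape[0]) / (G.shape[0] - 1)
        G *= 0.5 * (1.0 + np.cos(np.pi * f))
        g_t = np.fft.irfft(G, size)
        g = g_t[: len(g)]
    elif filter_name != "ram-lak":
        raise ValueError(f"unknown filter '{filter_name}'")
    return g


def fbp_fan(
    p: np.ndarray,
    geometry: ScannerGeometry,
    det: DetectorConfig,
    *,
    out_n: int = 625,
    out_fov_mm: float | None = None,
    filter_name: str = "ram-lak",
) -> np.ndarray:
    """Equiangular fan-beam FBP of a (views, binned columns) sinogram.

    Returns the reconstructed attenuation image (cm^-1) on an out_n×out_n
    grid covering ``out_fov_mm`` (default: the scanner FoV).  The operator
    is linear in p.
    """
    if p.ndim != 2:
        raise ValueError("sinogram must be 2-D (views, columns)")
    if p.shape[0] < 2:
        raise ValueError("at least 2 views are required")
    n_views, n_cols = p.shape
    _, cf = det.binning_factors
    if n_cols * cf != geometry.n_cols:
        # infer the column binning actually used
        if geometry.n_cols % n_cols:
            raise ValueError(
                f"{n_cols} sinogram columns incompatible with "
                f"{geometry.n_cols} native columns"
            )
        cf = geometry.n_cols // n_cols
    gammas = geometry.gamma_of_cols(n_cols, cf)
    dgamma = gammas[1] - gammas[0]

    weighted = p * (geometry.sid_mm * np.cos(gammas))[None, :]
    kernel = _ramp_kernel(n_cols, dgamma, filter_name)
    size = 1 << int(np.ceil(np.log2(len(kernel) + n_cols)))
    K = np.fft.rfft(kernel, size)
    P = np.fft.rfft(weighted, size, axis=1)
    conv = np.fft.irfft(P * K, size, axis=1)[:, n_cols - 1: 2 * n_cols - 1]
    q = np.ascontiguousarray(conv * dgamma)

    out_fov = geometry.fov_mm if out_fov_mm is None else out_fov_mm
    px = out_fov / out_n
    betas = geometry.view_angles()[:n_views]
    img_per_mm = backproject(q, px, geometry.sid_mm, betas, gammas, out_n)
    return img_per_mm * 10.0   # mm^-1 → cm^-1


def water_calibration(
    geometry: ScannerGeometry,
    spectrum: TubeSpectrum,
    bins: EnergyBinSet,
    det: DetectorConfig,
    *,
    out_n: int = 625,
    out_fov_mm: float | None = None,
    disc_radius_mm: float = 80.0,
    filter_name: str = "ram-lak",
    with_eid: bool = False,
) -> WaterCalibration:
    """Effective water attenuation per channel from a noiseless water scan.

    A centered water disc is acquired noiselessly and reconstructed; the
    mean attenuation in a central ROI defines mu_water_eff for each bin,
    for the total-energy channel, and (optionally) for the EID mode.
    """
    grid_n = 2 * out_n
    pixel = geometry.fov_mm / grid_n
    c = (np.arange(grid_n) - (grid_n - 1) / 2.0) * pixel
    x, y = np.meshgrid(c, -c)
    disc = (x**2 + y**2 <= disc_radius_mm**2).astype(float)
    phantom = DigitalPhantom("water_cal", pixel, {"water": disc})
    paths = project_material_paths(phantom, geometry)
    sino = acquire(phantom, geometry, spectrum, bins, det, seed=0,
                   paths=paths, noiseless=True)
    out_fov = geometry.fov_mm if out_fov_mm is None else out_fov_mm
    px = out_fov / out_n
    cc = (np.arange(out_n) - (out_n - 1) / 2.0) * px
    xx, yy = np.meshgrid(cc, -cc)
    roi = xx**2 + yy**2 <= (disc_radius_mm / 4.0) ** 2

    mu_bins = np.empty(bins.n_bins)
    for b in range(bins.n_bins):
        img = fbp_fan(log_normalize(sino, b), geometry, det,
                      out_n=out_n, out_fov_mm=out_fov, filter_name=filter_name)
        mu_bins[b] = img[roi].mean()
    img_t = fbp_fan(log_normalize(sino, "total"), geometry, det,
                    out_n=out_n, out_fov_mm=out_fov, filter_name=filter_name)
    mu_total = float(img_t[roi].mean())
    mu_eid = np.nan
    if with_eid:
        signal, air_signal = simulate_eid(paths, spectrum, det, seed=None)
        p = -np.log(np.maximum(signal, 1e-12) / air_signal)
        p = _bin_columns(p, det, geometry)
        img_e = fbp_fan(p, geometry, det, out_n=out_n, out_fov_mm=out_fov,
                        filter_name=filter_name)
        mu_eid = float(img_e[roi].mean())
    return WaterCalibration(mu_bins, mu_total, mu_eid)


def _bin_columns(p: np.ndarray, det: DetectorConfig,
                 geometry: ScannerGeometry) -> np.ndarray:
    """Average a native-column line-integral sinogram into binned columns."""
    _, cf = det.binning_factors
    if cf == 1 or p.shape[1] != geometry.n_cols:
        return p
    v, c = p.shape
    return p.reshape(v, c // cf, cf).mean(axis=2)


def reconstruct_all(
    sino: BinnedSinogram,
    water_cal: WaterCalibration,
    *,
    out_n: int = 625,
    out_fov_mm: float | None = None,
    filter_name: str = "ram-lak",
) -> dict[str, ReconImage]:
    """Per-bin and total-energy HU images from a binned sinogram."""
    if water_cal is None:
        raise ValueError("water calibration is required to produce HU images")
    geometry = sino.geometry
    out_fov = geometry.fov_mm if out_fov_mm is None else out_fov_mm
    px = out_fov / out_n
    images = {}
    for b in range(sino.bins.n_bins):
        mu = fbp_fan(log_normalize(sino, b), geometry, sino.det,
                     out_n=out_n, out_fov_mm=out_fov, filter_name=filter_name)
        images[f"bin{b + 1}"] = ReconImage(
            hu_from_mu(mu, water_cal.mu_water_bins[b]), px,
            provenance=f"bin{b + 1}", filter_name=filter_name,
            meta={"seed": sino.seed},
        )
    mu = fbp_fan(log_normalize(sino, "total"), geometry, sino.det,
                 out_n=out_n, out_fov_mm=out_fov, filter_name=filter_name)
    images["total"] = ReconImage(
        hu_from_mu(mu, water_cal.mu_water_total), px,
        provenance="total", filter_name=filter_name, meta={"seed": sino.seed},
    )
    return images


def reconstruct_eid(
    signal: np.ndarray,
    air_signal: float,
    geometry: ScannerGeometry,
    det: DetectorConfig,
    water_cal: WaterCalibration,
    *,
    out_n: int = 625,
    out_fov_mm: float | None = None,
    filter_name: str = "ram-lak",
) -> ReconImage:
    """HU image from an energy-integrating acquisition."""
    if not np.isfinite(water_cal.mu_water_eid):
        raise ValueError("water calibration lacks the EID channel "
                         "(run water_calibration(..., with_eid=True))")
    p = -np.log(np.maximum(signal, 1e-12) / air_signal)
    p = _bin_columns(p, det, geometry)
    out_fov = geometry.fov_mm if out_fov_mm is None else out_fov_mm
    mu = fbp_fan(p, geometry, det, out_n=out_n, out_fov_mm=out_fov,
                 filter_name=filter_name)
    return ReconImage(hu_from_mu(mu, water_cal.mu_water_eid),
                      out_fov / out_n, provenance="eid",
                      filter_name=filter_name)


# ---------------------------------------------------------------------------
# Image output
# ---------------------------------------------------------------------------


def save_nifti(image: ReconImage, path) -> None:
    import nibabel as nib

    affine = np.diag([image.pixel_mm, image.pixel_mm, 1.0, 1.0])
    nib.save(nib.Nifti1Image(image.hu.astype(np.float32), affine), path)


def save_tiff(image: ReconImage, path) -> None:
    import json

    import tifffile

    clipped = np.clip(image.hu, -1024, 64511) + 1024
    tifffile.imwrite(path, clipped.astype(np.uint16))
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as f:
        json.dump({"pixel_mm": image.pixel_mm, "provenance": image.provenance,
                   "filter": image.filter_name, "offset_hu": -1024}, f)


def save_png_preview(image: ReconImage, path, *, window: float = 450.0,
                     level: float = 100.0) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = level - window / 2.0, level + window / 2.0
    fig, ax = plt.subplots(figsize=(4, 4), dpi=150)
    ax.imshow(image.hu, cmap="gray", vmin=lo, vmax=hi)
    ax.axis("off")
    fig.tight_layout(pad=0)
    fig.savefig(path)
    plt.close(fig)
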