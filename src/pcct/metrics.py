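"""ROI statistics, CNR, iodine-map CNR gain, HU comparison, bar modulation.

The contrast-to-noise ratio follows the system's evaluation convention:
CNR = (ROI_tissue − ROI_muscle) / SD_noise, where the noise SD is
measured in a homogeneous background ROI of the same image.  The
iodine-map CNR gain is the per-tissue ratio of the CNR measured on the
decomposed iodine map to the CNR measured on the total-energy image of
the same acquisition; replicate acquisitions (different noise seeds)
stand in for repeated manual measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from pcct.phantoms import DigitalPhantom, ROISpec
from pcct.recon import ReconImage

__all__ = [
    "ROIStats",
    "CNRReport",
    "roi_mask",
    "roi_stats",
    "cnr",
    "cnr_gain",
    "hu_comparison",
    "bar_modulation",
]


@dataclass(frozen=True)
class ROIStats:
    label: str
    n_pixels: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n_pixels < 1:
            raise ValueError(f"ROI '{self.label}' contains no pixels")


@dataclass(frozen=True)
class CNRReport:
    """Per-tissue CNR on the total-energy image and the iodine map."""

    tissues: tuple
    cnr_total: dict
    cnr_iodine: dict
    gain: dict
    n_replicates: int = 1

    def to_frame(self):
        import pandas as pd

        rows = []
        for t in self.tissues:
            rows.append({
                "tissue": t,
                "cnr_total_mean": np.mean(self.cnr_total[t]),
                "cnr_total_sd": np.std(self.cnr_total[t]),
                "cnr_iodine_mean": np.mean(self.cnr_iodine[t]),
                "cnr_iodine_sd": np.std(self.cnr_iodine[t]),
                "gain_mean": np.mean(self.gain[t]),
                "gain_sd": np.std(self.gain[t]),
            })
        return pd.DataFrame(rows)


def _image_array(image):
    return image.hu if isinstance(image, ReconImage) else np.asarray(image)


def _pixel_mm(image, default=0.4):
    return image.pixel_mm if isinstance(image, ReconImage) else default


def roi_mask(shape, roi: ROISpec, pixel_mm: float) -> np.ndarray:
    """Pixels whose centers fall inside the circular ROI."""
    n = shape[0]
    half = (n - 1) / 2.0
    cols = (np.arange(n) - half) * pixel_mm
    rows = (half - np.arange(n)) * pixel_mm
    x = cols[None, :]
    y = rows[:, None]
    cx, cy = roi.center_mm
    return (x - cx) ** 2 + (y - cy) ** 2 <= roi.radius_mm**2


def roi_stats(image, roi: ROISpec, pixel_mm: float | None = None) -> ROIStats:
    """Mean and SD over pixels whose centers fall inside the circle."""
    arr = _image_array(image)
    px = pixel_mm if pixel_mm is not None else _pixel_mm(image)
    mask = roi_mask(arr.shape, roi, px)
    vals = arr[mask]
    if vals.size == 0:
        raise ValueError(f"ROI '{roi.label}' lies outside the image")
    return ROIStats(roi.label, int(vals.size), float(vals.mean()),
                    float(vals.std()))


def cnr(image, tissue: ROISpec, muscle: ROISpec, noise: ROISpec,
        pixel_mm: float | None = None) -> float:
    """CNR = (mean_tissue − mean_muscle) / SD_noise; sign preserved."""
    st = roi_stats(image, tissue, pixel_mm)
    sm = roi_stats(image, muscle, pixel_mm)
    sn = roi_stats(image, noise, pixel_mm)
    if sn.sd <= 0:
        raise ZeroDivisionError(
            "noise ROI has zero SD; use a noisy acquisition or a "
            "background region with nonzero texture"
        )
    return (st.mean - sm.mean) / sn.sd


def cnr_gain(
    total_images,
    iodine_maps,
    rois: list[ROISpec],
    *,
    tissues=("tumor", "liver", "aorta"),
    pixel_mm: float | None = None,
) -> CNRReport:
    """Per-tissue CNR_iodine / CNR_total over replicate acquisitions.

    ``total_images`` and ``iodine_maps`` are matched replicate lists
    (same phantom and dose, different noise seeds).
    """
    if not isinstance(total_images, (list, tuple)):
        total_images = [total_images]
    if not isinstance(iodine_maps, (list, tuple)):
        iodine_maps = [iodine_maps]
    if len(total_images) != len(iodine_maps):
        raise ValueError("need matched replicate lists")
    by_role = {r.role: r for r in rois}
    muscle, noise = by_role["muscle"], by_role["noise"]
    cnr_t = {t: [] for t in tissues}
    cnr_i = {t: [] for t in tissues}
    gain = {t: [] for t in tissues}
    for img, iod in zip(total_images, iodine_maps):
        px = pixel_mm if pixel_mm is not None else _pixel_mm(img)
        for t in tissues:
            roi = by_role[t]
            ct = cnr(img, roi, muscle, noise,
                     pixel_mm=None if isinstance(img, ReconImage) else px)
            ci = cnr(iod, roi, muscle, noise, pixel_mm=px)
            if ct == 0:
                raise ZeroDivisionError(
                    f"total-energy CNR for '{t}' is zero; the gain ratio "
                    "is undefined"
                )
            cnr_t[t].append(ct)
            cnr_i[t].append(ci)
            gain[t].append(ci / ct)
    return CNRReport(tuple(tissues), cnr_t, cnr_i, gain,
                     n_replicates=len(total_images))


def hu_comparison(
    pcd_image,
    eid_image,
    rois: list[ROISpec],
    *,
    air_offset: bool = True,
):
    """Mean HU per ROI for both systems and their difference.

    Air ROIs are reported with the +1000 HU display offset convention
    when ``air_offset`` is set.
    """
    import pandas as pd

    rows = []
    for roi in rois:
        sp = roi_stats(pcd_image, roi)
        se = roi_stats(eid_image, roi)
        offset = 1000.0 if (air_offset and roi.role == "air") else 0.0
        rows.append({
            "roi": roi.label,
            "pcd_hu": sp.mean + offset,
            "eid_hu": se.mean + offset,
            "difference_hu": sp.mean - se.mean,
        })
    return pd.DataFrame(rows)


def bar_modulation(image, phantom: DigitalPhantom,
                   hu_bar: float | None = None,
                   hu_gap: float | None = None) -> float:
    """Resolved fraction of the bar-pattern contrast, in [0, ~1].

    (mean over bar-center pixels − mean over gap-center pixels) divided by
    the ideal bar−gap contrast.  1 means perfectly resolved; 0 means the
    pattern is washed out.  The ideal contrast defaults to the bone/air
    HU contrast measured on wide reference regions of the ground truth
    (≈ bone HU − air HU).
    """
    meta = phantom.meta
    if "bar_centers_mm" not in meta:
        raise ValueError("phantom does not describe a bar pattern")
    arr = _image_array(image)
    if isinstance(image, ReconImage):
        px = image.pixel_mm
    elif arr.shape[0] == phantom.grid_n:
        px = phantom.pixel_mm
    else:
        px = phantom.fov_mm / arr.shape[0]
    n = arr.shape[0]
    half = (n - 1) / 2.0
    y_half = meta["y_half_mm"]
    rows = np.where(np.abs((half - np.arange(n)) * px) <= y_half)[0]
    if rows.size == 0:
        raise ValueError("bar pattern lies outside the image")

    def col_mean(x_mm):
        col = x_mm / px + half
        c = int(round(col))
        if c < 0 or c >= n:
            raise ValueError("bar pattern lies outside the image")
        return arr[rows, c].mean()

    bar_mean = np.mean([col_mean(x) for x in meta["bar_centers_mm"]])
    gap_mean = np.mean([col_mean(x) for x in meta["gap_centers_mm"]])
    if hu_bar is None or hu_gap is None:
        # ideal contrast from the material HU endpoints at 70 keV: bar vs air
        from pcct.materials import get_material

        mu_w = get_material("water").linear_attenuation(70.0)
        mu_bar = get_material(
            meta.get("contrast_material", "cortical_bone")
        ).linear_attenuation(70.0)
        if hu_bar is None:
            hu_bar = 1000.0 * (mu_bar / mu_w - 1.0)
        if hu_gap is None:
            hu_gap = -1000.0
    ideal = hu_bar - hu_gap
    if ideal <= 0:
        raise ValueError("ideal bar-gap contrast must be positive")
    return float((bar_mean - gap_mean) / ideal)
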