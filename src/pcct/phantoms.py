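"""Digital 2-D phantoms with per-material volume-fraction maps.

Four phantom families mirror the experiments the simulator supports:

* an insert (multi-energy calibration) phantom — a water cylinder with
  cylindrical holes holding iodine and calcium solutions at several
  concentrations plus one water insert; its ROIs are the training source
  for the material-decomposition network;
* a brain phantom — elliptical skull, gray-matter ribbon, white-matter
  core, scalp muscle, optional iodinated vessels;
* a liver phantom — body ellipse with liver, a rim-enhanced tumor,
  an iodinated aorta, and back muscle (the CNR experiment);
* a bar phantom — alternating 0.5 mm bone/air bars emulating the
  sub-millimeter nasal-turbinate structures used to compare standard and
  high-resolution detector modes.

Solute concentrations are expressed in mg/mL of iodine or calcium in
water with linear partial-attenuation mixing: a concentration c maps to an
elemental volume fraction c / (1000 · density) and the water fraction is
reduced accordingly, so per-pixel fractions always sum to at most 1.

Coordinates: physical origin at the isocenter, x to the right, y toward
the anterior (image row 0); pixel centers at half-integer offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pcct.materials import get_material
from pcct.physics import linear_attenuation

__all__ = [
    "DigitalPhantom",
    "ROISpec",
    "make_insert_phantom",
    "make_brain_phantom",
    "make_liver_phantom",
    "make_bar_phantom",
]


@dataclass(frozen=True)
class ROISpec:
    """Circular region of interest (square patches for training extraction).

    ``role`` is one of tissue/muscle/noise/training-material plus the
    organ labels used by the liver pipeline (tumor, liver, aorta, air,
    brain, skull).
    """

    label: str
    center_mm: tuple
    radius_mm: float
    role: str = "tissue"
    material: str | None = None
    concentration_mg_ml: float | None = None


@dataclass(frozen=True)
class DigitalPhantom:
    """Per-material volume-fraction maps on a square grid."""

    name: str
    pixel_mm: float
    fractions: dict = field(repr=False)
    meta: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        shapes = {m.shape for m in self.fractions.values()}
        if len(shapes) > 1:
            raise ValueError("all fraction maps must share one grid")
        total = self.fraction_sum()
        if total.size and (total.max() > 1.0 + 1e-6 or total.min() < -1e-9):
            raise ValueError("per-pixel fractions must lie in [0, 1]")

    @property
    def grid_n(self) -> int:
        return next(iter(self.fractions.values())).shape[0]

    @property
    def fov_mm(self) -> float:
        return self.grid_n * self.pixel_mm

    def fraction_sum(self) -> np.ndarray:
        return sum(self.fractions.values())

    def coords_mm(self):
        """(x, y) physical coordinates of pixel centers (2-D arrays)."""
        n = self.grid_n
        c = (np.arange(n) - (n - 1) / 2.0) * self.pixel_mm
        x = c[None, :]
        y = -c[:, None]
        return np.broadcast_to(x, (n, n)), np.broadcast_to(y, (n, n))

    def mu_map(self, E: float) -> np.ndarray:
        """Ground-truth linear attenuation (cm^-1) at energy E."""
        mu = np.zeros((self.grid_n, self.grid_n))
        for name, frac in self.fractions.items():
            tab = get_material(name)
            mu += frac * tab.density_g_cm3 * tab.mass_attenuation(E)
        return mu


def _grid_coords(grid_n: int, pixel_mm: float):
    c = (np.arange(grid_n) - (grid_n - 1) / 2.0) * pixel_mm
    x = np.broadcast_to(c[None, :], (grid_n, grid_n))
    y = np.broadcast_to(-c[:, None], (grid_n, grid_n))
    return x, y


def _disc(x, y, cx, cy, r):
    return (x - cx) ** 2 + (y - cy) ** 2 <= r * r


def _ellipse(x, y, cx, cy, a, b):
    return ((x - cx) / a) ** 2 + ((y - cy) / b) ** 2 <= 1.0


def _solute_fraction(conc_mg_ml: float, material: str) -> float:
    return conc_mg_ml / 1000.0 / get_material(material).density_g_cm3


def _add_solution(fractions, region, host: str, solutes: dict):
    """Fill region with host liquid carrying dissolved solutes."""
    taken = 0.0
    for mat, conc in solutes.items():
        if conc <= 0:
            continue
        f = _solute_fraction(conc, mat)
        fractions.setdefault(mat, np.zeros(region.shape))[region] += f
        taken += f
    fractions.setdefault(host, np.zeros(region.shape))[region] = 1.0 - taken


def make_insert_phantom(
    iodine_concs=(2.0, 5.0, 10.0),
    calcium_concs=(50.0, 150.0, 300.0),
    body_radius_mm: float = 95.0,
    seed: int = 0,
    *,
    grid_n: int = 1250,
    fov_mm: float = 250.0,
    insert_radius_mm: float = 16.0,
    ring_radius_mm: float = 62.0,
    roi_radius_mm: float = 10.0,
):
    """Water cylinder with iodine/calcium/water inserts on a ring.

    Returns the phantom and one training ROI centered in each insert
    (iodine and calcium at each concentration, plus one water insert).
    """
    pixel_mm = fov_mm / grid_n
    x, y = _grid_coords(grid_n, pixel_mm)

    inserts = (
        [("iodine", c) for c in iodine_concs]
        + [("calcium", c) for c in calcium_concs]
        + [("water", 0.0)]
    )
    n = len(inserts)
    if n > 1:
        spacing = 2.0 * ring_radius_mm * np.sin(np.pi / n)
        if spacing < 2.0 * insert_radius_mm:
            raise ValueError(
                f"{n} inserts of radius {insert_radius_mm} mm overlap on a "
                f"{ring_radius_mm} mm ring"
            )
    if ring_radius_mm + insert_radius_mm > body_radius_mm:
        raise ValueError("insert ring extends beyond the phantom body")

    fractions = {"water": np.zeros((grid_n, grid_n))}
    body = _disc(x, y, 0.0, 0.0, body_radius_mm)
    fractions["water"][body] = 1.0

    rois = []
    angles = np.pi / 2.0 + 2.0 * np.pi * np.arange(n) / max(n, 1)
    for (mat, conc), ang in zip(inserts, angles):
        cx = ring_radius_mm * np.cos(ang)
        cy = ring_radius_mm * np.sin(ang)
        region = _disc(x, y, cx, cy, insert_radius_mm)
        if mat == "water":
            fractions["water"][region] = 1.0
            label = "water"
        else:
            _add_solution(fractions, region, "water", {mat: conc})
            label = f"{mat}_{conc:g}mgml"
        rois.append(ROISpec(label, (cx, cy), roi_radius_mm,
                            role="training-material", material=mat,
                            concentration_mg_ml=conc))
    phantom = DigitalPhantom(
        "insert", pixel_mm, fractions,
        meta={"seed": seed, "body_radius_mm": body_radius_mm,
              "insert_radius_mm": insert_radius_mm},
    )
    return phantom, rois


def make_brain_phantom(
    vessel_iodine_mg_ml: float = 4.0,
    *,
    grid_n: int = 1250,
    fov_mm: float = 250.0,
    seed: int = 0,
):
    """Elliptical head: scalp muscle, skull, gray ribbon, white core, vessels.

    Emits two tissue-training ROIs (one white matter, one gray matter) and
    the air/muscle/brain/skull metric ROIs used for system HU comparison.
    """
    pixel_mm = fov_mm / grid_n
    x, y = _grid_coords(grid_n, pixel_mm)
    zeros = np.zeros((grid_n, grid_n))
    fractions = {
        "muscle": zeros.copy(), "cortical_bone": zeros.copy(),
        "gray_matter": zeros.copy(), "white_matter": zeros.copy(),
        "water": zeros.copy(),
    }

    scalp = _ellipse(x, y, 0, 0, 82, 94)
    skull = _ellipse(x, y, 0, 0, 74, 86)
    brain = _ellipse(x, y, 0, 0, 68, 80)
    white = _ellipse(x, y, 0, 0, 40, 52)

    fractions["muscle"][scalp & ~skull] = 1.0
    fractions["cortical_bone"][skull & ~brain] = 1.0
    fractions["gray_matter"][brain & ~white] = 1.0
    fractions["white_matter"][white] = 1.0

    vessel_centers = [(-22.0, -20.0), (24.0, 18.0)]
    for cx, cy in vessel_centers:
        v = _disc(x, y, cx, cy, 5.0)
        for m in ("gray_matter", "white_matter"):
            fractions[m][v] = 0.0
        _add_solution(fractions, v, "water",
                      {"iodine": vessel_iodine_mg_ml})

    rois = [
        ROISpec("white_matter", (0.0, 0.0), 10.0,
                role="training-material", material="white_matter"),
        ROISpec("gray_matter", (54.0, 0.0), 6.0,
                role="training-material", material="gray_matter"),
        ROISpec("air", (-105.0, 0.0), 6.0, role="air"),
        ROISpec("muscle", (0.0, -90.0), 3.0, role="muscle"),
        ROISpec("brain", (0.0, 30.0), 8.0, role="brain"),
        ROISpec("skull", (0.0, -83.0), 2.0, role="skull"),
        ROISpec("vessel", vessel_centers[0], 3.0, role="vessel",
                material="iodine", concentration_mg_ml=vessel_iodine_mg_ml),
    ]
    phantom = DigitalPhantom("brain", pixel_mm, fractions,
                             meta={"seed": seed,
                                   "vessel_iodine_mg_ml": vessel_iodine_mg_ml})
    return phantom, rois


def make_liver_phantom(
    tumor_radius_mm: float = 18.0,
    rim_width_mm: float = 6.0,
    iodine_rim_mg_ml: float = 5.0,
    iodine_aorta_mg_ml: float = 10.0,
    seed: int = 0,
    *,
    grid_n: int = 1250,
    fov_mm: float = 250.0,
    iodine_liver_mg_ml: float = 1.0,
):
    """Abdomen with a rim-enhanced liver tumor, iodinated aorta, back muscle.

    The tumor rim carries the contrast agent (hypervascular margin); the
    core is unenhanced.  ROI roles: tumor (on the rim — the measurement
    targets the enhancing hotspot), liver, aorta, muscle, noise.
    """
    if rim_width_mm >= tumor_radius_mm:
        raise ValueError("rim width must be smaller than the tumor radius")
    pixel_mm = fov_mm / grid_n
    x, y = _grid_coords(grid_n, pixel_mm)
    zeros = np.zeros((grid_n, grid_n))
    fractions = {"soft_tissue": zeros.copy(), "muscle": zeros.copy(),
                 "water": zeros.copy()}

    body = _ellipse(x, y, 0, 0, 110, 80)
    fractions["soft_tissue"][body] = 1.0
    back = body & (y < -55.0)
    fractions["soft_tissue"][back] = 0.0
    fractions["muscle"][back] = 1.0

    liver_c, liver_r = (-45.0, 15.0), 45.0
    liver = _disc(x, y, *liver_c, liver_r)
    _add_solution(fractions, liver, "soft_tissue",
                  {"iodine": iodine_liver_mg_ml})

    tumor_c = (-50.0, 18.0)
    tumor = _disc(x, y, *tumor_c, tumor_radius_mm)
    core = _disc(x, y, *tumor_c, tumor_radius_mm - rim_width_mm)
    rim = tumor & ~core
    for m in ("soft_tissue", "iodine"):
        if m in fractions:
            fractions[m][tumor] = 0.0
    fractions["water"][core] = 1.0
    _add_solution(fractions, rim, "water", {"iodine": iodine_rim_mg_ml})

    aorta_c = (20.0, -35.0)
    aorta = _disc(x, y, *aorta_c, 9.0)
    for m in ("soft_tissue", "muscle", "iodine"):
        if m in fractions:
            fractions[m][aorta] = 0.0
    _add_solution(fractions, aorta, "water", {"iodine": iodine_aorta_mg_ml})

    rim_mid = tumor_radius_mm - rim_width_mm / 2.0
    rim_roi_c = (tumor_c[0] + rim_mid * np.cos(np.pi / 4),
                 tumor_c[1] + rim_mid * np.sin(np.pi / 4))
    rois = [
        ROISpec("tumor", rim_roi_c, min(rim_width_mm / 2.0 - 0.5, 2.5),
                role="tumor", material="iodine",
                concentration_mg_ml=iodine_rim_mg_ml),
        ROISpec("liver", (-20.0, -5.0), 6.0, role="liver"),
        ROISpec("aorta", aorta_c, 4.0, role="aorta", material="iodine",
                concentration_mg_ml=iodine_aorta_mg_ml),
        ROISpec("muscle", (0.0, -65.0), 6.0, role="muscle"),
        ROISpec("noise", (-30.0, 35.0), 8.0, role="noise"),
    ]
    phantom = DigitalPhantom(
        "liver", pixel_mm, fractions,
        meta={"seed": seed, "tumor_radius_mm": tumor_radius_mm,
              "rim_width_mm": rim_width_mm,
              "iodine_rim_mg_ml": iodine_rim_mg_ml,
              "iodine_aorta_mg_ml": iodine_aorta_mg_ml},
    )
    return phantom, rois


def make_bar_phantom(
    bar_width_mm: float = 0.5,
    n_bars: int = 8,
    contrast_material: str = "cortical_bone",
    *,
    grid_n: int = 640,
    fov_mm: float = 64.0,
    disc_radius_mm: float = 28.0,
):
    """Alternating bone/air bars of equal width inside a soft-tissue disc.

    The default 0.5 mm bar width matches the scale of the sub-millimeter
    anatomy (nasal turbinates) used to demonstrate high-resolution mode.
    The bar period is 2 × bar_width; bar/gap center positions are recorded
    in ``meta`` for the modulation metric.
    """
    pixel_mm = fov_mm / grid_n
    if bar_width_mm < pixel_mm:
        raise ValueError(
            f"bar width {bar_width_mm} mm is below the phantom pixel "
            f"{pixel_mm:g} mm"
        )
    x, y = _grid_coords(grid_n, pixel_mm)
    zeros = np.zeros((grid_n, grid_n))
    fractions = {"soft_tissue": zeros.copy(), contrast_material: zeros.copy()}
    disc = _disc(x, y, 0, 0, disc_radius_mm)
    fractions["soft_tissue"][disc] = 1.0

    period = 2.0 * bar_width_mm
    half_extent = n_bars * period / 2.0
    y_half = min(10.0, disc_radius_mm / 2.0)
    region = disc & (np.abs(y) <= y_half) & (np.abs(x) <= half_extent)
    bar_centers, gap_centers = [], []
    for i in range(n_bars):
        x0 = -half_extent + i * period
        bar = region & (x >= x0) & (x < x0 + bar_width_mm)
        fractions["soft_tissue"][bar] = 0.0
        fractions[contrast_material][bar] = 1.0
        gap = region & (x >= x0 + bar_width_mm) & (x < x0 + period)
        fractions["soft_tissue"][gap] = 0.0
        bar_centers.append(x0 + bar_width_mm / 2.0)
        gap_centers.append(x0 + 1.5 * bar_width_mm)
    meta = {
        "bar_width_mm": bar_width_mm,
        "bar_centers_mm": bar_centers,
        "gap_centers_mm": gap_centers,
        "y_half_mm": y_half * 0.8,
        "contrast_material": contrast_material,
        "region_x_mm": (-half_extent, half_extent),
    }
    return DigitalPhantom("bars", pixel_mm, fractions, meta=meta)
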