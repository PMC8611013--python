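"""Scanner geometry, energy bins, and detector configuration.

The scanner is a third-generation fan-beam system with a curved,
equiangular photon-counting detector: 48 modules of 80×48 pixels give a
native assembly of 80 rows × 2304 columns at 0.230 mm (in-plane) ×
0.190 mm (z) pitch.  The source-to-detector distance is not an
independently published number; it is fixed so that the 0.190 mm native z
pitch, binned 5×, magnifies to the published 0.640 mm slice thickness at
the isocenter: SDD = SID × (5 × 0.190) / 0.640 = 337.7 mm.  The same
geometry then yields a 0.128 mm effective z pixel in 1×1 high-resolution
mode.

The simulator itself is single-slice 2-D: detector rows enter only
through binning and slice accounting, and ray tracing uses one in-plane
fan.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "ScannerGeometry",
    "EnergyBinSet",
    "DetectorConfig",
    "effective_pixel_at_iso",
    "FULL_GEOMETRY",
    "REDUCED_GEOMETRY",
    "TINY_GEOMETRY",
]


@dataclass(frozen=True)
class ScannerGeometry:
    """Fan-beam geometry with a curved equiangular detector."""

    sid_mm: float = 227.5          # source to isocenter
    sdd_mm: float = 227.5 * 0.95 / 0.640   # source to detector (337.7 mm)
    n_views: int = 1440
    rotation_time_s: float = 2.0   # metadata only; the simulation is static
    n_cols: int = 2304             # native detector columns
    n_rows: int = 80               # native detector rows
    col_pitch_mm: float = 0.230    # in-plane
    row_pitch_mm: float = 0.190    # z
    fov_mm: float = 250.0
    cols_per_module: int = 48

    def __post_init__(self):
        if self.sdd_mm <= self.sid_mm:
            raise ValueError("source-to-detector must exceed source-to-isocenter")
        if self.n_cols % self.cols_per_module:
            raise ValueError("columns must be a whole number of modules")
        # the fan must cover the field of view
        half_fan = 0.5 * self.n_cols * self.delta_gamma
        if self.sid_mm * np.sin(half_fan) < 0.5 * self.fov_mm:
            raise ValueError("detector fan does not cover the field of view")

    @property
    def delta_gamma(self) -> float:
        """Angular pitch of one native column (rad)."""
        return self.col_pitch_mm / self.sdd_mm

    @property
    def n_modules(self) -> int:
        return self.n_cols // self.cols_per_module

    @property
    def channels_per_module(self) -> int:
        return self.n_rows * self.cols_per_module

    def gamma_of_cols(self, n_cols: int, col_binning: int = 1) -> np.ndarray:
        """Fan angles of (possibly binned) column centers, rad."""
        pitch = self.delta_gamma * col_binning
        return (np.arange(n_cols) - (n_cols - 1) / 2.0) * pitch

    def view_angles(self) -> np.ndarray:
        return 2.0 * np.pi * np.arange(self.n_views) / self.n_views


@dataclass(frozen=True)
class EnergyBinSet:
    """Ascending photon-energy thresholds; bins live between them."""

    thresholds_keV: tuple = (30.0, 50.0, 65.0, 140.0)

    def __post_init__(self):
        t = tuple(float(x) for x in self.thresholds_keV)
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("thresholds must be strictly ascending")
        if t[0] < 20.0:
            raise ValueError("lowest threshold must be at least 20 keV")
        object.__setattr__(self, "thresholds_keV", t)

    @property
    def n_bins(self) -> int:
        return len(self.thresholds_keV) - 1

    @property
    def edges(self) -> list[tuple[float, float]]:
        t = self.thresholds_keV
        return list(zip(t[:-1], t[1:]))

    @property
    def total_range(self) -> tuple[float, float]:
        return self.thresholds_keV[0], self.thresholds_keV[-1]


@dataclass(frozen=True)
class DetectorConfig:
    """Counting-chain configuration: counters, binning mode, energy response."""

    bit_depths: tuple = (14, 13, 12)
    binning_mode: str = "standard"        # "standard" (5x6) or "hr" (1x1)
    row_binning: int = 5
    col_binning: int = 6
    energy_sigma_keV: float = 4.0         # Gaussian energy response
    threshold_gain: float = 1.0           # keV per DAC unit (calibration sim)
    threshold_offset_keV: float = 0.0

    def __post_init__(self):
        if any(b <= 0 for b in self.bit_depths):
            raise ValueError("counter bit depths must be positive")
        if self.binning_mode not in ("standard", "hr"):
            raise ValueError(f"unknown binning mode '{self.binning_mode}'")

    @property
    def binning_factors(self) -> tuple[int, int]:
        """(rows, cols) summed per binned pixel in the active mode."""
        if self.binning_mode == "hr":
            return (1, 1)
        return (self.row_binning, self.col_binning)

    @property
    def saturation(self) -> np.ndarray:
        """Per-bin counter saturation, 2^bits - 1."""
        return np.array([2 ** b - 1 for b in self.bit_depths], dtype=np.int64)

    def with_mode(self, mode: str) -> "DetectorConfig":
        return replace(self, binning_mode=mode)


def effective_pixel_at_iso(
    geometry: ScannerGeometry, det: DetectorConfig, axis: str = "z"
) -> float:
    """Effective detector pixel size projected to the isocenter, mm.

    native pitch × binning factor × (SID / SDD).  With the default
    geometry, standard (5×6) mode gives 0.640 mm in z and high-resolution
    (1×1) mode gives 0.128 mm.
    """
    mag = geometry.sid_mm / geometry.sdd_mm
    rows, cols = det.binning_factors
    if axis == "z":
        return geometry.row_pitch_mm * rows * mag
    if axis in ("inplane", "in-plane"):
        return geometry.col_pitch_mm * cols * mag
    raise ValueError("axis must be 'z' or 'in-plane'")


#: published full-scale geometry
FULL_GEOMETRY = ScannerGeometry()

#: reduced geometry for desk-scale runs: one third the columns at 3x the
#: pitch (same fan coverage), half the views
REDUCED_GEOMETRY = ScannerGeometry(
    n_views=720, n_cols=768, col_pitch_mm=0.230 * 3, cols_per_module=48
)

#: minimal geometry for fast unit tests: one sixth the columns at 6x pitch
TINY_GEOMETRY = ScannerGeometry(
    n_views=240, n_cols=384, col_pitch_mm=0.230 * 6, cols_per_module=48
)
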