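"""Energy grid, tube spectrum model, mixture attenuation, and HU conversion.

The tube output is an analytic bremsstrahlung (Kramers-type) spectrum,
fluence ∝ E·(kVp − E), hardened by inherent filtration via Beer–Lambert.
The spectrum is discretised on a uniform 1 keV grid and scaled linearly
with exposure (mAs); absolute fluence is expressed as photons per detector
column per view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from pcct.materials import AttenuationTable, get_material

__all__ = [
    "EnergyGrid",
    "TubeSpectrum",
    "mass_attenuation",
    "linear_attenuation",
    "kedge_energy",
    "generate_tube_spectrum",
    "hu_from_mu",
    "mu_from_hu",
    "spectrum_to_csv",
    "spectrum_from_csv",
]

#: diagnostic range within which K-edges are considered usable landmarks
KEDGE_WINDOW_KEV = (30.0, 140.0)


@dataclass(frozen=True)
class EnergyGrid:
    """Uniform 1 keV energy grid over [lo, hi]."""

    lo_keV: float = 20.0
    hi_keV: float = 140.0
    spacing_keV: float = 1.0

    def __post_init__(self):
        if self.lo_keV < 1.0:
            raise ValueError("energy grid must start at or above 1 keV")
        if self.hi_keV <= self.lo_keV:
            raise ValueError("energy grid upper bound must exceed lower bound")

    @property
    def energies(self) -> np.ndarray:
        n = int(round((self.hi_keV - self.lo_keV) / self.spacing_keV)) + 1
        return self.lo_keV + self.spacing_keV * np.arange(n)


@dataclass(frozen=True)
class TubeSpectrum:
    """Discretised polychromatic tube output.

    ``fluence`` is photons·keV⁻¹ per ray (native detector column, one view)
    at the stated exposure; it is zero above the tube potential and scales
    linearly with mAs.
    """

    kVp: float
    energies_keV: np.ndarray = field(repr=False)
    fluence: np.ndarray = field(repr=False)
    mAs: float = 1.0

    def __post_init__(self):
        E = np.asarray(self.energies_keV, dtype=float)
        f = np.asarray(self.fluence, dtype=float)
        if E.shape != f.shape:
            raise ValueError("energies and fluence must have matching shape")
        if np.any(f < 0):
            raise ValueError("fluence must be nonnegative")
        if np.any(f[E > self.kVp] > 0):
            raise ValueError("fluence must vanish above the tube potential")
        object.__setattr__(self, "energies_keV", E)
        object.__setattr__(self, "fluence", f)

    def scaled(self, mAs: float) -> "TubeSpectrum":
        """Same spectral shape at a different exposure."""
        return TubeSpectrum(self.kVp, self.energies_keV,
                            self.fluence * (mAs / self.mAs), mAs)

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())


def mass_attenuation(material: AttenuationTable | str, E) -> float | np.ndarray:
    """mu/rho (cm^2/g) at E keV; on-edge queries take the right limit."""
    if isinstance(material, str):
        material = get_material(material)
    return material.mass_attenuation(E)


def linear_attenuation(fractions: dict, E) -> float | np.ndarray:
    """Linear attenuation (cm^-1) of a volume-fraction mixture.

    mu(E) = sum_m fraction_m * density_m * (mu/rho)_m(E).  Fractions must be
    nonnegative and sum to at most 1; the remainder is vacuum.
    """
    total = 0.0
    for frac in fractions.values():
        if frac < 0:
            raise ValueError("volume fractions must be nonnegative")
        total += frac
    if total > 1.0 + 1e-9:
        raise ValueError(f"volume fractions sum to {total:g} > 1")
    mu = 0.0
    for name, frac in fractions.items():
        tab = get_material(name) if isinstance(name, str) else name
        mu = mu + frac * tab.density_g_cm3 * tab.mass_attenuation(E)
    return mu


def kedge_energy(material: AttenuationTable | str) -> float | None:
    """Lowest K-edge within the diagnostic window, or None."""
    if isinstance(material, str):
        material = get_material(material)
    lo, hi = KEDGE_WINDOW_KEV
    for k in material.kedges_keV:
        if lo <= k <= hi:
            return k
    return None


def generate_tube_spectrum(
    kVp: float = 140.0,
    filtration: tuple = (("aluminium", 2.5),),
    mAs: float = 1.0,
    *,
    grid: EnergyGrid | None = None,
    photons_per_mAs: float = 600.0,
) -> TubeSpectrum:
    """Kramers-type bremsstrahlung spectrum with Beer–Lambert filtration.

    Parameters
    ----------
    kVp : tube potential, keV (must be in [40, 150]).
    filtration : iterable of (material name, thickness mm).
    mAs : exposure; fluence scales linearly.
    grid : energy grid; defaults to 1 keV steps over [20, kVp].
    photons_per_mAs : total filtered photons per ray per mAs; sets the
        absolute dose scale of the simulator.
    """
    if not (40.0 <= kVp <= 150.0):
        raise ValueError(f"kVp {kVp:g} outside supported range [40, 150]")
    if grid is None:
        grid = EnergyGrid(20.0, kVp)
    E = grid.energies
    raw = np.clip(E * (kVp - E), 0.0, None)
    atten = np.zeros_like(E)
    for name, thickness_mm in filtration:
        if thickness_mm < 0:
            raise ValueError(f"negative filtration thickness for {name}")
        tab = get_material(name)
        atten += tab.density_g_cm3 * tab.mass_attenuation(E) * (thickness_mm / 10.0)
    fluence = raw * np.exp(-atten)
    s = fluence.sum()
    if s > 0:
        fluence *= photons_per_mAs * mAs / s
    return TubeSpectrum(kVp, E, fluence, mAs)


def hu_from_mu(mu_image, mu_water_eff: float):
    """HU = 1000·(mu − mu_water)/mu_water, elementwise."""
    if mu_water_eff <= 0:
        raise ValueError("effective water attenuation must be positive")
    return 1000.0 * (np.asarray(mu_image, dtype=float) - mu_water_eff) / mu_water_eff


def mu_from_hu(hu_image, mu_water_eff: float):
    """Inverse of :func:`hu_from_mu`."""
    if mu_water_eff <= 0:
        raise ValueError("effective water attenuation must be positive")
    return mu_water_eff * (1.0 + np.asarray(hu_image, dtype=float) / 1000.0)


def spectrum_to_csv(spec: TubeSpectrum, path) -> None:
    np.savetxt(path, np.column_stack([spec.energies_keV, spec.fluence]),
               delimiter=",", header="keV,fluence", comments="")


def spectrum_from_csv(path, kVp: float, mAs: float = 1.0) -> TubeSpectrum:
    arr = np.loadtxt(path, delimiter=",", skiprows=1)
    return TubeSpectrum(kVp, arr[:, 0], arr[:, 1], mAs)
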