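"""Material attenuation tables with explicit K-edge discontinuities.

Each material carries a density and one or more log-log sampled segments of
the mass attenuation coefficient mu/rho (cm^2/g).  Segment boundaries sit at
K-edges, where photoelectric absorption jumps discontinuously; interpolation
never bridges a segment boundary, so the discontinuity is preserved exactly.

The built-in tables are compact (8-12 samples per segment) renderings of the
standard published photon cross-section shapes for each element or mixture
over the diagnostic range 20-150 keV.  The two K-edge energies that matter
for threshold calibration — gadolinium at 50.2 keV and tungsten at
69.5 keV — anchor the energy scale of the whole simulator.

White and gray matter are modelled as water-based tissues: a small density
offset plus a configurable low-energy "photoelectric tilt" standing in for a
difference in effective atomic number, so that the three energy bins carry
separable white/gray signal.  The tilt magnitude is a phantom parameter, not
a physical claim.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AttenuationTable",
    "get_material",
    "material_names",
    "register_material",
    "table_to_json",
    "table_from_json",
    "make_tilted_water_tissue",
]


@dataclass(frozen=True)
class AttenuationTable:
    """Energy-dependent mass attenuation for one material.

    Parameters
    ----------
    name : str
        Material identifier.
    density_g_cm3 : float
        Bulk density in g/cm^3.
    segments : tuple of (ndarray, ndarray)
        ``(E_keV, mu_rho_cm2_g)`` sample pairs; each segment spans the open
        interval between consecutive K-edges and is interpolated log-log.
    kedges_keV : tuple of float
        Energies where the table is discontinuous (ascending).
    """

    name: str
    density_g_cm3: float
    segments: tuple = field(repr=False, default=())
    kedges_keV: tuple = ()

    def __post_init__(self):
        segs = []
        for E, mr in self.segments:
            E = np.asarray(E, dtype=float)
            mr = np.asarray(mr, dtype=float)
            if E.ndim != 1 or E.shape != mr.shape:
                raise ValueError(f"{self.name}: malformed segment arrays")
            if np.any(np.diff(E) <= 0):
                raise ValueError(f"{self.name}: segment energies not increasing")
            if np.any(mr <= 0):
                raise ValueError(f"{self.name}: mu/rho must be positive")
            segs.append((E, mr))
        object.__setattr__(self, "segments", tuple(segs))
        object.__setattr__(self, "kedges_keV", tuple(float(k) for k in self.kedges_keV))

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.segments[0][0][0]), float(self.segments[-1][0][-1])

    def _segment_for(self, E: float):
        """Segment containing E; on-edge queries take the right limit."""
        for i, (Es, _) in enumerate(self.segments):
            lo = Es[0]
            hi = Es[-1]
            # right-continuity: an energy exactly at a K-edge belongs to the
            # segment that starts there
            if (lo <= E <= hi) and not (
                i + 1 < len(self.segments) and E >= self.segments[i + 1][0][0]
            ):
                return self.segments[i]
        raise ValueError(
            f"energy {E:g} keV outside table range "
            f"[{self.energy_range[0]:g}, {self.energy_range[1]:g}] keV "
            f"for material '{self.name}'"
        )

    def mass_attenuation(self, E):
        """mu/rho (cm^2/g) at energy E (keV); scalar or array.

        Log-log interpolation within a segment; interpolation never bridges
        a K-edge, and an on-edge query returns the right (above-edge) limit.
        """
        E_arr = np.atleast_1d(np.asarray(E, dtype=float))
        lo, hi = self.energy_range
        if np.any(E_arr < lo) or np.any(E_arr > hi):
            raise ValueError(
                f"energy outside table range [{lo:g}, {hi:g}] keV "
                f"for material '{self.name}'"
            )
        out = np.empty_like(E_arr)
        # assign each query to its segment (right-continuous at edges)
        starts = np.array([s[0][0] for s in self.segments])
        idx = np.searchsorted(starts, E_arr, side="right") - 1
        idx = np.clip(idx, 0, len(self.segments) - 1)
        for i, (Es, mr) in enumerate(self.segments):
            sel = idx == i
            if not np.any(sel):
                continue
            out[sel] = np.exp(
                np.interp(np.log(E_arr[sel]), np.log(Es), np.log(mr))
            )
        return out if np.ndim(E) else float(out[0])

    def linear_attenuation(self, E):
        """mu (cm^-1) of the bulk material at energy E."""
        return self.density_g_cm3 * self.mass_attenuation(E)


# ---------------------------------------------------------------------------
# Built-in tables.  mu/rho in cm^2/g at the listed keV.  Shapes follow the
# standard published photon cross sections; segments split at K-edges.
# ---------------------------------------------------------------------------

_E_COMMON = [20.0, 30.0, 40.0, 50.0, 60.0, 80.0, 100.0, 120.0, 150.0]

_BUILTIN: dict[str, AttenuationTable] = {}


def register_material(table: AttenuationTable) -> AttenuationTable:
    _BUILTIN[table.name] = table
    return table


def _simple(name, density, mu_rho, energies=_E_COMMON):
    return register_material(
        AttenuationTable(name, density, segments=((energies, mu_rho),))
    )


_simple("water", 1.000,
        [0.8096, 0.3756, 0.2683, 0.2269, 0.2059, 0.1837, 0.1707, 0.1614, 0.1505])
_simple("air", 0.0012,
        [0.7779, 0.3538, 0.2485, 0.2080, 0.1875, 0.1662, 0.1541, 0.1456, 0.1356])
_simple("aluminium", 2.699,
        [3.441, 1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1536, 0.1378])
_simple("soft_tissue", 1.060,
        [0.8210, 0.3780, 0.2685, 0.2262, 0.2048, 0.1823, 0.1693, 0.1600, 0.1492])
_simple("muscle", 1.050,
        [0.8205, 0.3783, 0.2687, 0.2264, 0.2048, 0.1824, 0.1693, 0.1600, 0.1492])
_simple("cortical_bone", 1.920,
        [4.001, 1.331, 0.6655, 0.4242, 0.3148, 0.2229, 0.1855, 0.1686, 0.1480])
_simple("calcium", 1.550,
        [6.621, 2.192, 1.019, 0.6578, 0.4857, 0.3656, 0.3116, 0.2762, 0.2208])

# vacuum pseudo-material: attenuates nothing (tiny positive mu/rho to keep
# the positivity invariant; density zero makes linear attenuation exactly 0)
register_material(
    AttenuationTable("vacuum", 0.0, segments=(([20.0, 150.0], [1e-12, 1e-12]),))
)

# Iodine, K-edge 33.17 keV
register_material(AttenuationTable(
    "iodine", 4.930,
    segments=(
        ([20.0, 25.0, 30.0, 33.17], [25.43, 14.16, 8.561, 6.553]),
        ([33.17, 40.0, 50.0, 60.0, 80.0, 100.0, 120.0, 150.0],
         [35.82, 22.10, 12.32, 7.579, 3.510, 1.942, 1.247, 0.7100]),
    ),
    kedges_keV=(33.17,),
))

# Gadolinium, K-edge 50.2 keV (the energy-calibration anchor)
register_material(AttenuationTable(
    "gadolinium", 7.900,
    segments=(
        ([20.0, 25.0, 30.0, 40.0, 50.2], [13.50, 7.506, 4.820, 2.800, 2.500]),
        ([50.2, 60.0, 80.0, 100.0, 120.0, 150.0],
         [12.60, 7.881, 3.600, 2.000, 1.270, 0.7400]),
    ),
    kedges_keV=(50.2,),
))

# Tungsten, K-edge 69.5 keV (the second calibration anchor)
register_material(AttenuationTable(
    "tungsten", 19.30,
    segments=(
        ([20.0, 30.0, 40.0, 50.0, 60.0, 69.5],
         [65.73, 22.73, 10.67, 5.949, 3.713, 2.552]),
        ([69.5, 80.0, 100.0, 120.0, 150.0],
         [11.23, 7.810, 4.438, 2.766, 1.581]),
    ),
    kedges_keV=(69.5,),
))


def make_tilted_water_tissue(
    name: str,
    density_offset: float,
    tilt: float,
    *,
    ref_keV: float = 70.0,
) -> AttenuationTable:
    """Water-based tissue with a density offset and a photoelectric tilt.

    The mass attenuation is water's, scaled by
    ``1 + tilt * ((30/E)^3 - (30/ref)^3)`` so the factor is 1 at ``ref_keV``
    and the low-energy bins gain (tilt > 0) or lose (tilt < 0) attenuation —
    a minimal stand-in for an effective-atomic-number difference.
    """
    water = _BUILTIN["water"]
    Es, mr = water.segments[0]
    factor = 1.0 + tilt * ((30.0 / Es) ** 3 - (30.0 / ref_keV) ** 3)
    return AttenuationTable(
        name, 1.0 + density_offset, segments=((Es, mr * factor),)
    )


# defaults: gray +0.5% density / positive tilt, white -0.5% / negative tilt.
# The tilt magnitude is calibrated so the white/gray pair is separable in
# the three-bin data at the full imaging dose — a demonstration parameter,
# not a tissue property claim.
register_material(make_tilted_water_tissue("gray_matter", +0.005, +0.12))
register_material(make_tilted_water_tissue("white_matter", -0.005, -0.12))


def get_material(name: str) -> AttenuationTable:
    try:
        return _BUILTIN[name]
    except KeyError:
        raise KeyError(
            f"unknown material '{name}'; known: {sorted(_BUILTIN)}"
        ) from None


def material_names() -> list[str]:
    return sorted(_BUILTIN)


# ---------------------------------------------------------------------------
# Plain-JSON serialization
# ---------------------------------------------------------------------------

def table_to_json(table: AttenuationTable) -> str:
    return json.dumps({
        "name": table.name,
        "density_g_cm3": table.density_g_cm3,
        "segments": [
            {"E_keV": list(map(float, E)), "mu_rho_cm2_g": list(map(float, mr))}
            for E, mr in table.segments
        ],
        "kedges_keV": list(table.kedges_keV),
    }, indent=1)


def table_from_json(text: str) -> AttenuationTable:
    d = json.loads(text)
    return AttenuationTable(
        d["name"],
        float(d["density_g_cm3"]),
        segments=tuple(
            (s["E_keV"], s["mu_rho_cm2_g"]) for s in d["segments"]
        ),
        kedges_keV=tuple(d.get("kedges_keV", ())),
    )
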