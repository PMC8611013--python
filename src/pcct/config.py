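"""Run configuration: YAML in, validated RunProfile + phantom spec out.

A run config is a nested mapping with optional blocks ``geometry``,
``spectrum``, ``bins``, ``detector``, ``recon``, ``phantom``, ``training``
and a ``seed``.  Unknown keys and out-of-range values are reported
together as a :class:`ConfigError` listing every offending field.  Every
pipeline command writes its fully resolved configuration next to its
outputs so any run can be reproduced exactly.
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from pcct.decomposition import TrainingConfig
from pcct.geometry import (
    FULL_GEOMETRY,
    REDUCED_GEOMETRY,
    DetectorConfig,
    EnergyBinSet,
)
from pcct.pipeline import RunProfile

__all__ = ["ConfigError", "load_config", "resolve_profile", "dump_config"]

_GEOMETRY_PRESETS = {"reduced": REDUCED_GEOMETRY, "full": FULL_GEOMETRY}

_KNOWN_BLOCKS = {"geometry", "spectrum", "bins", "detector", "recon",
                 "phantom", "training", "seed", "out_dir"}

_PHANTOMS = {"insert", "brain", "liver", "bars"}


class ConfigError(ValueError):
    """Invalid run configuration; message lists the offending fields."""


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def resolve_profile(cfg: dict) -> tuple[RunProfile, dict]:
    """Validate a config mapping and build the RunProfile.

    Returns (profile, resolved config dict).  The resolved dict contains
    every default filled in, suitable for re-running the same pipeline.
    """
    errors = []
    for key in cfg:
        if key not in _KNOWN_BLOCKS:
            errors.append(f"unknown top-level key '{key}'")

    geo_cfg = dict(cfg.get("geometry") or {})
    preset = geo_cfg.pop("preset", "reduced")
    if preset not in _GEOMETRY_PRESETS:
        errors.append(f"geometry.preset must be one of {sorted(_GEOMETRY_PRESETS)}")
        preset = "reduced"
    geometry = _GEOMETRY_PRESETS[preset]
    try:
        if geo_cfg:
            geometry = replace(geometry, **geo_cfg)
    except (TypeError, ValueError) as exc:
        errors.append(f"geometry: {exc}")

    spec_cfg = dict(cfg.get("spectrum") or {})
    kVp = float(spec_cfg.get("kvp", 140.0))
    mAs = float(spec_cfg.get("mas", 10.0))
    filtration = tuple(
        (str(m), float(t)) for m, t in spec_cfg.get(
            "filtration", [["aluminium", 2.5]])
    )
    photons = float(spec_cfg.get("photons_per_mas", 600.0))
    if not (40.0 <= kVp <= 150.0):
        errors.append("spectrum.kvp must lie in [40, 150]")
    if mAs <= 0:
        errors.append("spectrum.mas must be positive")

    bins_cfg = cfg.get("bins") or {}
    try:
        bins = EnergyBinSet(tuple(bins_cfg.get(
            "thresholds_kev", (30.0, 50.0, 65.0, 140.0))))
    except ValueError as exc:
        errors.append(f"bins: {exc}")
        bins = EnergyBinSet()

    det_cfg = dict(cfg.get("detector") or {})
    try:
        det = DetectorConfig(
            bit_depths=tuple(det_cfg.get("bit_depths", (14, 13, 12))),
            binning_mode=det_cfg.get("binning_mode", "standard"),
            energy_sigma_keV=float(det_cfg.get("energy_sigma_kev", 4.0)),
        )
    except ValueError as exc:
        errors.append(f"detector: {exc}")
        det = DetectorConfig()

    recon_cfg = cfg.get("recon") or {}
    recon_n = int(recon_cfg.get("grid", 313 if preset == "reduced" else 625))
    filter_name = recon_cfg.get("filter", "ram-lak")
    if filter_name not in ("ram-lak", "hann"):
        errors.append("recon.filter must be 'ram-lak' or 'hann'")
    if recon_n < 16:
        errors.append("recon.grid must be at least 16")

    tr_cfg = cfg.get("training") or {}
    try:
        training = TrainingConfig(
            learning_rate=float(tr_cfg.get("learning_rate", 0.00005)),
            epochs=int(tr_cfg.get("epochs", 4500)),
            seed=int(tr_cfg.get("seed", 0)),
            hidden_width=int(tr_cfg.get("hidden_width", 16)),
            optimizer=tr_cfg.get("optimizer", "adam"),
        )
    except ValueError as exc:
        errors.append(f"training: {exc}")
        training = TrainingConfig(hidden_width=16)

    ph_cfg = dict(cfg.get("phantom") or {"name": "insert"})
    if ph_cfg.get("name", "insert") not in _PHANTOMS:
        errors.append(f"phantom.name must be one of {sorted(_PHANTOMS)}")

    if errors:
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(errors))

    profile = RunProfile(
        geometry=geometry, bins=bins, det=det, recon_n=recon_n,
        kVp=kVp, mAs=mAs, filtration=filtration, photons_per_mAs=photons,
        filter_name=filter_name, training=training,
    )
    resolved = {
        "geometry": {"preset": preset,
                     "n_views": geometry.n_views,
                     "n_cols": geometry.n_cols,
                     "sid_mm": geometry.sid_mm,
                     "sdd_mm": geometry.sdd_mm,
                     "col_pitch_mm": geometry.col_pitch_mm,
                     "fov_mm": geometry.fov_mm},
        "spectrum": {"kvp": kVp, "mas": mAs,
                     "filtration": [list(f) for f in filtration],
                     "photons_per_mas": photons},
        "bins": {"thresholds_kev": list(bins.thresholds_keV)},
        "detector": {"bit_depths": list(det.bit_depths),
                     "binning_mode": det.binning_mode,
                     "energy_sigma_kev": det.energy_sigma_keV},
        "recon": {"grid": recon_n, "filter": filter_name},
        "training": {"learning_rate": training.learning_rate,
                     "epochs": training.epochs,
                     "seed": training.seed,
                     "hidden_width": training.hidden_width,
                     "optimizer": training.optimizer},
        "phantom": ph_cfg,
        "seed": int(cfg.get("seed", 0)),
    }
    return profile, resolved


def dump_config(resolved: dict, path) -> None:
    """Atomic write of the resolved config (temp file + rename)."""
    import os

    tmp = str(path) + ".tmp"
    with open(tmp, "w") as f:
        yaml.safe_dump(resolved, f, sort_keys=False)
    os.replace(tmp, path)
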