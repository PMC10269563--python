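"""Configuration, measurement I/O and run manifests.

Measurements arrive as long-format CSV (variable, time_h, value, unit)
with per-variable sampling grids; units are converted to the internal
mM / gDW-per-L convention through a shipped molar-mass table.  Every run
can write a manifest (config hash, seed, package version) sufficient to
reproduce it.
"""

from __future__ import annotations

import functools
import hashlib
import importlib.metadata
import importlib.resources
import json
from pathlib import Path

import pandas as pd
import yaml

from .estimation import MeasurementSet


class UnitError(ValueError):
    pass


@functools.lru_cache(maxsize=1)
def molar_masses() -> dict:
    path = importlib.resources.files("ferment_dfba").joinpath(
        "data").joinpath("molar_masses.csv")
    df = pd.read_csv(path)
    return dict(zip(df["variable"], df["g_per_mol"]))


def to_millimolar(variable: str, value: float, unit: str) -> float:
    """Convert a measurement to mM (or gDW/L for biomass dry weight)."""
    unit = unit.strip()
    if unit in ("mM", "mmol/L"):
        return value
    if unit in ("gDW/L", "g_dw/L"):
        return value
    masses = molar_masses()
    if unit == "g/L":
        if variable not in masses:
            raise UnitError(f"no molar mass on record for {variable}")
        return value / masses[variable] * 1000.0
    if unit == "mg/L":
        if variable not in masses:
            raise UnitError(f"no molar mass on record for {variable}")
        return value / masses[variable]
    raise UnitError(f"unknown unit {unit!r} for {variable}")


def read_measurements(path, t_end=None) -> MeasurementSet:
    """Load a long-format measurement CSV into internal units.

    Duplicated (variable, time) rows are kept as replicate observations.
    Negative values abort with the offending row number.
    """
    df = pd.read_csv(path)
    required = {"variable", "time_h", "value", "unit"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    if len(df) == 0:
        raise ValueError(f"{path}: no records")
    neg = df.index[df["value"] < 0]
    if len(neg):
        raise ValueError(f"{path}: negative value in row {int(neg[0]) + 2}")
    df = df.assign(value=[to_millimolar(v, x, u) for v, x, u in
                          zip(df["variable"], df["value"], df["unit"])])
    return MeasurementSet(df[["variable", "time_h", "value"]], t_end=t_end)


def write_measurements(df: pd.DataFrame, path) -> None:
    out = df.copy()
    if "unit" not in out.columns:
        out["unit"] = ["gDW/L" if v == "DW" else "mM"
                       for v in out["variable"]]
    out.to_csv(path, index=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config: dict, seed=None, extras=None) -> dict:
    try:
        version = importlib.metadata.version("ferment-dfba")
    except importlib.metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    manifest = {"config_hash": config_hash(config), "seed": seed,
                "package_version": version}
    manifest.update(extras or {})
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def write_trajectory(traj, state_path, flux_path=None) -> None:
    traj.to_frame().to_csv(state_path, index=False)
    if flux_path is not None and traj.fluxes is not None:
        traj.flux_frame().to_csv(flux_path, index=False)
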