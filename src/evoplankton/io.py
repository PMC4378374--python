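"""Serialization: NetCDF state/forcing snapshots and tidy CSV tables.

NetCDF files are written through xarray's scipy backend (NetCDF-3
classic format), readable by any NetCDF tool.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .column import ColumnGrid, ColumnState, SeasonalForcing
from .diagnostics import FitnessLandscape

__all__ = [
    "forcing_to_dataset", "state_to_dataset", "save_dataset", "open_dataset",
    "landscape_to_dataset", "run_manifest",
]

_ENGINE = "scipy"


def forcing_to_dataset(forcing: SeasonalForcing, grid: ColumnGrid) -> xr.Dataset:
    """Seasonal forcing as (day-of-year x depth) arrays."""
    day = np.arange(forcing.irradiance.shape[0])
    iface = np.cumsum(grid.thickness)[:-1]
    return xr.Dataset(
        {
            "surface_irradiance": ("day", forcing.irradiance),
            "temperature": (("day", "depth"), forcing.temperature),
            "diffusivity": (("day", "interface"), forcing.kappa),
            "mixed_layer_depth": ("day", forcing.mld),
        },
        coords={"day": day, "depth": grid.mid, "interface": iface},
        attrs={"depth_units": "m", "irradiance_units": "W m-2",
               "diffusivity_units": "m2 d-1"})


def state_to_dataset(state: ColumnState, grid: ColumnGrid,
                     species_ids: list[str], zoo_ids: list[str]) -> xr.Dataset:
    """One state snapshot as a depth-resolved dataset."""
    from .foodweb import DET_NAMES, NUT_NAMES
    tracer = ["C", "N", "Chl"]
    return xr.Dataset(
        {
            "nutrients": (("depth", "nutrient"), state.nut),
            "detritus": (("depth", "det_pool"), state.det),
            "phyto": (("depth", "species", "tracer"), state.phy),
            "zoo": (("depth", "zoo_species", "tracer"), state.zoo),
        },
        coords={
            "depth": grid.mid,
            "nutrient": list(NUT_NAMES),
            "det_pool": list(DET_NAMES),
            "species": species_ids,
            "zoo_species": zoo_ids,
            "tracer": tracer,
        },
        attrs={"time_days": state.time, "concentration_units": "mmol m-3"})


def landscape_to_dataset(landscape: FitnessLandscape) -> xr.Dataset:
    """Fitness landscape as (type x probe) arrays."""
    types = list(landscape.volumes)
    n = max(len(v) for v in landscape.volumes.values())
    vols = np.full((len(types), n), np.nan)
    fit = np.full((len(types), n), np.nan)
    for i, t in enumerate(types):
        vols[i, : len(landscape.volumes[t])] = landscape.volumes[t]
        fit[i, : len(landscape.fitness[t])] = landscape.fitness[t]
    return xr.Dataset(
        {"probe_volume": (("ftype", "probe"), vols),
         "invasion_fitness": (("ftype", "probe"), fit)},
        coords={"ftype": types, "probe": np.arange(n)})


def trajectory_to_dataset(record) -> xr.Dataset:
    """Trait trajectories of an evolution record as (cycle x species)."""
    df = record.trait_trajectory()
    wide = df.pivot(index="cycle", columns="species", values="volume")
    return xr.Dataset(
        {"volume": (("cycle", "species"), wide.values)},
        coords={"cycle": wide.index.values,
                "species": list(wide.columns)},
        attrs={"volume_units": "um3", "cycle_length_years": 3})


def save_dataset(ds: xr.Dataset, path: str | Path) -> None:
    ds.to_netcdf(path, engine=_ENGINE)


def open_dataset(path: str | Path) -> xr.Dataset:
    return xr.open_dataset(path, engine=_ENGINE)


def run_manifest(params: dict, seed: int, path: str | Path) -> None:
    """JSON manifest of a run: full configuration plus the RNG seed."""
    import evoplankton
    payload = {"seed": seed, "version": evoplankton.__version__,
               "params": params}
    Path(path).write_text(json.dumps(payload, indent=2, default=float))
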