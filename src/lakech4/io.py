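"""Reading and writing pipeline inputs and outputs.

Gridded fields go to NetCDF (classic format via xarray's scipy backend,
which supports no 64-bit integers or booleans — those are cast); tables go
to CSV; reports to JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import compilation
from .engine import EmissionReport
from .synthetic import SyntheticWorld


def _sanitize(ds: xr.Dataset) -> xr.Dataset:
    out = ds.copy()
    for name in list(out.variables):
        v = out[name]
        if v.dtype == bool:
            out[name] = v.astype(np.int8)
        elif v.dtype in (np.int64, np.uint64):
            out[name] = v.astype(np.int32)
    out.attrs = {
        k: (v if isinstance(v, (str, int, float)) else str(v))
        for k, v in ds.attrs.items()
    }
    for name in out.variables:
        out[name].attrs = {
            k: (v if isinstance(v, (str, int, float)) else str(v))
            for k, v in out[name].attrs.items()
        }
    return out


def save_dataset(ds: xr.Dataset, path) -> None:
    _sanitize(ds).to_netcdf(path, engine="scipy")


def load_dataset(path) -> xr.Dataset:
    return xr.load_dataset(path, engine="scipy")


_GRID_FILES = {
    "layers": "layers.nc",
    "monthly_temp": "monthly_temp.nc",
    "areas": "area_sources.nc",
}


def write_world(world: SyntheticWorld, outdir) -> Path:
    """Write all pipeline inputs of a world to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_dataset(world.layers, outdir / _GRID_FILES["layers"])
    save_dataset(world.monthly_temp.to_dataset(name="air_temperature"),
                 outdir / _GRID_FILES["monthly_temp"])
    save_dataset(
        xr.Dataset(
            {
                "primary_area": world.primary_area,
                "small_lake_area": world.small_lake_area,
                "river_mask": world.river_mask,
                "reservoir_mask": world.reservoir_mask,
                "large_lake_cells": world.large_lake_cells,
                "ice_phenology_mask": world.ice_phenology_mask,
                "true_type_map": world.true_type_map,
            }
        ),
        outdir / _GRID_FILES["areas"],
    )
    for source, (thaw, freeze) in world.phenology.items():
        save_dataset(
            xr.Dataset({"thaw_doy": thaw, "freeze_doy": freeze}),
            outdir / f"phenology_{source}.nc",
        )
    compilation.write_compilation(world.records, outdir / "compilation.csv")
    if world.cfg is not None:
        (outdir / "generator_config.json").write_text(
            json.dumps(
                {
                    k: (v if not isinstance(v, dict)
                        else {str(kk): vv for kk, vv in v.items()})
                    for k, v in dataclasses.asdict(world.cfg).items()
                },
                indent=2,
            )
        )
    return outdir


def load_world(indir) -> SyntheticWorld:
    """Load a world written by :func:`write_world` (config not restored)."""
    indir = Path(indir)
    layers = load_dataset(indir / _GRID_FILES["layers"])
    monthly_temp = load_dataset(indir / _GRID_FILES["monthly_temp"])["air_temperature"]
    area = load_dataset(indir / _GRID_FILES["areas"])
    phenology = {}
    for f in sorted(indir.glob("phenology_*.nc")):
        source = f.stem.removeprefix("phenology_")
        ds = load_dataset(f)
        phenology[source] = (ds["thaw_doy"], ds["freeze_doy"])
    records = compilation.read_compilation(indir / "compilation.csv")
    return SyntheticWorld(
        cfg=None,
        layers=layers,
        monthly_temp=monthly_temp,
        true_type_map=area["true_type_map"],
        phenology=phenology,
        primary_area=area["primary_area"],
        small_lake_area=area["small_lake_area"],
        river_mask=area["river_mask"],
        reservoir_mask=area["reservoir_mask"],
        large_lake_cells=area["large_lake_cells"].astype(bool),
        ice_phenology_mask=area["ice_phenology_mask"].astype(bool),
        records=records,
    )


def write_report(report: EmissionReport, outdir) -> None:
    """Write an emission report as JSON summary + CSV aggregates."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = {
        "global_total_tg_yr": report.global_total,
        "pathway_totals_tg_yr": report.pathway_totals,
        "type_totals_tg_yr": report.type_totals,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    report.zonal.to_csv(outdir / "zonal_annual_tg.csv", index=False)
    report.daily_zonal.to_csv(outdir / "daily_band_tg.csv", index=False)
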