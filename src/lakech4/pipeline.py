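"""End-to-end orchestration: inputs -> daily emission climatology -> report.

The pipeline wires the modules together in the order the upscaling defines:
classify the grid, build areas, reduce phenology to a season grid, clean and
correct the flux compilation, fit and project the temperature model, spline
to daily curves, add episodic fluxes, integrate, aggregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from . import compilation, seasonality
from .constants import DAYS_PER_YEAR, LAKE_TYPES, N_MONTHS, PATHWAYS, TYPE_CODES
from .engine import (
    DEFAULT_LARGE_LAKE_SCALE,
    EmissionReport,
    aggregate,
    compute_daily_emissions,
)
from .episodic import EpisodicParams, episodic_daily_fields
from .lake_grid import (
    ClassificationThresholds,
    build_lake_area_grid,
    classify_ecoclimatic,
    merge_area_sources,
)
from .seasons import climatological_dates, merge_sources, open_water_mask
from .constants import MG_M2_DAY_TIMES_KM2_TO_TG_PER_DAY


@dataclass
class PipelineParams:
    """Tunable parameters of a pipeline run."""

    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    episodic: EpisodicParams = field(default_factory=EpisodicParams)
    scale_large: float = DEFAULT_LARGE_LAKE_SCALE
    diel_factor: float = 0.7
    min_fit_records: int = seasonality.MIN_FIT_RECORDS


@dataclass
class PipelineResult:
    params: PipelineParams
    type_map: xr.DataArray
    areas: xr.Dataset
    season: xr.Dataset
    records: pd.DataFrame            # corrected, type-labelled records
    rejections: pd.DataFrame
    models: dict
    monthly_table: pd.DataFrame
    stratum_cvs: pd.DataFrame
    curves: xr.DataArray
    e5_by_type: dict
    emissions: xr.Dataset
    report: EmissionReport


def deep_water_rates(
    monthly_table: pd.DataFrame,
    type_monthly_temp: pd.DataFrame,
    slope: float,
    t_deep: float,
) -> dict[str, float]:
    """Per-type ebullition rate at deep-water temperature (mg m-2 d-1).

    Every month's mean ebullition flux is rescaled to t_deep through the
    fitted temperature model and the 12 estimates averaged; with exact
    exponential data all 12 agree, so the mean is a noise-robust estimator.
    """
    out = {}
    ebul = monthly_table[monthly_table["pathway"] == "ebullition"]
    for t, sub in ebul.groupby("lake_type"):
        temps = type_monthly_temp.loc[t].values  # (12,)
        sub = sub.sort_values("month")
        est = sub["flux"].values * np.exp(slope * (t_deep - temps))
        out[t] = float(max(0.0, est.mean()))
    return out


def _type_monthly_temperature(
    monthly_temp: xr.DataArray, type_map: xr.DataArray, areas: xr.Dataset
) -> pd.DataFrame:
    """Lake-area-weighted mean monthly air temperature per lake type."""
    codes = type_map.values
    weights = areas["lake_area"].sum("size_class").values  # (type, lat, lon)
    rows = {}
    for t, c in TYPE_CODES.items():
        sel = codes == c
        w = weights[c][sel]
        if w.sum() == 0:
            continue
        temps = monthly_temp.values[:, sel]  # (12, n)
        rows[t] = (temps * w).sum(axis=1) / w.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=range(1, N_MONTHS + 1))


def prepare_records(
    world, type_map: xr.DataArray, params: PipelineParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Filter, disaggregate, diel-correct and type-label the compilation."""
    kept, rejected = compilation.filter_records(world.records)
    kept = compilation.disaggregate(kept)
    kept = compilation.apply_diel_correction(kept, params.diel_factor)
    kept, rej_type = compilation.assign_lake_type(kept, type_map)
    nonempty = [df for df in (rejected, rej_type) if len(df)]
    rejections = (
        pd.concat(nonempty, ignore_index=True) if nonempty else rejected.copy()
    )
    # Records lacking a contemporaneous air temperature fall back to the
    # site's climatological temperature of the measurement month (flagged).
    missing_t = ~np.isfinite(kept["air_temp_obs"].astype(float))
    if missing_t.any():
        mt = world.monthly_temp
        lat, lon = mt["lat"].values, mt["lon"].values
        for idx in kept.index[missing_t]:
            i = int(np.argmin(np.abs(lat - kept.at[idx, "lat"])))
            j = int(np.argmin(np.abs(lon - kept.at[idx, "lon"])))
            kept.at[idx, "air_temp_obs"] = mt.values[int(kept.at[idx, "month"]) - 1, i, j]
    kept["air_temp_fallback"] = missing_t.values
    return kept, rejections


def build_season_grid(world, params: PipelineParams, lake_mask=None) -> xr.Dataset:
    from .seasons import SOURCE_LAKE_ICE, SOURCE_LANDSCAPE

    land = climatological_dates(*world.phenology["landscape"], source=SOURCE_LANDSCAPE)
    ice = climatological_dates(*world.phenology["lake_ice"], source=SOURCE_LAKE_ICE)
    return merge_sources(ice, land, world.ice_phenology_mask, lake_mask=lake_mask)


def run_pipeline(world, params: PipelineParams | None = None) -> PipelineResult:
    """Run the full upscaling on a (synthetic or loaded) world."""
    params = params or PipelineParams()

    type_map = classify_ecoclimatic(world.layers, params.thresholds)
    merged = merge_area_sources(
        world.primary_area,
        world.small_lake_area,
        world.river_mask,
        world.reservoir_mask,
        world.large_lake_cells,
    )
    areas = build_lake_area_grid(merged, type_map)
    lake_mask = areas["lake_area"].sum(("lake_type", "size_class")) > 0
    season = build_season_grid(world, params, lake_mask=lake_mask)

    records, rejections = prepare_records(world, type_map, params)

    models = {
        p: seasonality.fit_temp_flux(records, p, params.min_fit_records)
        for p in PATHWAYS
    }
    projected = seasonality.project_records(records, models, world.monthly_temp)
    present = areas["lake_area"].sum(("size_class", "lat", "lon"))
    required = [t for t in LAKE_TYPES if float(present.sel(lake_type=t)) > 0]
    monthly_table = seasonality.aggregate_monthly(projected, required_types=required)
    cvs = seasonality.stratum_cv(projected)
    curves = seasonality.spline_to_daily(monthly_table)

    type_temps = _type_monthly_temperature(world.monthly_temp, type_map, areas)
    e5 = deep_water_rates(
        monthly_table, type_temps, models["ebullition"].slope, params.episodic.t_deep
    )
    e5_map = xr.DataArray(
        np.array([[e5.get(t, 0.0) for t in LAKE_TYPES]])
        .ravel()[type_map.values],
        coords=type_map.coords,
        dims=type_map.dims,
    )
    episodic_fields = episodic_daily_fields(season, e5_map, params.episodic)

    emissions = compute_daily_emissions(
        areas, curves, season, type_map, episodic_fields, params.scale_large
    )
    report = aggregate(emissions, type_map, areas)
    return PipelineResult(
        params=params,
        type_map=type_map,
        areas=areas,
        season=season,
        records=records,
        rejections=rejections,
        models=models,
        monthly_table=monthly_table,
        stratum_cvs=cvs,
        curves=curves,
        e5_by_type=e5,
        emissions=emissions,
        report=report,
    )


def stratum_decomposition(result: PipelineResult) -> pd.DataFrame:
    """Annual D+E emission per type x pathway, split by size class (Tg yr-1).

    The large-class column is reported at unit scaling (multiply by the
    large-lake factor to recover its contribution); used by the uncertainty
    module's linearized total model and by closure tests.
    """
    season = result.season
    curves = result.curves
    mask = open_water_mask(season)  # (day, lat, lon)
    codes = result.type_map.values
    rows = []
    for t in curves["lake_type"].values:
        sel = codes == TYPE_CODES[t]
        if not sel.any():
            continue
        a_small = result.areas["lake_area"].sel(lake_type=t, size_class="small").values
        a_large = result.areas["lake_area"].sel(lake_type=t, size_class="large").values
        open_days = mask[:, sel]  # (day, n)
        for p in PATHWAYS:
            f = curves.sel(lake_type=t, pathway=p).values  # (day,)
            integral = (open_days * f[:, None]).sum(axis=0)  # (n,) mg m-2 yr-1
            small = float((integral * a_small[sel]).sum()) * MG_M2_DAY_TIMES_KM2_TO_TG_PER_DAY
            large = float((integral * a_large[sel]).sum()) * MG_M2_DAY_TIMES_KM2_TO_TG_PER_DAY
            rows.append({"lake_type": t, "pathway": p, "small_tg": small, "large_tg_unit": large})
    return pd.DataFrame(rows)
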