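"""Climatological emission-season grid from multi-year freeze/thaw dates.

The emission season of a cell is the open-water period between the
climatological thaw and freeze day-of-year. Two phenology sources are
merged: a lake-ice phenology product for cells containing lakes >= 50 km2,
and a landscape freeze/thaw product everywhere else.
"""

from __future__ import annotations

import warnings

import numpy as np
import xarray as xr

from .constants import DAYS_PER_YEAR

SOURCE_LANDSCAPE = 0
SOURCE_LAKE_ICE = 1

# Beyond this spread (days) between per-year dates, the plain mean would
# straddle the new-year wrap; use the circular mean instead.
_WRAP_SPREAD_DAYS = 182


def season_length_days(thaw: np.ndarray, freeze: np.ndarray) -> np.ndarray:
    """Emission-season length (freeze - thaw) mod 365, in days.

    Modular arithmetic keeps Southern-Hemisphere seasons (freeze DOY before
    thaw DOY) positive; equal dates are read as a full-year season.
    """
    length = np.mod(np.asarray(freeze, float) - np.asarray(thaw, float), DAYS_PER_YEAR)
    return np.where(length == 0, DAYS_PER_YEAR, length)


def _circular_mean_doy(doys: np.ndarray, axis: int = 0) -> np.ndarray:
    """Circular mean of day-of-year values (1..365), NaN-aware."""
    ang = (np.asarray(doys, float) - 1.0) * (2 * np.pi / DAYS_PER_YEAR)
    s = np.nanmean(np.sin(ang), axis=axis)
    c = np.nanmean(np.cos(ang), axis=axis)
    mean = np.arctan2(s, c) * (DAYS_PER_YEAR / (2 * np.pi)) + 1.0
    return np.mod(mean - 1.0, DAYS_PER_YEAR) + 1.0


def _mean_doy(per_year: np.ndarray) -> np.ndarray:
    """Mean DOY over the year axis; circular where dates straddle new year."""
    with warnings.catch_warnings():
        # all-NaN cells (never frozen) are expected and handled by the caller
        warnings.simplefilter("ignore", RuntimeWarning)
        plain = np.nanmean(per_year, axis=0)
        spread = np.nanmax(per_year, axis=0) - np.nanmin(per_year, axis=0)
        wraps = spread > _WRAP_SPREAD_DAYS
        if np.any(wraps):
            circ = _circular_mean_doy(per_year, axis=0)
            plain = np.where(wraps, circ, plain)
    return plain


def climatological_dates(
    thaw: xr.DataArray, freeze: xr.DataArray, source: int = SOURCE_LANDSCAPE
) -> xr.Dataset:
    """Reduce per-year thaw/freeze DOY grids to a climatological season grid.

    ``thaw``/``freeze`` have dims (year, lat, lon); years in which a cell
    never froze are NaN in both. Cells unfrozen in *every* year get the
    ``no_freeze`` flag and a 365-day season. Dates are the per-cell mean DOY
    over years with freezing, rounded to the nearest day (circular mean when
    the per-year dates straddle the new year).
    """
    thaw_v = thaw.values.astype(float)
    freeze_v = freeze.values.astype(float)
    frozen_any = ~np.all(np.isnan(thaw_v), axis=0)

    with np.errstate(invalid="ignore"):
        thaw_clim = np.round(_mean_doy(thaw_v))
        freeze_clim = np.round(_mean_doy(freeze_v))
    thaw_clim = np.mod(thaw_clim - 1, DAYS_PER_YEAR) + 1
    freeze_clim = np.mod(freeze_clim - 1, DAYS_PER_YEAR) + 1

    no_freeze = ~frozen_any
    thaw_clim = np.where(no_freeze, 1.0, thaw_clim)
    freeze_clim = np.where(no_freeze, 1.0, freeze_clim)
    length = np.where(no_freeze, DAYS_PER_YEAR, season_length_days(thaw_clim, freeze_clim))

    coords = {"lat": thaw["lat"], "lon": thaw["lon"]}
    return xr.Dataset(
        {
            "thaw_doy": (("lat", "lon"), thaw_clim),
            "freeze_doy": (("lat", "lon"), freeze_clim),
            "season_length": (("lat", "lon"), length.astype(float)),
            "no_freeze": (("lat", "lon"), no_freeze),
            "source": (("lat", "lon"), np.full(no_freeze.shape, source, dtype=np.int8)),
        },
        coords=coords,
    )


def merge_sources(
    lake_ice: xr.Dataset,
    landscape: xr.Dataset,
    large_lake_mask: xr.DataArray,
    lake_mask: xr.DataArray | None = None,
    no_freeze_fallback_lat: float = 40.0,
) -> xr.Dataset:
    """Combine the two phenology sources into one season grid.

    Cells flagged by ``large_lake_mask`` (containing lakes >= 50 km2) take
    the lake-ice phenology; all others the landscape product. Masked cells
    missing from the lake-ice source fall back to the landscape product
    (counted in ``attrs["n_lake_ice_fallback"]``). Cells missing from both
    sources default to no-freeze when |lat| < ``no_freeze_fallback_lat``;
    a missing higher-latitude cell that contains lakes (``lake_mask``) is a
    hard error.
    """
    mask = large_lake_mask.values.astype(bool)
    ice_valid = ~np.isnan(lake_ice["season_length"].values)
    land_valid = ~np.isnan(landscape["season_length"].values)

    use_ice = mask & ice_valid
    n_fallback = int(np.count_nonzero(mask & ~ice_valid & land_valid))

    out = {}
    for var in ("thaw_doy", "freeze_doy", "season_length"):
        out[var] = np.where(use_ice, lake_ice[var].values, landscape[var].values)
    no_freeze = np.where(use_ice, lake_ice["no_freeze"].values, landscape["no_freeze"].values)
    source = np.where(use_ice, SOURCE_LAKE_ICE, SOURCE_LANDSCAPE).astype(np.int8)

    missing = ~np.where(use_ice, ice_valid, land_valid)
    if np.any(missing):
        lat2d = np.broadcast_to(
            landscape["lat"].values[:, None], missing.shape
        )
        low_lat = np.abs(lat2d) < no_freeze_fallback_lat
        fill = missing & low_lat
        out["thaw_doy"] = np.where(fill, 1.0, out["thaw_doy"])
        out["freeze_doy"] = np.where(fill, 1.0, out["freeze_doy"])
        out["season_length"] = np.where(fill, DAYS_PER_YEAR, out["season_length"])
        no_freeze = np.where(fill, True, no_freeze)
        bad = missing & ~low_lat
        if lake_mask is not None and bool((bad & lake_mask.values.astype(bool)).any()):
            raise ValueError(
                "phenology missing for high-latitude lake cells; "
                f"{int(np.count_nonzero(bad))} cells affected"
            )

    coords = {"lat": landscape["lat"], "lon": landscape["lon"]}
    return xr.Dataset(
        {
            "thaw_doy": (("lat", "lon"), out["thaw_doy"]),
            "freeze_doy": (("lat", "lon"), out["freeze_doy"]),
            "season_length": (("lat", "lon"), out["season_length"]),
            "no_freeze": (("lat", "lon"), no_freeze.astype(bool)),
            "source": (("lat", "lon"), source),
        },
        coords=coords,
        attrs={"n_lake_ice_fallback": n_fallback},
    )


def open_water_mask(season: xr.Dataset, days: np.ndarray | None = None) -> np.ndarray:
    """Boolean (day, lat, lon) array: True on open-water (emitting) days.

    Emissions commence on the thaw date and end on the freeze date (thaw day
    inclusive, freeze day exclusive), so the number of open days equals the
    season length exactly; no-freeze cells are open all year.
    """
    if days is None:
        days = np.arange(1, DAYS_PER_YEAR + 1)
    thaw = season["thaw_doy"].values
    length = season["season_length"].values
    rel = np.mod(days[:, None, None] - thaw[None, :, :], DAYS_PER_YEAR)
    mask = rel < length[None, :, :]
    mask |= season["no_freeze"].values[None, :, :]
    return mask
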