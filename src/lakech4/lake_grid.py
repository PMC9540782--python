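"""0.25-degree lake-area grid and ecoclimatic classification.

Every lake cell is assigned exactly one of seven ecoclimatic types from a
fixed-precedence decision tree over permafrost category, ground-ice content,
soil organic carbon and annual soil temperature. Lake area per cell is the
merger of a primary per-lake inventory (which also flags cells containing
lakes >= 5,000 km2) and a remote-sensing small-lake source from which river
and reservoir area fractions are first removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .constants import (
    CODE_TYPES,
    EARTH_RADIUS_KM,
    GRID_RESOLUTION_DEG,
    LAKE_TYPES,
    PERMAFROST_CODES,
    SIZE_CLASSES,
    TYPE_CODES,
)


@dataclass(frozen=True)
class ClassificationThresholds:
    """Thresholds of the ecoclimatic decision tree.

    soc_organic
        Soil organic carbon (kgC m-2, depth-weighted to 1 m) at or above
        which sporadic/isolated-permafrost cells are peat pond or organic.
    ground_ice_rich
        Ground-ice content (% volume) separating thermokarst from
        glacial/postglacial, and peat pond from organic.
    t_tropical
        Annual soil temperature (deg C) at or above which a no-permafrost
        cell is tropical/subtropical. Varied by +-2.5 deg C in the
        uncertainty analysis.
    t_boreal
        Annual soil temperature (deg C) separating temperate from other
        boreal. Not printed in the source inventory; 8.0 deg C is this
        package's documented convention.
    """

    soc_organic: float = 10.0
    ground_ice_rich: float = 10.0
    t_tropical: float = 20.0
    t_boreal: float = 8.0


def grid_coords(
    lat_min: float,
    lat_max: float,
    lon_min: float,
    lon_max: float,
    res: float = GRID_RESOLUTION_DEG,
) -> tuple[np.ndarray, np.ndarray]:
    """Cell-center coordinates of a regular lat/lon grid.

    The global convention is centers at -89.875 ... 89.875 and
    -179.875 ... 179.875; subgrids are aligned to the same lattice.
    """
    lat = np.arange(lat_min + res / 2, lat_max, res)
    lon = np.arange(lon_min + res / 2, lon_max, res)
    return lat, lon


def cell_area_km2(lat: np.ndarray, res: float = GRID_RESOLUTION_DEG) -> np.ndarray:
    """Geographic area (km2) of res x res cells centered at latitudes ``lat``.

    Spherical Earth, exact integral of cos(phi) across the cell.
    """
    lat = np.asarray(lat, dtype=float)
    dphi = np.deg2rad(res)
    phi1 = np.deg2rad(lat - res / 2)
    phi2 = np.deg2rad(lat + res / 2)
    return EARTH_RADIUS_KM**2 * dphi * (np.sin(phi2) - np.sin(phi1))


def classify_ecoclimatic(
    layers: xr.Dataset,
    thresholds: ClassificationThresholds | None = None,
) -> xr.DataArray:
    """Classify every cell into one of the seven ecoclimatic lake types.

    ``layers`` must hold ``permafrost_category`` (integer codes, see
    :data:`lakech4.constants.PERMAFROST_CODES`), ``ground_ice`` (% volume),
    ``soc`` (kgC m-2) and ``annual_soil_temp`` (deg C).

    Decision tree, fixed precedence:

    1. continuous/discontinuous permafrost, ground ice >= 10 % -> thermokarst
    2. continuous/discontinuous permafrost, ground ice < 10 % ->
       glacial/postglacial
    3. sporadic/isolated permafrost, SOC >= 10, ground ice >= 10 % -> peat pond
    4. sporadic/isolated permafrost, SOC >= 10, ground ice < 10 % -> organic
    5. otherwise (no permafrost, or sporadic/isolated with SOC < 10, which
       falls through and is counted): annual soil temperature >= t_tropical ->
       tropical/subtropical; >= t_boreal -> temperate; else other boreal.

    Returns an integer-coded type map (:data:`lakech4.constants.TYPE_CODES`)
    with the number of fall-through cells recorded in
    ``attrs["n_fallthrough"]``.
    """
    th = thresholds or ClassificationThresholds()
    pf = layers["permafrost_category"].values
    ice = layers["ground_ice"].values
    soc = layers["soc"].values
    temp = layers["annual_soil_temp"].values

    cd = (pf == PERMAFROST_CODES["C"]) | (pf == PERMAFROST_CODES["D"])
    si = (pf == PERMAFROST_CODES["S"]) | (pf == PERMAFROST_CODES["I"])
    icy = ice >= th.ground_ice_rich
    carbon_rich = soc >= th.soc_organic

    out = np.full(pf.shape, -1, dtype=np.int16)
    out[cd & icy] = TYPE_CODES["thermokarst"]
    out[cd & ~icy] = TYPE_CODES["glacial_postglacial"]
    out[si & carbon_rich & icy] = TYPE_CODES["peat_pond"]
    out[si & carbon_rich & ~icy] = TYPE_CODES["organic"]

    rest = out == -1
    fallthrough = int(np.count_nonzero(rest & si))
    out[rest & (temp >= th.t_tropical)] = TYPE_CODES["tropical_subtropical"]
    rest = out == -1
    out[rest & (temp >= th.t_boreal)] = TYPE_CODES["temperate"]
    out[out == -1] = TYPE_CODES["other_boreal"]

    da = xr.DataArray(
        out,
        coords={"lat": layers["lat"], "lon": layers["lon"]},
        dims=("lat", "lon"),
        name="lake_type",
        attrs={
            "codes": ", ".join(f"{i}={t}" for i, t in CODE_TYPES.items()),
            "n_fallthrough": fallthrough,
        },
    )
    return da


def merge_area_sources(
    primary_area: xr.DataArray,
    small_lake_area: xr.DataArray,
    river_mask: xr.DataArray,
    reservoir_mask: xr.DataArray,
    large_lake_cells: xr.DataArray,
) -> xr.Dataset:
    """Merge primary and small-lake area sources into per-cell lake area (km2).

    River/reservoir masks are area amounts (same units as the small-lake
    source) subtracted from the small-lake source before merging; the small
    contribution is clamped at zero. ``large_lake_cells`` is a boolean flag
    for cells containing a lake >= 5,000 km2 (from the primary source's
    per-lake attribute): the primary area of such cells goes to the large
    size class, everything else to the small class.
    """
    for name, da in (
        ("small_lake_area", small_lake_area),
        ("river_mask", river_mask),
        ("reservoir_mask", reservoir_mask),
        ("large_lake_cells", large_lake_cells),
    ):
        if da.shape != primary_area.shape:
            raise ValueError(
                f"grid mismatch: {name} has shape {da.shape}, "
                f"primary has {primary_area.shape}"
            )
    small = (small_lake_area - river_mask - reservoir_mask).clip(min=0.0)
    large_flag = large_lake_cells.astype(bool)
    area_large = primary_area.where(large_flag, 0.0)
    area_small = primary_area.where(~large_flag, 0.0) + small
    return xr.Dataset(
        {
            "area_small": area_small.rename("area_small"),
            "area_large": area_large.rename("area_large"),
        },
        attrs={"units": "km2"},
    )


def build_lake_area_grid(merged: xr.Dataset, type_map: xr.DataArray) -> xr.Dataset:
    """Split merged per-cell areas by ecoclimatic type and size class.

    Returns a dataset with ``lake_area`` (lake_type, size_class, lat, lon)
    and ``cell_area`` (lat, lon), both km2. Each cell carries one type, so
    its area lands entirely in that type's slot.
    """
    lat = merged["lat"].values
    lon = merged["lon"].values
    codes = type_map.values
    area = np.zeros((len(LAKE_TYPES), len(SIZE_CLASSES), len(lat), len(lon)))
    for t, code in TYPE_CODES.items():
        sel = codes == code
        area[code, 0][sel] = merged["area_small"].values[sel]
        area[code, 1][sel] = merged["area_large"].values[sel]

    cell = np.broadcast_to(cell_area_km2(lat)[:, None], (len(lat), len(lon)))
    ds = xr.Dataset(
        {
            "lake_area": (("lake_type", "size_class", "lat", "lon"), area),
            "cell_area": (("lat", "lon"), cell.copy()),
        },
        coords={
            "lake_type": list(LAKE_TYPES),
            "size_class": list(SIZE_CLASSES),
            "lat": lat,
            "lon": lon,
        },
        attrs={"units": "km2"},
    )
    total = ds["lake_area"].sum(("lake_type", "size_class"))
    if bool((total > ds["cell_area"] * (1 + 1e-9)).any()):
        raise ValueError("lake area exceeds cell geographic area")
    return ds
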