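"""Synthetic world generator: every pipeline input with known ground truth.

The generator emulates the statistical structure the upscaling assumes — an
exponential flux-temperature law per pathway with lognormal scatter and a
daytime sampling bias, a latitude-driven climate, geophysical layers
realizing all seven ecoclimatic type signatures, latitude-driven freeze/thaw
phenology from two sources, and lake-area sources split at 5,000 km2 — so
the full pipeline can run and be validated without any real-data downloads.
It emulates no real geography and no satellite retrieval error.

A single integer seed drives independent substreams per component, so each
input can be regenerated on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from .constants import (
    DAYS_PER_YEAR,
    LAKE_TYPES,
    N_MONTHS,
    PERMAFROST_CODES,
    TYPE_CODES,
)
from .lake_grid import cell_area_km2, grid_coords
from .reference import reference_inventory

# Substream indices off the master seed.
_STREAM_PHENOLOGY = 1
_STREAM_RECORDS = 2


def _default_alpha() -> dict:
    """Base fluxes (mg m-2 d-1 at 0 degC) per (type, pathway).

    Chosen so that alpha * exp(beta * T_ref) reproduces the published
    season-mean flux of each type at a representative season temperature,
    split ~60/40 ebullition/diffusion (35/65 for other boreal, where
    diffusion dominates observations). Organic copies peat pond, mirroring
    the alias used on the measurement side.
    """
    beta = _default_beta()
    t_ref = {
        "thermokarst": 8.0,
        "glacial_postglacial": 8.0,
        "peat_pond": 11.0,
        "organic": 11.0,
        "other_boreal": 10.0,
        "temperate": 15.0,
        "tropical_subtropical": 26.0,
    }
    ebul_share = {t: 0.6 for t in LAKE_TYPES}
    ebul_share["other_boreal"] = 0.35
    ref = reference_inventory()["flux_small_mg_m2_d"]
    alpha = {}
    for t in LAKE_TYPES:
        for p, share in (("diffusion", 1 - ebul_share[t]), ("ebullition", ebul_share[t])):
            alpha[(t, p)] = share * float(ref[t]) / float(np.exp(beta[p] * t_ref[t]))
    for p in ("diffusion", "ebullition"):
        alpha[("organic", p)] = alpha[("peat_pond", p)]
    return alpha


def _default_beta() -> dict:
    # Temperature sensitivities (degC-1): Q10 ~ 2 for diffusion, ~3 for
    # ebullition, in line with published flux-temperature relationships.
    return {"diffusion": 0.07, "ebullition": 0.11}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic world; defaults are the study conditions.

    Counts mirror the real compilation (575 lake systems, 881 aggregated
    values); contamination fractions are small, realistic rates used to
    exercise the filters. Flux scatter ``sigma_lognoise`` is the sd of
    ln(flux) around the temperature model (0.8 ~ the large between-lake
    variability of flux compilations).
    """

    seed: int = 0
    n_sites: int = 575
    n_records: int = 881
    lat_min: float = -35.0
    lat_max: float = 80.0
    lon_min: float = 0.0
    lon_max: float = 10.0
    resolution: float = 0.25

    alpha: dict = field(default_factory=_default_alpha)
    beta: dict = field(default_factory=_default_beta)
    diel_day_multiplier: float = 1.0 / 0.7
    sigma_lognoise: float = 0.8
    daytime_fraction: float = 0.8
    indirect_fraction: float = 0.03
    beaver_pond_fraction: float = 0.02
    missing_metadata_fraction: float = 0.06  # split evenly: pathway/month/window
    component_fraction: float = 0.05         # records reported as k-component means
    explicit_label_fraction: float = 0.7

    # Climate: annual mean T(lat) = t_equator - lat_gradient * |lat|;
    # seasonal amplitude amp0 + amp_per_lat * |lat| peaking mid-summer.
    t_equator: float = 27.0
    lat_gradient: float = 0.45
    amp0: float = 2.0
    amp_per_lat: float = 0.35

    # Phenology: open-water season shrinks poleward of no_freeze_lat by
    # season_slope days per degree; per-year jitter sd in days.
    no_freeze_lat: float = 40.0
    season_slope: float = 6.0
    min_season: float = 60.0
    n_years: int = 13
    jitter_days: float = 5.0
    lake_ice_offset_days: float = 3.0  # big lakes thaw/freeze slightly later

    # Areas, as fractions of cell geographic area.
    primary_area_fraction: float = 0.02
    small_lake_area_fraction: float = 0.008
    river_mask_fraction: float = 0.002
    reservoir_mask_fraction: float = 0.001
    large_lake_cell_fraction: float = 0.30  # primary fraction in >=5,000 km2 cells

    def __post_init__(self):
        for key, a in self.alpha.items():
            if a <= 0:
                raise ValueError(f"alpha must be positive; alpha[{key}] = {a}")
        for key, b in self.beta.items():
            if b < 0:
                raise ValueError(f"beta must be non-negative; beta[{key}] = {b}")
        if self.sigma_lognoise < 0:
            raise ValueError("sigma_lognoise must be non-negative")
        if self.diel_day_multiplier < 1:
            raise ValueError("diel_day_multiplier must be >= 1")
        for name in (
            "daytime_fraction", "indirect_fraction", "beaver_pond_fraction",
            "missing_metadata_fraction", "component_fraction",
            "explicit_label_fraction",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def stream(self, index: int) -> np.random.Generator:
        """Independent RNG substream ``index`` of the master seed."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, index)))


def noise_free_config(**overrides) -> GeneratorConfig:
    """A configuration whose world is analytically solvable.

    No flux scatter, no temperature dependence, one common base flux, no
    contamination: the pipeline's global total has the closed form
    sum over cells of effective lake area x flux x season length (plus the
    episodic terms, which are closed-form too).
    """
    alpha = {(t, p): 50.0 for t in LAKE_TYPES for p in ("diffusion", "ebullition")}
    cfg = dict(
        alpha=alpha,
        beta={"diffusion": 0.0, "ebullition": 0.0},
        sigma_lognoise=0.0,
        indirect_fraction=0.0,
        beaver_pond_fraction=0.0,
        missing_metadata_fraction=0.0,
        component_fraction=0.0,
        jitter_days=0.0,
    )
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


@dataclass
class SyntheticWorld:
    """All generated pipeline inputs plus embedded ground truth."""

    cfg: GeneratorConfig
    layers: xr.Dataset              # soc, permafrost_category, ground_ice, annual_soil_temp
    monthly_temp: xr.DataArray      # (month, lat, lon) air-temperature climatology
    true_type_map: xr.DataArray     # intended ecoclimatic type per cell
    phenology: dict                 # source -> (thaw, freeze) per-year DOY grids
    primary_area: xr.DataArray      # km2 per cell, large-lake inventory source
    small_lake_area: xr.DataArray   # km2 per cell, small-lake source
    river_mask: xr.DataArray        # km2 to subtract from the small-lake source
    reservoir_mask: xr.DataArray
    large_lake_cells: xr.DataArray  # bool, cell contains a >=5,000 km2 lake
    ice_phenology_mask: xr.DataArray  # bool, cell contains a >=50 km2 lake
    records: pd.DataFrame


def _latlon(cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray]:
    return grid_coords(cfg.lat_min, cfg.lat_max, cfg.lon_min, cfg.lon_max, cfg.resolution)


def _annual_temp(cfg: GeneratorConfig, lat: np.ndarray) -> np.ndarray:
    return cfg.t_equator - cfg.lat_gradient * np.abs(lat)


def monthly_temperature(cfg: GeneratorConfig) -> xr.DataArray:
    """Monthly air-temperature climatology (month, lat, lon), degC.

    Sinusoid around the latitude-driven annual mean, amplitude growing with
    |latitude|, peaking mid-July in the north and mid-January in the south;
    the annual mean of the 12 values equals the annual mean exactly.
    """
    lat, lon = _latlon(cfg)
    t_ann = _annual_temp(cfg, lat)
    amp = cfg.amp0 + cfg.amp_per_lat * np.abs(lat)
    months = np.arange(1, N_MONTHS + 1)
    peak = np.where(lat >= 0, 7.0, 1.0)
    cyc = np.cos(2 * np.pi * (months[:, None] - peak[None, :]) / N_MONTHS)
    temp = t_ann[None, :] + amp[None, :] * cyc
    temp3 = np.repeat(temp[:, :, None], len(lon), axis=2)
    return xr.DataArray(
        temp3,
        coords={"month": months, "lat": lat, "lon": lon},
        dims=("month", "lat", "lon"),
        name="air_temperature",
        attrs={"units": "degC"},
    )


def generate_geophysical_layers(
    cfg: GeneratorConfig,
) -> tuple[xr.Dataset, xr.DataArray, xr.DataArray]:
    """Geophysical layer stack, monthly temperature, and the true type map.

    Latitude bands set the thermal regime (tropical poleward through
    permafrost); longitude stripes alternate ground-ice and soil-carbon
    signatures within bands so that every one of the seven classification
    signatures occurs. Annual soil temperature equals the annual mean air
    temperature, keeping classification and flux modeling consistent.
    """
    lat, lon = _latlon(cfg)
    t_ann = _annual_temp(cfg, lat)
    ny, nx = len(lat), len(lon)

    t2 = np.broadcast_to(t_ann[:, None], (ny, nx)).copy()
    stripe = np.broadcast_to((np.arange(nx) % 2)[None, :], (ny, nx))

    # Thermal bands on annual mean temperature (degC).
    cd_band = t2 < -2.0            # continuous/discontinuous permafrost
    si_band = (t2 >= -2.0) & (t2 < 1.0)  # sporadic/isolated permafrost

    pf = np.full((ny, nx), PERMAFROST_CODES["none"], dtype=np.int8)
    pf[cd_band & (stripe == 0)] = PERMAFROST_CODES["C"]
    pf[cd_band & (stripe == 1)] = PERMAFROST_CODES["D"]
    pf[si_band & (stripe == 0)] = PERMAFROST_CODES["S"]
    pf[si_band & (stripe == 1)] = PERMAFROST_CODES["I"]

    # Ground ice alternates rich/poor on a 2-cell longitude period offset
    # from the permafrost stripes, so every ice x permafrost combination
    # appears; SOC is high wherever sporadic/isolated permafrost occurs.
    ice_stripe = np.broadcast_to(((np.arange(nx) // 2) % 2)[None, :], (ny, nx))
    ice = np.where(ice_stripe == 0, 15.0, 5.0)
    ice = np.where(cd_band | si_band, ice, 0.0)
    soc = np.where(si_band, 12.0, 2.0)

    true = np.full((ny, nx), -1, dtype=np.int16)
    true[cd_band & (ice >= 10)] = TYPE_CODES["thermokarst"]
    true[cd_band & (ice < 10)] = TYPE_CODES["glacial_postglacial"]
    true[si_band & (ice >= 10)] = TYPE_CODES["peat_pond"]
    true[si_band & (ice < 10)] = TYPE_CODES["organic"]
    rest = true == -1
    true[rest & (t2 >= 20.0)] = TYPE_CODES["tropical_subtropical"]
    rest = true == -1
    true[rest & (t2 >= 8.0)] = TYPE_CODES["temperate"]
    true[true == -1] = TYPE_CODES["other_boreal"]

    coords = {"lat": lat, "lon": lon}
    layers = xr.Dataset(
        {
            "soc": (("lat", "lon"), soc),
            "permafrost_category": (("lat", "lon"), pf),
            "ground_ice": (("lat", "lon"), ice),
            "annual_soil_temp": (("lat", "lon"), t2),
        },
        coords=coords,
    )
    true_map = xr.DataArray(true, coords=coords, dims=("lat", "lon"), name="true_type")
    missing = [t for t, c in TYPE_CODES.items() if not np.any(true == c)]
    if missing:
        raise ValueError(
            f"grid extent {cfg.lat_min}..{cfg.lat_max} does not realize lake "
            f"types {missing}; widen the latitude range"
        )
    return layers, monthly_temperature(cfg), true_map


def _season_params(cfg: GeneratorConfig, lat: np.ndarray):
    """Climatological season length, thaw and freeze DOY per latitude."""
    alat = np.abs(lat)
    length = np.clip(
        DAYS_PER_YEAR - cfg.season_slope * (alat - cfg.no_freeze_lat),
        cfg.min_season,
        DAYS_PER_YEAR,
    )
    no_freeze = alat < cfg.no_freeze_lat
    center = np.where(lat >= 0, 196.0, 15.0)  # mid-summer DOY per hemisphere
    thaw = np.mod(center - length / 2 - 1, DAYS_PER_YEAR) + 1
    freeze = np.mod(thaw + length - 1, DAYS_PER_YEAR) + 1
    return length, thaw, freeze, no_freeze


def generate_phenology(cfg: GeneratorConfig) -> dict:
    """Per-year thaw/freeze DOY grids for the two phenology sources.

    Poleward cells thaw later and freeze earlier; cells equatorward of
    ``no_freeze_lat`` never freeze (NaN in every year). Each year jitters
    around the climatological date with sd ``jitter_days``; the lake-ice
    source lags the landscape source by ``lake_ice_offset_days`` on both
    dates (large water bodies respond more slowly).
    """
    lat, lon = _latlon(cfg)
    ny, nx = len(lat), len(lon)
    rng = cfg.stream(_STREAM_PHENOLOGY)
    _, thaw0, freeze0, no_freeze = _season_params(cfg, lat)

    out = {}
    for source, offset in (("landscape", 0.0), ("lake_ice", cfg.lake_ice_offset_days)):
        thaw_years = np.empty((cfg.n_years, ny, nx))
        freeze_years = np.empty((cfg.n_years, ny, nx))
        for y in range(cfg.n_years):
            jt = rng.normal(0, cfg.jitter_days, size=(ny, nx)) if cfg.jitter_days else 0.0
            jf = rng.normal(0, cfg.jitter_days, size=(ny, nx)) if cfg.jitter_days else 0.0
            thaw_years[y] = np.mod(thaw0[:, None] + offset + jt - 1, DAYS_PER_YEAR) + 1
            freeze_years[y] = np.mod(freeze0[:, None] + offset + jf - 1, DAYS_PER_YEAR) + 1
        thaw_years[:, no_freeze, :] = np.nan
        freeze_years[:, no_freeze, :] = np.nan
        coords = {"year": np.arange(cfg.n_years), "lat": lat, "lon": lon}
        out[source] = (
            xr.DataArray(thaw_years, coords=coords, dims=("year", "lat", "lon")),
            xr.DataArray(freeze_years, coords=coords, dims=("year", "lat", "lon")),
        )
    return out


def generate_area_sources(cfg: GeneratorConfig):
    """Deterministic lake-area sources (km2 per cell) and size/phenology masks.

    Every cell holds lakes: a primary-source fraction of cell area plus a
    small-lake source partly masked by rivers and reservoirs. A sparse
    longitude stripe of mid/high-latitude cells carries >=5,000 km2 lakes
    (30 % of cell area, flagged large); a wider stripe carries >=50 km2
    lakes with their own ice-phenology record.
    """
    lat, lon = _latlon(cfg)
    ny, nx = len(lat), len(lon)
    cell = np.broadcast_to(cell_area_km2(lat, cfg.resolution)[:, None], (ny, nx))

    jj = np.broadcast_to(np.arange(nx)[None, :], (ny, nx))
    large_cells = (jj == nx // 2) & (np.abs(lat)[:, None] > 20.0)
    ice_mask = (jj % 8 == nx // 2 % 8) & (np.abs(lat)[:, None] > 20.0)

    primary = np.where(large_cells, cfg.large_lake_cell_fraction, cfg.primary_area_fraction) * cell
    small = cfg.small_lake_area_fraction * cell
    river = cfg.river_mask_fraction * cell
    reservoir = cfg.reservoir_mask_fraction * cell

    coords = {"lat": lat, "lon": lon}

    def da(v, name):
        return xr.DataArray(v, coords=coords, dims=("lat", "lon"), name=name)

    return (
        da(primary, "primary_area"),
        da(small, "small_lake_area"),
        da(river, "river_mask"),
        da(reservoir, "reservoir_mask"),
        da(large_cells, "large_lake_cells"),
        da(ice_mask | large_cells, "ice_phenology_mask"),
    )


def generate_flux_records(
    cfg: GeneratorConfig,
    monthly_temp: xr.DataArray | None = None,
    true_type_map: xr.DataArray | None = None,
) -> pd.DataFrame:
    """The synthetic flux-measurement compilation.

    Each record's expected flux is alpha(type, pathway) *
    exp(beta(pathway) * T(site, month)) * m * lognormal noise, with m the
    daytime multiplier for daytime-sampled records. Sites sit on non-organic
    lake cells (organic lakes have no measurements, mirroring the real
    compilation); months are drawn from each site's open-water season.
    Contamination (indirect methods, beaver ponds, missing metadata) is
    planted in disjoint record subsets; ground-truth columns are prefixed
    ``true_``.
    """
    if monthly_temp is None or true_type_map is None:
        _, monthly_temp, true_type_map = generate_geophysical_layers(cfg)
    rng = cfg.stream(_STREAM_RECORDS)
    lat, lon = _latlon(cfg)
    length, thaw, freeze, no_freeze = _season_params(cfg, lat)
    codes = true_type_map.values

    eligible_types = [t for t in LAKE_TYPES if t != "organic"]
    cells_by_type = {
        t: np.argwhere(codes == TYPE_CODES[t]) for t in eligible_types
    }
    for t, cells in cells_by_type.items():
        if len(cells) == 0:
            raise ValueError(f"no cells of type {t} on the grid")

    # Sites round-robin over types first (coverage guarantee), then random.
    site_cells, site_types = [], []
    for k in range(cfg.n_sites):
        t = eligible_types[k % len(eligible_types)]
        cells = cells_by_type[t]
        site_cells.append(cells[rng.integers(len(cells))])
        site_types.append(t)

    month_mid_doy = (np.arange(N_MONTHS) + 0.5) * DAYS_PER_YEAR / N_MONTHS

    def open_months(i: int) -> np.ndarray:
        if no_freeze[i]:
            return np.arange(1, 13)
        rel = np.mod(month_mid_doy - thaw[i], DAYS_PER_YEAR)
        months = np.where(rel < length[i])[0] + 1
        return months if len(months) else np.arange(1, 13)

    rows = []
    for r in range(cfg.n_records):
        # First pass guarantees both pathways for every sampled type.
        if r < 2 * len(eligible_types):
            s = r % len(eligible_types)
            pathway = "diffusion" if r < len(eligible_types) else "ebullition"
        else:
            s = int(rng.integers(cfg.n_sites))
            pathway = "diffusion" if rng.random() < 674 / 881 else "ebullition"
        i, j = site_cells[s]
        t = site_types[s]
        months = open_months(i)
        month = int(months[rng.integers(len(months))])
        temp = float(monthly_temp.values[month - 1, i, j])
        daytime = rng.random() < cfg.daytime_fraction
        m = cfg.diel_day_multiplier if daytime else 1.0
        mean = cfg.alpha[(t, pathway)] * np.exp(cfg.beta[pathway] * temp) * m

        n_comp = 0
        components = None
        if rng.random() < cfg.component_fraction:
            n_comp = int(rng.integers(2, 4))
            comps = mean * np.exp(rng.normal(0, cfg.sigma_lognoise, n_comp))
            flux = float(np.mean(comps))
            components = [float(c) for c in comps]
        else:
            flux = float(mean * np.exp(rng.normal(0, cfg.sigma_lognoise))) \
                if cfg.sigma_lognoise else float(mean)

        rows.append(
            {
                "record_id": r,
                "site_id": f"site{s:04d}",
                "lat": float(lat[i]),
                "lon": float(lon[j]),
                "lake_type": t if rng.random() < cfg.explicit_label_fraction else None,
                "lake_area_class": "small",
                "pathway": pathway,
                "flux": flux,
                "month": month,
                "sampling_window": "daytime" if daytime else "24h",
                "air_temp_obs": temp,
                "method": "direct",
                "system_class": "lake",
                "n_underlying": max(1, n_comp),
                "components": components,
                "diel_corrected": False,
                "true_lake_type": t,
                "true_expected_flux": mean,
            }
        )
    df = pd.DataFrame(rows)

    # Plant contamination in disjoint subsets of a shuffled index.
    order = rng.permutation(len(df))
    n_ind = int(round(cfg.indirect_fraction * len(df)))
    n_bvr = int(round(cfg.beaver_pond_fraction * len(df)))
    n_missing = int(round(cfg.missing_metadata_fraction * len(df)))
    n_mp, n_mm = n_missing // 3, n_missing // 3
    n_mw = n_missing - n_mp - n_mm
    pos = 0
    df.loc[df.index[order[pos:pos + n_ind]], "method"] = "indirect"; pos += n_ind
    df.loc[df.index[order[pos:pos + n_bvr]], "system_class"] = "beaver_pond"; pos += n_bvr
    df.loc[df.index[order[pos:pos + n_mp]], "pathway"] = None; pos += n_mp
    df.loc[df.index[order[pos:pos + n_mm]], "month"] = np.nan; pos += n_mm
    df.loc[df.index[order[pos:pos + n_mw]], "sampling_window"] = None
    return df


def generate_world(cfg: GeneratorConfig | None = None) -> SyntheticWorld:
    """Generate every pipeline input from one configuration."""
    cfg = cfg or GeneratorConfig()
    layers, monthly_temp, true_map = generate_geophysical_layers(cfg)
    phenology = generate_phenology(cfg)
    primary, small, river, reservoir, large_cells, ice_mask = generate_area_sources(cfg)
    records = generate_flux_records(cfg, monthly_temp, true_map)
    return SyntheticWorld(
        cfg=cfg,
        layers=layers,
        monthly_temp=monthly_temp,
        true_type_map=true_map,
        phenology=phenology,
        primary_area=primary,
        small_lake_area=small,
        river_mask=river,
        reservoir_mask=reservoir,
        large_lake_cells=large_cells,
        ice_phenology_mask=ice_mask,
        records=records,
    )


def small_world_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """A reduced world (narrow longitude band, fewer records) for fast runs."""
    base = dict(
        seed=seed, n_sites=120, n_records=400,
        lat_min=-35.0, lat_max=80.0, lon_min=0.0, lon_max=3.0,
    )
    base.update(overrides)
    return GeneratorConfig(**base)
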