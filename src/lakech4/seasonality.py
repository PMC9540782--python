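"""Temperature-driven flux seasonality.

Most flux measurements come from the warm season; applying them year-round
would overestimate annual emissions. An exponential flux-temperature model
ln(F) = a + b*T, fitted per pathway on the corrected compilation, projects
every measurement through the seasonal air-temperature cycle of its site to
monthly-mean daily fluxes, which are aggregated per type x pathway x month
and interpolated to a 365-day curve with a periodic cubic spline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import xarray as xr
from scipy.interpolate import CubicSpline

from .constants import (
    DAYS_PER_YEAR,
    EMISSION_RATE_ALIASES,
    MONTH_MIDPOINT_DOY,
    N_MONTHS,
    PATHWAYS,
)

MIN_FIT_RECORDS = 10


class FitRefusedError(ValueError):
    """Too few usable records, or a degenerate design, for the flux fit."""


@dataclass(frozen=True)
class TempFluxModel:
    """Exponential flux-temperature model ln(F) = intercept + slope * T.

    ``slope`` is the temperature sensitivity b (degC-1); the 95 % confidence
    interval of b and the residual standard deviation (ln units) are kept
    for diagnostics and uncertainty use.
    """

    pathway: str
    intercept: float
    slope: float
    n: int
    n_nonpositive: int
    r_squared: float
    resid_sigma: float
    slope_ci: tuple[float, float]


def fit_temp_flux(
    records: pd.DataFrame, pathway: str, min_records: int = MIN_FIT_RECORDS
) -> TempFluxModel:
    """OLS of ln(flux) on observation air temperature for one pathway.

    Non-positive fluxes cannot enter the log fit; they are excluded and
    counted. Fewer than ``min_records`` usable records, or a single unique
    temperature, refuses the fit.
    """
    sub = records[records["pathway"] == pathway]
    sub = sub[np.isfinite(sub["air_temp_obs"].astype(float))]
    positive = sub[sub["flux"] > 0]
    n_nonpos = len(sub) - len(positive)
    if len(positive) < min_records:
        raise FitRefusedError(
            f"{pathway}: {len(positive)} usable records < {min_records}"
        )
    temp = positive["air_temp_obs"].astype(float).values
    if np.ptp(temp) == 0:
        raise FitRefusedError(f"{pathway}: all records at one temperature")
    y = np.log(positive["flux"].astype(float).values)
    res = sm.OLS(y, sm.add_constant(temp)).fit()
    ci = res.conf_int(alpha=0.05)
    return TempFluxModel(
        pathway=pathway,
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        n=len(positive),
        n_nonpositive=n_nonpos,
        r_squared=float(res.rsquared),
        resid_sigma=float(np.sqrt(res.scale)),
        slope_ci=(float(ci[1, 0]), float(ci[1, 1])),
    )


def project_to_months(
    flux: float, obs_month: int, slope: float, site_monthly_temp: np.ndarray
) -> np.ndarray:
    """Project one corrected flux through the site's annual temperature cycle.

    flux(m) = flux * exp(b * (T_m - T_obs_month)) where T_obs_month is the
    site's climatological temperature for the measurement month, so the
    measurement month returns the corrected flux exactly.
    """
    temps = np.asarray(site_monthly_temp, dtype=float)
    if temps.shape != (N_MONTHS,):
        raise ValueError("site_monthly_temp must have 12 values")
    t_obs = temps[int(obs_month) - 1]
    return float(flux) * np.exp(slope * (temps - t_obs))


def project_records(
    records: pd.DataFrame,
    models: dict[str, TempFluxModel],
    monthly_temp: xr.DataArray,
) -> pd.DataFrame:
    """Monthly-mean daily fluxes for every record (long table).

    ``monthly_temp`` is the (month, lat, lon) climatology; each record uses
    the cycle of its containing cell. Records outside the climatology domain
    are skipped with a log-level reason. Returns columns
    [record_id, lake_type, pathway, month, flux_monthly].
    """
    lat = monthly_temp["lat"].values
    lon = monthly_temp["lon"].values
    rows = []
    for _, row in records.iterrows():
        i = int(np.argmin(np.abs(lat - row["lat"])))
        j = int(np.argmin(np.abs(lon - row["lon"])))
        if abs(lat[i] - row["lat"]) > 0.5 or abs(lon[j] - row["lon"]) > 0.5:
            continue
        temps = monthly_temp.values[:, i, j]
        slope = models[row["pathway"]].slope
        monthly = project_to_months(row["flux"], int(row["month"]), slope, temps)
        for m in range(N_MONTHS):
            rows.append(
                (row["record_id"], row["lake_type"], row["pathway"], m + 1, monthly[m])
            )
    return pd.DataFrame(
        rows, columns=["record_id", "lake_type", "pathway", "month", "flux_monthly"]
    )


def aggregate_monthly(
    projected: pd.DataFrame,
    required_types: list[str] | None = None,
    aliases: dict[str, str] = EMISSION_RATE_ALIASES,
) -> pd.DataFrame:
    """Mean monthly-mean daily flux per lake type x pathway x month.

    Returns a tidy table [lake_type, pathway, month, flux, n, cv] where
    ``cv`` is the coefficient of variation across records in the stratum
    month. Alias types (organic <- peat pond) are filled from their donor.
    A required type (present in the area grid) with no data after aliasing
    is a hard error listing the gap.
    """
    g = projected.groupby(["lake_type", "pathway", "month"])["flux_monthly"]
    table = g.agg(flux="mean", n="count", sd=lambda v: v.std(ddof=1)).reset_index()
    with np.errstate(invalid="ignore", divide="ignore"):
        table["cv"] = np.where(table["flux"] != 0, table["sd"] / table["flux"].abs(), 0.0)
    table["cv"] = table["cv"].fillna(0.0)
    table = table.drop(columns="sd")

    present = set(table["lake_type"])
    for target, donor in aliases.items():
        if target not in present and donor in present:
            donated = table[table["lake_type"] == donor].copy()
            donated["lake_type"] = target
            donated["n"] = 0  # borrowed rates, no own measurements
            table = pd.concat([table, donated], ignore_index=True)
            present.add(target)
    if required_types:
        missing = [t for t in required_types if t not in present]
        if missing:
            raise ValueError(f"no flux data (even via alias) for lake types: {missing}")
    return table.sort_values(["lake_type", "pathway", "month"]).reset_index(drop=True)


def stratum_cv(
    projected: pd.DataFrame, aliases: dict[str, str] = EMISSION_RATE_ALIASES
) -> pd.DataFrame:
    """Per type x pathway coefficient of variation of the stratum mean flux.

    The annual-mean projected flux of each record is the stratum's sampling
    unit; CV of the stratum mean = (sd / sqrt(n)) / mean. Used by the
    uncertainty module as the flux-variability component. Alias strata
    inherit their donor's CV.
    """
    per_record = (
        projected.groupby(["lake_type", "pathway", "record_id"])["flux_monthly"]
        .mean()
        .reset_index()
    )
    g = per_record.groupby(["lake_type", "pathway"])["flux_monthly"]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count").reset_index()
    out["sd"] = out["sd"].fillna(0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["cv_mean"] = np.where(
            out["mean"] != 0, out["sd"] / np.sqrt(out["n"]) / out["mean"].abs(), 0.0
        )
    present = set(out["lake_type"])
    for target, donor in aliases.items():
        if target not in present and donor in present:
            donated = out[out["lake_type"] == donor].copy()
            donated["lake_type"] = target
            out = pd.concat([out, donated], ignore_index=True)
    return out[["lake_type", "pathway", "mean", "n", "cv_mean"]]


def spline_to_daily(table: pd.DataFrame) -> xr.DataArray:
    """Interpolate monthly anchor fluxes to a 365-day periodic curve.

    Anchors sit at uniform month midpoints; a periodic cubic spline closes
    the annual cycle. Negative values on ebullition curves (a spline
    overshoot artefact; bubbles cannot flow backwards) are clipped to zero.
    Returns a DataArray (lake_type, pathway, dayofyear).
    """
    types = sorted(table["lake_type"].unique())
    doy = np.arange(1, DAYS_PER_YEAR + 1, dtype=float)
    out = np.full((len(types), len(PATHWAYS), DAYS_PER_YEAR), np.nan)
    x = np.append(MONTH_MIDPOINT_DOY, MONTH_MIDPOINT_DOY[0] + DAYS_PER_YEAR)
    for it, t in enumerate(types):
        for ip, p in enumerate(PATHWAYS):
            sub = table[(table["lake_type"] == t) & (table["pathway"] == p)]
            if len(sub) == 0:
                continue
            if len(sub) != N_MONTHS:
                raise ValueError(f"{t}/{p}: need 12 monthly anchors, got {len(sub)}")
            y = sub.sort_values("month")["flux"].values
            spline = CubicSpline(x, np.append(y, y[0]), bc_type="periodic")
            vals = spline(np.mod(doy - x[0], DAYS_PER_YEAR) + x[0])
            if p == "ebullition":
                vals = np.clip(vals, 0.0, None)
            out[it, ip] = vals
    return xr.DataArray(
        out,
        coords={"lake_type": types, "pathway": list(PATHWAYS), "dayofyear": np.arange(1, DAYS_PER_YEAR + 1)},
        dims=("lake_type", "pathway", "dayofyear"),
        name="daily_flux",
        attrs={"units": "mg CH4 m-2 d-1"},
    )
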