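"""Flux-measurement compilation: ingest, filter, disaggregate, correct, label.

The compilation is a table of aggregated CH4 flux measurements (mg m-2 d-1)
with sampling metadata. Records are held in a pandas DataFrame with the
fixed schema below; optional fields that fail to parse become missing values
rather than errors.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import xarray as xr

from .constants import DIEL_SCALING_FACTOR, MONTH_NAMES, CODE_TYPES, LAKE_TYPES

logger = logging.getLogger(__name__)

#: Columns that must exist in a compilation CSV (values may still be missing).
REQUIRED_COLUMNS = (
    "site_id",
    "lat",
    "lon",
    "pathway",
    "flux",
    "month",
    "sampling_window",
    "method",
)

#: Optional columns, created as missing when absent.
OPTIONAL_COLUMNS = (
    "record_id",
    "lake_type",
    "lake_area_class",
    "air_temp_obs",
    "system_class",
    "n_underlying",
    "components",
)

# Rejection reasons, in filtering precedence order.
REASON_INDIRECT = "indirect"
REASON_BEAVER_POND = "beaver_pond"
REASON_MISSING_PATHWAY = "missing_pathway"
REASON_MISSING_MONTH = "missing_month"
REASON_MISSING_WINDOW = "missing_window"
REASON_OUT_OF_DOMAIN = "out_of_domain"
REASON_UNASSIGNABLE_TYPE = "unassignable_type"


class SchemaError(ValueError):
    """A required compilation column is absent."""


def _parse_month(value) -> float:
    if pd.isna(value):
        return np.nan
    if isinstance(value, str):
        name = value.strip().lower()
        for i, m in enumerate(MONTH_NAMES, start=1):
            if m.startswith(name[:3]) and len(name) >= 3:
                return float(i)
        try:
            value = float(name)
        except ValueError:
            return np.nan
    try:
        month = float(value)
    except (TypeError, ValueError):
        return np.nan
    return month if 1 <= month <= 12 else np.nan


def _parse_components(value) -> list[float] | None:
    if pd.isna(value) or value == "":
        return None
    try:
        parts = [float(p) for p in str(value).split(";") if p.strip() != ""]
    except ValueError:
        return None
    return parts or None


def read_compilation(path) -> pd.DataFrame:
    """Read a compilation CSV into the canonical record table.

    Raises :class:`SchemaError` naming the first missing required column.
    Unparseable optional values become missing, never errors.
    """
    df = pd.read_csv(path, dtype={"components": "string", "month": "object"})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"required column missing: {col!r}")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = pd.NA
    if df["record_id"].isna().all():
        df["record_id"] = np.arange(len(df))
    df["month"] = df["month"].map(_parse_month)
    df["flux"] = pd.to_numeric(df["flux"], errors="coerce")
    df["air_temp_obs"] = pd.to_numeric(df["air_temp_obs"], errors="coerce")
    df["components"] = df["components"].map(_parse_components)
    df["n_underlying"] = pd.to_numeric(df["n_underlying"], errors="coerce").fillna(1)
    df["system_class"] = df["system_class"].fillna("lake")
    df["diel_corrected"] = False
    return df


def write_compilation(records: pd.DataFrame, path) -> None:
    """Write the record table back to CSV (component lists as 'a;b;c')."""
    out = records.copy()
    if "components" in out.columns:
        out["components"] = out["components"].map(
            lambda c: ";".join(f"{v:g}" for v in c) if isinstance(c, list) else ""
        )
    out.to_csv(path, index=False)


def filter_records(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, rejected) per the compilation filter.

    Kept records are direct-method lake measurements with pathway, month and
    sampling window all present. Each rejected record carries exactly one
    primary ``reason``, assigned in precedence order: indirect method,
    beaver pond, missing pathway, missing month, missing sampling window.
    """
    reason = pd.Series(pd.NA, index=records.index, dtype="string")
    method = records["method"].astype("string").str.lower()
    system = records["system_class"].astype("string").str.lower()
    pathway = records["pathway"].astype("string").str.lower()
    window = records["sampling_window"].astype("string").str.lower()

    checks = [
        (method == "indirect", REASON_INDIRECT),
        (system == "beaver_pond", REASON_BEAVER_POND),
        (pathway.isna() | (pathway == ""), REASON_MISSING_PATHWAY),
        (records["month"].isna(), REASON_MISSING_MONTH),
        (window.isna() | (window == ""), REASON_MISSING_WINDOW),
    ]
    for cond, tag in checks:
        reason = reason.mask(cond.fillna(True) & reason.isna(), tag)

    rejected = records[reason.notna()].copy()
    rejected["reason"] = reason[reason.notna()]
    kept = records[reason.isna()].copy()
    return kept, rejected


def disaggregate(records: pd.DataFrame, mean_tolerance: float = 0.01) -> pd.DataFrame:
    """Expand records carrying component flux lists into one record each.

    A record whose ``components`` column lists k individual fluxes is
    replaced by k records inheriting all metadata; a component mean
    differing from the reported flux by more than ``mean_tolerance``
    (relative) is logged as a warning, and the components are used anyway.
    """
    has = records["components"].map(lambda c: isinstance(c, list))
    if not has.any():
        return records.copy()
    plain = records[~has]
    expanded = []
    for _, row in records[has].iterrows():
        comps = row["components"]
        mean = float(np.mean(comps))
        if row["flux"] and abs(mean - row["flux"]) > mean_tolerance * max(abs(row["flux"]), 1e-12):
            logger.warning(
                "record %s: component mean %.4g differs from reported flux %.4g; "
                "using components",
                row["record_id"], mean, row["flux"],
            )
        for j, comp in enumerate(comps):
            new = row.copy()
            new["flux"] = comp
            new["components"] = None
            new["n_underlying"] = 1
            new["record_id"] = f"{row['record_id']}.{j}"
            expanded.append(new)
    out = pd.concat([plain, pd.DataFrame(expanded)], ignore_index=True)
    return out


def apply_diel_correction(
    records: pd.DataFrame, factor: float = DIEL_SCALING_FACTOR
) -> pd.DataFrame:
    """Convert daytime-only fluxes to 24-h means by the diel scaling factor.

    Daytime here means sampling confined to 07:00-20:00 local time; such
    fluxes are multiplied by ``factor`` (default 0.7). 24-h records pass
    unchanged. Re-application is refused via the ``diel_corrected`` flag,
    and a missing sampling window (which filtering should have removed) is a
    contract violation.
    """
    if records["diel_corrected"].any():
        raise ValueError("diel correction already applied; refusing to reapply")
    window = records["sampling_window"].astype("string").str.lower()
    if window.isna().any() or (window == "").any():
        raise ValueError("record with missing sampling window reached diel correction")
    out = records.copy()
    daytime = window == "daytime"
    out.loc[daytime, "flux"] = out.loc[daytime, "flux"] * factor
    out["diel_corrected"] = True
    return out


def assign_lake_type(
    records: pd.DataFrame, type_map: xr.DataArray
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Label each record with its ecoclimatic lake type.

    An explicit ``lake_type`` label wins; otherwise the record takes the
    classified type of the grid cell containing its coordinates. Records
    outside the grid domain, or with neither label nor usable coordinates,
    are rejected with a reason.
    """
    lat = type_map["lat"].values
    lon = type_map["lon"].values
    res_lat = lat[1] - lat[0] if len(lat) > 1 else 0.25
    res_lon = lon[1] - lon[0] if len(lon) > 1 else 0.25

    labels = []
    reasons = []
    for _, row in records.iterrows():
        explicit = row.get("lake_type")
        if isinstance(explicit, str) and explicit in LAKE_TYPES:
            labels.append(explicit)
            reasons.append(None)
            continue
        rlat, rlon = row["lat"], row["lon"]
        if pd.isna(rlat) or pd.isna(rlon):
            labels.append(None)
            reasons.append(REASON_UNASSIGNABLE_TYPE)
            continue
        i = int(np.floor((rlat - (lat[0] - res_lat / 2)) / res_lat))
        j = int(np.floor((rlon - (lon[0] - res_lon / 2)) / res_lon))
        if not (0 <= i < len(lat) and 0 <= j < len(lon)):
            labels.append(None)
            reasons.append(REASON_OUT_OF_DOMAIN)
            continue
        labels.append(CODE_TYPES[int(type_map.values[i, j])])
        reasons.append(None)

    records = records.copy()
    records["lake_type"] = labels
    ok = pd.Series([r is None for r in reasons], index=records.index)
    rejected = records[~ok].copy()
    rejected["reason"] = [r for r in reasons if r is not None]
    return records[ok], rejected
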