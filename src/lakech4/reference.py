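"""Published reference values for the global lake CH4 inventory.

These are the printed per-type areas, emission-season lengths, mean
emission-season fluxes and annual totals of the observation-driven global
upscaling this package implements, together with the global CH4 budget
numbers used in the freshwater-substitution arithmetic. They serve as
cross-check targets and as parameters for reference fixtures; nothing in the
pipeline computes *from* them except the explicitly labelled closure checks.
"""

from __future__ import annotations

import pandas as pd

# Columns: areas in 1e3 km2 split at 5,000 km2 lake size; seasons in days;
# fluxes in mg CH4 m-2 d-1 (means over the emission season); annual totals in
# Tg CH4 yr-1. n_* are counts of aggregated flux measurements per pathway.
_ROWS = [
    # type, n_diff, n_ebul, area_small, area_large, season_small, season_large,
    # flux_small, flux_large, annual_tg
    ("thermokarst", 70, 17, 234.0, 0.0, 107.0, 0.0, 80.0, 0.0, 2.0),
    ("glacial_postglacial", 66, 30, 357.0, 0.0, 117.0, 0.0, 31.0, 0.0, 1.3),
    ("peat_pond", 42, 1, 69.0, 0.0, 167.0, 0.0, 94.0, 0.0, 1.1),
    ("organic", 0, 0, 49.0, 0.0, 183.0, 0.0, 89.0, 0.0, 0.8),
    ("other_boreal", 130, 4, 407.0, 218.0, 152.0, 135.0, 65.0, 7.0, 4.2),
    ("temperate", 280, 121, 427.0, 674.0, 289.0, 206.0, 65.0, 9.0, 9.3),
    ("tropical_subtropical", 86, 34, 204.0, 167.0, 363.0, 365.0, 235.0, 23.0, 18.8),
]

_COLUMNS = [
    "lake_type", "n_diffusion", "n_ebullition",
    "area_small_1e3km2", "area_large_1e3km2",
    "season_small_days", "season_large_days",
    "flux_small_mg_m2_d", "flux_large_mg_m2_d",
    "annual_tg",
]


def reference_inventory() -> pd.DataFrame:
    """Per-type reference table of the published global inventory."""
    return pd.DataFrame(_ROWS, columns=_COLUMNS).set_index("lake_type")


# Global aggregates (Tg CH4 yr-1 unless noted).
GLOBAL_TOTALS = {
    "diffusion": 14.1,
    "ebullition": 23.4,
    "d_plus_e": 37.5,
    "iceout_spring": 3.1,
    "fall_turnover": 1.0,
    "total": 41.6,
    "uncertainty": 18.3,
    "large_lake_share": 2.9,
}

# Global lake areas (1e3 km2).
GLOBAL_AREAS = {
    "primary_source": 2640.0,       # large-lake polygon inventory
    "small_lake_source": 166.0,     # remote-sensing small-lake augmentation
    "total": 2806.0,
    "small_class": 1747.0,
    "large_class": 1059.0,
}

# Global CH4 budget arithmetic (Tg CH4 yr-1): replacing the prior non-wetland
# freshwater source with rivers + reservoirs + this lake estimate.
BUDGET = {
    "bottom_up": 737.0,
    "top_down": 576.0,
    "imbalance": 112.0,
    "freshwater_prior": 159.0,
    "rivers": 27.0,
    "reservoirs": 10.0,
    "lakes": 42.0,
}
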