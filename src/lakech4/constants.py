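"""Shared vocabulary, calendar and unit conventions for the lake CH4 pipeline.

All unit conversions live here so the mg m-2 d-1 -> Tg yr-1 chain cannot
drift between modules.
"""

from __future__ import annotations

import numpy as np

# The seven ecoclimatic lake types, in classification-precedence order.
LAKE_TYPES: tuple[str, ...] = (
    "thermokarst",
    "glacial_postglacial",
    "peat_pond",
    "organic",
    "other_boreal",
    "temperate",
    "tropical_subtropical",
)
TYPE_CODES: dict[str, int] = {t: i for i, t in enumerate(LAKE_TYPES)}
CODE_TYPES: dict[int, str] = {i: t for t, i in TYPE_CODES.items()}

# Types without their own flux measurements borrow emission rates from a donor
# type (organic lakes use peat-pond rates).
EMISSION_RATE_ALIASES: dict[str, str] = {"organic": "peat_pond"}

PATHWAYS: tuple[str, ...] = ("diffusion", "ebullition")
EPISODIC_PATHWAYS: tuple[str, ...] = ("iceout_spring", "fall_turnover")
ALL_PATHWAYS: tuple[str, ...] = PATHWAYS + EPISODIC_PATHWAYS

SIZE_CLASSES: tuple[str, ...] = ("small", "large")  # <5,000 km2 / >=5,000 km2
LARGE_LAKE_THRESHOLD_KM2 = 5_000.0
# Lakes at or above this area have their own satellite ice-phenology record.
ICE_PHENOLOGY_MIN_LAKE_KM2 = 50.0

# Permafrost extent categories: continuous, discontinuous, sporadic, isolated.
PERMAFROST_CATEGORIES: tuple[str, ...] = ("none", "C", "D", "S", "I")
PERMAFROST_CODES: dict[str, int] = {c: i for i, c in enumerate(PERMAFROST_CATEGORIES)}

# 365-day no-leap climatological calendar.
DAYS_PER_YEAR = 365
N_MONTHS = 12
DOY = np.arange(1, DAYS_PER_YEAR + 1)
# Monthly anchors at uniform month midpoints on the 365-day year, rounded to
# whole days (16, 46, 76, ...); periodic boundary for spline interpolation,
# so the daily curve passes through the monthly anchors exactly.
MONTH_MIDPOINT_DOY = np.round(
    (np.arange(N_MONTHS) + 0.5) * DAYS_PER_YEAR / N_MONTHS + 0.5
)

MONTH_NAMES = (
    "january", "february", "march", "april", "may", "june",
    "july", "august", "september", "october", "november", "december",
)

EARTH_RADIUS_KM = 6371.0
GRID_RESOLUTION_DEG = 0.25

# Unit chain: flux [mg CH4 m-2 d-1] x area [km2] x duration [d]
#   mg m-2 -> mg km-2 : x1e6 ; mg -> Tg : x1e-15  => x1e-9 per km2-day.
MG_M2_DAY_TIMES_KM2_TO_TG_PER_DAY = 1e-9
# Same chain to grams per day (per-cell gridded fields).
MG_M2_DAY_TIMES_KM2_TO_G_PER_DAY = 1e3
G_TO_TG = 1e-12

# Diel scaling: daytime-only chamber fluxes overestimate the 24-h mean.
DIEL_SCALING_FACTOR = 0.7
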