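import numpy as np
import pandas as pd
import pytest
import xarray as xr

from lakech4.constants import DAYS_PER_YEAR, LAKE_TYPES, SIZE_CLASSES, TYPE_CODES
from lakech4.engine import (
    aggregate,
    annual_type_total,
    compute_daily_emissions,
    revised_budget_imbalance,
)
from lakech4.reference import reference_inventory
from lakech4.seasonality import spline_to_daily


class TestAnnualTypeTotal:
    def test_thermokarst_row(self):
        """234e3 km2 at 80 mg m-2 d-1 over 107 days is 2.0 Tg."""
        total = annual_type_total(234e3, 0.0, 80.0, 0.0, 107.0, 0.0)
        assert round(total, 1) == 2.0

    def test_temperate_row_with_large_lakes(self):
        total = annual_type_total(427e3, 674e3, 65.0, 9.0, 289.0, 206.0)
        assert round(total, 1) == 9.3

    def test_zero_area_gives_zero(self):
        assert annual_type_total(0.0, 0.0, 100.0, 10.0, 365.0, 365.0) == 0.0

    def test_unit_chain(self):
        # 1 km2 at 1 mg m-2 d-1 for 1 day = 1e6 mg = 1e-9 Tg
        assert annual_type_total(1.0, 0.0, 1.0, 0.0, 1.0, 0.0) == pytest.approx(1e-9)


def test_budget_substitution():
    freshwater, imbalance = revised_budget_imbalance(112.0, 159.0, 27.0, 10.0, 42.0)
    assert freshwater == 79.0
    assert imbalance == 32.0


def _single_cell_inputs(flux=12.0, area_small=5.0, area_large=0.0,
                        thaw=100.0, length=200.0, no_freeze=False,
                        lake_type="temperate"):
    lat, lon = [50.125], [0.125]
    coords = {"lat": lat, "lon": lon}
    code = TYPE_CODES[lake_type]
    area = np.zeros((len(LAKE_TYPES), len(SIZE_CLASSES), 1, 1))
    area[code, 0, 0, 0] = area_small
    area[code, 1, 0, 0] = area_large
    areas = xr.Dataset(
        {
            "lake_area": (("lake_type", "size_class", "lat", "lon"), area),
            "cell_area": (("lat", "lon"), np.array([[600.0]])),
        },
        coords={"lake_type": list(LAKE_TYPES), "size_class": list(SIZE_CLASSES), **coords},
    )
    table = pd.DataFrame(
        {
            "lake_type": lake_type,
            "pathway": "diffusion",
            "month": np.arange(1, 13),
            "flux": flux,
            "n": 1,
            "cv": 0.0,
        }
    )
    ebul = table.copy()
    ebul["pathway"] = "ebullition"
    ebul["flux"] = 0.0
    curves = spline_to_daily(pd.concat([table, ebul], ignore_index=True))
    freeze = (thaw + length - 1) % DAYS_PER_YEAR + 1
    season = xr.Dataset(
        {
            "thaw_doy": (("lat", "lon"), np.array([[thaw]])),
            "freeze_doy": (("lat", "lon"), np.array([[freeze]])),
            "season_length": (("lat", "lon"), np.array([[float(length)]])),
            "no_freeze": (("lat", "lon"), np.array([[no_freeze]])),
            "source": (("lat", "lon"), np.array([[0]], dtype=np.int8)),
        },
        coords=coords,
    )
    type_map = xr.DataArray(np.array([[code]], dtype=np.int16), coords=coords,
                            dims=("lat", "lon"))
    return areas, curves, season, type_map


class TestComputeDailyEmissions:
    def test_single_cell_annual_total_matches_brute_force(self):
        """Constant flux c, area A, season L gives annual total c*A*L."""
        areas, curves, season, type_map = _single_cell_inputs()
        em = compute_daily_emissions(areas, curves, season, type_map)
        got = float(em["flux_total"].sum())  # g/yr
        # brute-force day loop oracle
        expected = 0.0
        for day in range(1, DAYS_PER_YEAR + 1):
            if (day - 100) % 365 < 200:
                expected += 12.0 * 5.0 * 1e3
        assert got == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(12.0 * 5.0 * 200 * 1e3)

    def test_days_outside_season_are_exactly_zero(self):
        areas, curves, season, type_map = _single_cell_inputs()
        em = compute_daily_emissions(areas, curves, season, type_map)
        daily = em["flux_total"].values[:, 0, 0]
        open_days = (np.arange(1, 366) - 100) % 365 < 200
        assert (daily[~open_days] == 0).all()
        assert (daily[open_days] > 0).all()

    def test_scale_large_zero_removes_large_lake_contribution(self):
        areas, curves, season, type_map = _single_cell_inputs(area_small=0.0,
                                                              area_large=7.0)
        em = compute_daily_emissions(areas, curves, season, type_map, scale_large=0.0)
        assert float(em["flux_total"].sum()) == 0.0

    def test_large_lakes_scaled_by_factor(self):
        areas, curves, season, type_map = _single_cell_inputs(area_small=0.0,
                                                              area_large=7.0)
        em10 = compute_daily_emissions(areas, curves, season, type_map, scale_large=0.1)
        em25 = compute_daily_emissions(areas, curves, season, type_map, scale_large=0.25)
        assert float(em25["flux_total"].sum()) == pytest.approx(
            2.5 * float(em10["flux_total"].sum()), rel=1e-12
        )

    def test_missing_curve_for_present_type_is_hard_error(self):
        areas, _, season, type_map = _single_cell_inputs(lake_type="thermokarst")
        _, temperate_curves, _, _ = _single_cell_inputs(lake_type="temperate")
        with pytest.raises(ValueError, match="thermokarst"):
            compute_daily_emissions(areas, temperate_curves, season, type_map)

    def test_linearity_in_area(self, small_result):
        report = small_result.report
        doubled = small_result.emissions * 2
        doubled.attrs = small_result.emissions.attrs
        rep2 = aggregate(doubled, small_result.type_map, small_result.areas)
        assert rep2.global_total == pytest.approx(2 * report.global_total, rel=1e-12)


class TestAggregate:
    def test_single_nonzero_cell_owns_its_zone(self):
        areas, curves, season, type_map = _single_cell_inputs()
        em = compute_daily_emissions(areas, curves, season, type_map)
        report = aggregate(em, type_map, areas)
        assert len(report.zonal) == 1
        assert report.zonal["zone_south"].iloc[0] == 50.0
        assert report.zonal["total"].iloc[0] == pytest.approx(report.global_total)

    def test_closure_global_equals_types_pathways_zones(self, small_result):
        report = small_result.report
        assert sum(report.type_totals.values()) == pytest.approx(
            report.global_total, rel=1e-9
        )
        assert sum(report.pathway_totals.values()) == pytest.approx(
            report.global_total, rel=1e-9
        )
        assert report.zonal["total"].sum() == pytest.approx(
            report.global_total, rel=1e-9
        )

    def test_per_lake_map_masks_lakeless_cells(self, small_result):
        per_lake = small_result.report.annual_per_lake_g_m2
        assert np.isfinite(per_lake.values).all()


def test_reference_type_totals_reproduce_printed_column():
    """area x flux x season reproduces every published per-type Tg total."""
    ref = reference_inventory()
    for t, row in ref.iterrows():
        total = annual_type_total(
            row["area_small_1e3km2"] * 1e3,
            row["area_large_1e3km2"] * 1e3,
            row["flux_small_mg_m2_d"],
            row["flux_large_mg_m2_d"] or 0.0,
            row["season_small_days"],
            row["season_large_days"] or 0.0,
        )
        assert round(total, 1) == row["annual_tg"], t
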