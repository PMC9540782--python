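import numpy as np
import pandas as pd
import pytest

from lakech4.constants import MONTH_MIDPOINT_DOY
from lakech4.seasonality import (
    FitRefusedError,
    aggregate_monthly,
    fit_temp_flux,
    project_to_months,
    spline_to_daily,
)


def _fit_records(n, alpha, beta, sigma, rng=None, pathway="ebullition"):
    temps = np.linspace(0, 25, n)
    noise = rng.normal(0, sigma, n) if sigma else np.zeros(n)
    flux = alpha * np.exp(beta * temps + noise)
    return pd.DataFrame(
        {"pathway": pathway, "flux": flux, "air_temp_obs": temps}
    )


class TestFitTempFlux:
    def test_noise_free_slope_recovered_exactly(self):
        model = fit_temp_flux(_fit_records(50, 20.0, 0.11, 0.0), "ebullition")
        assert model.slope == pytest.approx(0.11, abs=1e-10)
        assert model.intercept == pytest.approx(np.log(20.0), abs=1e-10)
        assert model.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_noisy_recovery_within_confidence_interval(self):
        rng = np.random.default_rng(11)
        model = fit_temp_flux(_fit_records(500, 20.0, 0.11, 0.3, rng), "ebullition")
        lo, hi = model.slope_ci
        assert lo <= 0.11 <= hi

    def test_too_few_records_refused(self):
        with pytest.raises(FitRefusedError, match="< 10"):
            fit_temp_flux(_fit_records(5, 20.0, 0.1, 0.0), "ebullition")

    def test_single_temperature_design_refused(self):
        df = pd.DataFrame(
            {"pathway": "diffusion", "flux": np.full(20, 5.0),
             "air_temp_obs": np.full(20, 10.0)}
        )
        with pytest.raises(FitRefusedError, match="one temperature"):
            fit_temp_flux(df, "diffusion")

    def test_nonpositive_fluxes_excluded_and_counted(self):
        df = _fit_records(20, 20.0, 0.1, 0.0, pathway="diffusion")
        df.loc[:4, "flux"] = -1.0
        model = fit_temp_flux(df, "diffusion")
        assert model.n == 15
        assert model.n_nonpositive == 5


class TestProjection:
    temps = 10 + 8 * np.cos(2 * np.pi * (np.arange(12) - 6) / 12)

    def test_zero_slope_gives_constant_months(self):
        out = project_to_months(42.0, 3, 0.0, self.temps)
        np.testing.assert_allclose(out, 42.0)

    def test_measurement_month_returns_corrected_flux_exactly(self):
        out = project_to_months(42.0, 5, 0.13, self.temps)
        assert out[4] == 42.0

    def test_ten_degree_step_gives_factor_e(self):
        temps = np.zeros(12)
        temps[6] = 10.0
        out = project_to_months(5.0, 1, 0.1, temps)
        assert out[6] / out[0] == pytest.approx(np.e, rel=1e-12)

    def test_warming_a_month_strictly_increases_its_flux(self):
        base = project_to_months(42.0, 3, 0.1, self.temps)
        for k in range(12):
            if k == 2:  # observation month stays anchored at the corrected flux
                continue
            warmer = self.temps.copy()
            warmer[k] += 2.0
            out = project_to_months(42.0, 3, 0.1, warmer)
            assert out[k] > base[k]
            assert out[2] == base[2] == 42.0


class TestAggregateMonthly:
    def _projected(self, rows):
        return pd.DataFrame(
            rows, columns=["record_id", "lake_type", "pathway", "month", "flux_monthly"]
        )

    def test_single_record_table_equals_its_values(self):
        rows = [(0, "temperate", "diffusion", m, float(m)) for m in range(1, 13)]
        table = aggregate_monthly(self._projected(rows))
        np.testing.assert_allclose(table.sort_values("month")["flux"], np.arange(1, 13))

    def test_two_records_average(self):
        rows = [(0, "temperate", "diffusion", 1, 10.0),
                (1, "temperate", "diffusion", 1, 30.0)]
        table = aggregate_monthly(self._projected(rows))
        assert table["flux"].iloc[0] == 20.0
        assert table["n"].iloc[0] == 2

    def test_organic_filled_from_peat_pond_alias(self):
        rows = [(0, "peat_pond", "ebullition", m, 7.0) for m in range(1, 13)]
        table = aggregate_monthly(self._projected(rows), required_types=["organic"])
        organic = table[table["lake_type"] == "organic"]
        assert len(organic) == 12
        np.testing.assert_allclose(organic["flux"], 7.0)
        assert (organic["n"] == 0).all()

    def test_missing_required_type_is_hard_error(self):
        rows = [(0, "temperate", "diffusion", 1, 10.0)]
        with pytest.raises(ValueError, match="thermokarst"):
            aggregate_monthly(self._projected(rows), required_types=["thermokarst"])

    def test_type_means_recover_generator_truth(self, small_result, small_world):
        """Stratum means match the generator's analytic expectation to 3 SE.

        The generated flux is alpha * exp(beta T) * lognormal(0, sigma); the
        diel-corrected record mean is therefore alpha * exp(beta T) *
        exp(sigma^2 / 2) at each record's own temperature. Comparing in log
        space removes the per-record temperature spread.
        """
        cfg = small_world.cfg
        recs = small_result.records
        sigma = cfg.sigma_lognoise
        for (t, p), grp in recs.groupby(["lake_type", "pathway"]):
            if t == "organic" or len(grp) < 30:
                continue
            expected_log = (
                np.log(cfg.alpha[(t, p)]) + cfg.beta[p] * grp["air_temp_obs"].values
            )
            resid = np.log(grp["flux"].values) - expected_log
            se = sigma / np.sqrt(len(grp))
            assert abs(resid.mean()) < 3 * se + 1e-12


class TestSplineToDaily:
    def _table(self, values, lake_type="temperate", pathway="diffusion"):
        return pd.DataFrame(
            {
                "lake_type": lake_type,
                "pathway": pathway,
                "month": np.arange(1, 13),
                "flux": values,
                "n": 1,
                "cv": 0.0,
            }
        )

    def test_constant_table_gives_constant_curve(self):
        curve = spline_to_daily(self._table(np.full(12, 3.5)))
        np.testing.assert_allclose(curve.values[0, 0], 3.5, rtol=1e-12)

    def test_curve_interpolates_monthly_anchors(self):
        vals = 10 + 5 * np.sin(2 * np.pi * np.arange(12) / 12)
        curve = spline_to_daily(self._table(vals))
        at_anchors = curve.values[0, 0][MONTH_MIDPOINT_DOY.astype(int) - 1]
        np.testing.assert_allclose(at_anchors, vals, rtol=1e-9)

    def test_daily_mean_close_to_monthly_mean_for_smooth_cycle(self):
        vals = 20 + 10 * np.sin(2 * np.pi * np.arange(12) / 12)
        curve = spline_to_daily(self._table(vals))
        assert curve.values[0, 0].mean() == pytest.approx(vals.mean(), rel=0.02)

    def test_negative_ebullition_clipped_to_zero(self):
        vals = np.full(12, 0.5)
        vals[5] = -30.0  # force deep overshoot
        curve = spline_to_daily(self._table(vals, pathway="ebullition"))
        assert curve.sel(pathway="ebullition").values.min() >= 0.0
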