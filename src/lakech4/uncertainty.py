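"""Quadrature propagation of the six uncorrelated uncertainty components.

eps_total^2 = eps_v^2 + eps_t^2 + eps_ai^2 + eps_af^2 + eps_ox^2 + eps_sf^2

eps_v   flux-measurement variability (CV of stratum mean fluxes)
eps_t   temperate/tropical soil-temperature threshold (20.0 +- 2.5 degC)
eps_ai  ice-out accumulation lag (60 +- 15 d)
eps_af  fall-turnover accumulation lag (60 +- 15 d)
eps_ox  oxidation fraction (swept 0.5-0.99)
eps_sf  large-lake emission scaling (swept 0-0.25)

Threshold and lag components are half the absolute spread of the global
total between the two endpoint runs; range components are the standard
deviation of totals over an 11-point sweep; the flux component combines
per-stratum CVs of the mean in quadrature weighted by each stratum's
emission sensitivity. A Monte-Carlo propagation jointly sampling all
parameters is available as an independence cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .constants import DAYS_PER_YEAR, PATHWAYS, TYPE_CODES
from .episodic import EpisodicParams
from .lake_grid import ClassificationThresholds
from .pipeline import PipelineParams, PipelineResult, run_pipeline, stratum_decomposition

COMPONENT_NAMES = ("eps_v", "eps_t", "eps_ai", "eps_af", "eps_ox", "eps_sf")

DEFAULT_SWEEPS = {
    "t_tropical": (17.5, 22.5),
    "lag": (45.0, 75.0),
    "ox_range": (0.5, 0.99),
    "sf_range": (0.0, 0.25),
    "n_sweep": 11,
}


@dataclass(frozen=True)
class UncertaintyComponents:
    """The six components (Tg CH4 yr-1), their quadrature total and shares."""

    eps_v: float
    eps_t: float
    eps_ai: float
    eps_af: float
    eps_ox: float
    eps_sf: float
    total: float
    shares: dict


def combine(components: dict[str, float]) -> UncertaintyComponents:
    """Quadrature-sum named components; shares are eps_i^2 / eps_total^2."""
    vals = {}
    for name in COMPONENT_NAMES:
        v = float(components.get(name, 0.0))
        if v < 0:
            raise ValueError(f"negative uncertainty component {name} = {v}")
        vals[name] = v
    total = float(np.sqrt(sum(v**2 for v in vals.values())))
    shares = {
        name: (v**2 / total**2 if total > 0 else 0.0) for name, v in vals.items()
    }
    return UncertaintyComponents(total=total, shares=shares, **vals)


def half_spread(total_lo: float, total_hi: float) -> float:
    """Endpoint-scenario epsilon: half the absolute spread of the totals."""
    return abs(total_hi - total_lo) / 2.0


def sweep_sd(totals) -> float:
    """Range-scenario epsilon: population sd of totals over the sweep."""
    return float(np.std(np.asarray(totals, float)))


class TotalModel:
    """Global-total response surface linearized over the pipeline's strata.

    Built from one full pipeline run per classification-threshold value, it
    evaluates the global total (Tg yr-1) for any combination of episodic
    parameters, large-lake scaling and per-stratum flux factors in
    microseconds, enabling scenario sweeps and Monte-Carlo draws without
    re-running the gridded engine. D+E totals are exactly linear in the
    flux factors and the large-lake scale; episodic totals are recomputed
    from per-cell season arrays, so lag and oxidation enter exactly.
    """

    def __init__(self, result: PipelineResult):
        self.params = result.params
        dec = stratum_decomposition(result)
        self.strata = dec.set_index(["lake_type", "pathway"])
        season = result.season
        freezing = ~season["no_freeze"].values
        self.cell_length = season["season_length"].values[freezing]
        a_small = result.areas["lake_area"].sel(size_class="small").sum("lake_type").values
        a_large = result.areas["lake_area"].sel(size_class="large").sum("lake_type").values
        self.cell_area_small = a_small[freezing]
        self.cell_area_large = a_large[freezing]
        codes = result.type_map.values[freezing]
        e5 = np.array(
            [result.e5_by_type.get(t, 0.0) for t in TYPE_CODES], dtype=float
        )
        self.cell_e5 = e5[codes]
        self.cell_type_code = codes

    def total(
        self,
        scale_large: float | None = None,
        episodic: EpisodicParams | None = None,
        flux_factors: pd.Series | None = None,
    ) -> float:
        """Global total (Tg yr-1) under the given parameter overrides.

        ``flux_factors`` is a Series indexed by (lake_type, pathway)
        multiplying each stratum's emission rate; ebullition factors also
        scale the cell's episodic source term (E5 is ebullition-derived).
        """
        sf = self.params.scale_large if scale_large is None else scale_large
        ep = episodic or self.params.episodic

        de = 0.0
        for (t, p), row in self.strata.iterrows():
            phi = 1.0 if flux_factors is None else float(flux_factors.get((t, p), 1.0))
            de += phi * (row["small_tg"] + sf * row["large_tg_unit"])

        if flux_factors is None:
            phi_cell = 1.0
        else:
            phi_e = np.ones(len(TYPE_CODES))
            for (t, p), v in flux_factors.items():
                if p == "ebullition":
                    phi_e[TYPE_CODES[t]] = v
            phi_cell = phi_e[self.cell_type_code]

        ice = DAYS_PER_YEAR - self.cell_length
        mass = self.cell_e5 * phi_cell * (
            np.maximum(0.0, ice - ep.lag_spring) * (1 - ep.ox_spring)
            + np.maximum(0.0, self.cell_length - ep.lag_fall) * (1 - ep.ox_fall)
        )  # mg m-2 yr-1 per cell
        area_eff = self.cell_area_small + sf * self.cell_area_large
        episodic_tg = float((mass * area_eff).sum()) * 1e-9
        return de + episodic_tg


def estimate_uncertainty(
    world,
    params: PipelineParams | None = None,
    sweeps: dict | None = None,
    baseline: PipelineResult | None = None,
) -> tuple[UncertaintyComponents, dict]:
    """Scenario (finite-difference) propagation of all six components.

    The classification threshold requires full pipeline re-runs (the type
    map changes); every other component is evaluated on the baseline run's
    linearized total model. Returns the combined components and a detail
    dict with baseline and scenario totals.
    """
    params = params or PipelineParams()
    sw = dict(DEFAULT_SWEEPS)
    if sweeps:
        sw.update(sweeps)

    base = baseline or run_pipeline(world, params)
    model = TotalModel(base)
    base_total = base.report.global_total

    # eps_t: endpoint pipeline runs with the threshold moved.
    t_totals = []
    for t_val in sw["t_tropical"]:
        p = replace(
            params,
            thresholds=replace(params.thresholds, t_tropical=t_val),
        )
        t_totals.append(run_pipeline(world, p).report.global_total)
    eps_t = half_spread(*t_totals)

    ep = params.episodic
    lag_lo, lag_hi = sw["lag"]
    eps_ai = half_spread(
        model.total(episodic=replace(ep, lag_spring=lag_lo)),
        model.total(episodic=replace(ep, lag_spring=lag_hi)),
    )
    eps_af = half_spread(
        model.total(episodic=replace(ep, lag_fall=lag_lo)),
        model.total(episodic=replace(ep, lag_fall=lag_hi)),
    )

    ox_vals = np.linspace(*sw["ox_range"], sw["n_sweep"])
    eps_ox = sweep_sd(
        [model.total(episodic=replace(ep, ox_spring=v, ox_fall=v)) for v in ox_vals]
    )
    sf_vals = np.linspace(*sw["sf_range"], sw["n_sweep"])
    eps_sf = sweep_sd([model.total(scale_large=v) for v in sf_vals])

    eps_v = flux_variability_epsilon(model, base.stratum_cvs)

    components = combine(
        {
            "eps_v": eps_v,
            "eps_t": eps_t,
            "eps_ai": eps_ai,
            "eps_af": eps_af,
            "eps_ox": eps_ox,
            "eps_sf": eps_sf,
        }
    )
    details = {
        "baseline_total": base_total,
        "threshold_totals": t_totals,
        "sweeps": sw,
    }
    return components, details


def flux_variability_epsilon(model: TotalModel, stratum_cvs: pd.DataFrame) -> float:
    """eps_v: quadrature of per-stratum (emission sensitivity x CV of mean).

    Each type x pathway stratum's mean flux is uncertain with relative sd
    CV_s (sd of record means / sqrt(n) / mean); the global total responds
    linearly with sensitivity dT/dphi_s, so the strata combine in
    quadrature as independent terms.
    """
    base = model.total()
    eps_sq = 0.0
    for _, row in stratum_cvs.iterrows():
        key = (row["lake_type"], row["pathway"])
        cv = float(row["cv_mean"])
        if cv == 0:
            continue
        factors = pd.Series({key: 1.0 + 1e-4})
        sens = (model.total(flux_factors=factors) - base) / 1e-4
        eps_sq += (sens * cv) ** 2
    return float(np.sqrt(eps_sq))


def monte_carlo_total_sd(
    models: dict[float, TotalModel],
    stratum_cvs: pd.DataFrame,
    params: PipelineParams,
    n_draws: int = 1000,
    seed: int = 0,
    sweeps: dict | None = None,
) -> tuple[float, np.ndarray]:
    """Brute-force propagation: jointly sample all six uncertainty sources.

    ``models`` maps each classification-threshold endpoint value to its
    TotalModel (the threshold is sampled between its two endpoints with
    equal probability, matching the half-spread convention); lags are
    likewise two-point, oxidation and large-lake scaling uniform over their
    ranges, and stratum flux factors normal with sd CV_s (truncated at
    0.05). Returns (sd of totals, the totals).
    """
    sw = dict(DEFAULT_SWEEPS)
    if sweeps:
        sw.update(sweeps)
    rng = np.random.default_rng(seed)
    thresholds = sorted(models)
    cv_items = [
        ((row["lake_type"], row["pathway"]), float(row["cv_mean"]))
        for _, row in stratum_cvs.iterrows()
    ]
    ep = params.episodic
    totals = np.empty(n_draws)
    for d in range(n_draws):
        model = models[thresholds[rng.integers(len(thresholds))]]
        lag_s = sw["lag"][rng.integers(2)]
        lag_f = sw["lag"][rng.integers(2)]
        ox = rng.uniform(*sw["ox_range"])
        sf = rng.uniform(*sw["sf_range"])
        factors = pd.Series(
            {
                key: max(0.05, rng.normal(1.0, cv)) for key, cv in cv_items
            }
        )
        totals[d] = model.total(
            scale_large=sf,
            episodic=replace(ep, lag_spring=lag_s, lag_fall=lag_f, ox_spring=ox, ox_fall=ox),
            flux_factors=factors,
        )
    return float(np.std(totals, ddof=1)), totals
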