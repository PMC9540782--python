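# Methods

This note documents the model implemented by `lakech4`, the choices made
where the design was genuinely open, what the synthetic-data generator does
and does not emulate, and the package's known limitations. Everything
quantitative stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is asserted from memory.

## The upscaling model

The target quantity is a climatological year (365 days, no leap) of lake
CH₄ emission per 0.25° × 0.25° cell, split by pathway. The global total is

&nbsp;&nbsp;E = Σ_cells Σ_days [A_small + s·A_large] · F(type, pathway, day) ·
1{open water} + episodic terms,

with A the lake area (km²) per size class (< / ≥ 5,000 km²), s the
large-lake scaling (default 0.1), F the type × pathway daily flux curve
(mg m⁻² d⁻¹), and the open-water indicator defined by the cell's
climatological thaw and freeze dates. The unit chain
mg m⁻² d⁻¹ × km² × d → Tg (factor 10⁻⁹) is centralized in
`lakech4.constants` so it cannot drift between modules.

### Flux compilation

Records are aggregated flux measurements with sampling metadata. Filtering
keeps direct-method lake records with pathway, month and sampling window
present; each rejection carries exactly one primary reason, assigned in the
fixed precedence indirect → beaver pond → missing pathway → missing month →
missing window, so rejection tallies are auditable. Records reported as
means of listed component observations are expanded into one record per
component (metadata inherited); a component mean inconsistent with the
reported value beyond 1 % is logged, and the components are used.

Daytime-only measurements (sampling confined to 07:00–20:00 local; the
stated endpoints are read as the closed-open interval [07:00, 20:00)) are
multiplied by the diel factor 0.7 to convert them to 24-h means; 24-h
measurements pass unchanged. The correction is flagged and refuses
re-application. Negative diffusion fluxes (uptake) are retained and
corrected multiplicatively like positive ones — the multiplicative diel
model is applied uniformly rather than special-casing sign.

### Ecoclimatic classification

The seven-type decision tree (thermokarst; glacial/postglacial; peat pond;
organic; other boreal; temperate; tropical/subtropical) is evaluated in
fixed precedence over permafrost category (continuous/discontinuous vs
sporadic/isolated vs none), ground ice (≥ 10 % volume), soil organic carbon
(≥ 10 kgC m⁻², depth-weighted to 1 m) and annual soil temperature.
Choices made here:

- **Temperate/boreal boundary.** The tropical threshold is 20.0 °C
  (± 2.5 °C in the uncertainty analysis); no boundary between temperate
  and other-boreal is printed anywhere, so `t_boreal = 8.0 °C` is a
  documented convention of this package, exposed in
  `ClassificationThresholds` and exercised in tests.
- **Fall-through cells.** Sporadic/isolated permafrost with SOC < 10
  matches no signature; such cells fall through to the temperature
  branches and are counted in the type map's attributes, keeping
  classification total without inventing a threshold.
- **Grid convention.** Cell centers at −89.875…89.875° / −179.875…179.875°;
  cell areas on a spherical Earth (R = 6,371 km) by exact integration of
  cos φ across the cell.

Lake types without their own measurements borrow emission rates through an
alias table; its single entry maps organic lakes to peat-pond rates.

### Temperature-driven seasonality

Most flux measurements are warm-season; applying them year-round would
bias annual totals high. Per pathway, ordinary least squares of ln(flux)
on observation air temperature gives the sensitivity b (°C⁻¹); the fit
refuses fewer than 10 usable records or a degenerate (single-temperature)
design, and non-positive fluxes are excluded from the log fit and counted.
ln-space OLS (rather than a nonlinear exponential fit) is the field's
standard for these models and keeps coefficients comparable. One pooled
model per pathway is the default — per-type fits would starve on the small
per-type ebullition counts — and records lacking a contemporaneous air
temperature fall back, flagged, to their site's climatological temperature
of the measurement month.

Each corrected record is projected to all 12 months by
F(m) = F_obs·exp(b·(T_m − T_obs,month)), which is exact at the measurement
month by construction. Type × pathway × month means (arithmetic across
records, with per-stratum CVs retained for the uncertainty module) are
interpolated to 365 days by a periodic cubic spline anchored at month
midpoints rounded to whole days (16, 46, 76, …), so the daily curve passes
through the monthly anchors exactly; the periodic boundary reflects that a
climatological year has no endpoints. Negative ebullition values from
spline overshoot are clipped to zero.

### Emission seasons

Per-year thaw/freeze day-of-year grids reduce to climatological dates by
the per-cell mean over years, rounded to the nearest day. When a cell's
per-year dates straddle the new year (spread > 182 d) the circular mean is
used instead — otherwise Southern-Hemisphere and maritime cells would
average to mid-year nonsense. Cells never freezing in any year get a
no-freeze flag and a 365-day season. Two sources merge: cells containing
lakes ≥ 50 km² take the lake-ice phenology product, all others the
landscape freeze/thaw product; a masked cell missing from the lake-ice
source falls back to the landscape value (counted). A cell missing from
both sources defaults to no-freeze when |lat| < 40° (low-latitude seasons
are essentially year-round) and is a hard error if it contains lakes at
higher latitude. One season per cell is applied even where the cell mixes
lake sizes; the ≥ 50 km² mask decides which.

Season length is (freeze − thaw) mod 365, with the thaw day emitting and
the freeze day not, so the number of open-water days equals the season
length exactly.

### Episodic fluxes

The accumulation–oxidation model assumes sediment CH₄ production at the
deep-water temperature of 5 °C (maximum water density + ~1 °C metabolic
heat), estimated per type by rescaling each month's mean ebullition flux
to 5 °C through the fitted model and averaging the 12 estimates (E5).
Accumulation starts a lag (default 60 d) after thaw or freeze, once
dissolved O₂ is depleted; oxidation removes 75 % (spring) / 89 % (fall) of
the accumulated mass; the remainder vents evenly over ±7 days of the thaw
date (ice-out + spring turnover) or the 7 days before the freeze date
(fall turnover). Mass closure is exact: the daily series sums to
E5 · max(0, period − lag) · (1 − ox) to machine precision.

Open choices, resolved as follows: episodic fluxes apply only to freezing
cells (the windows are defined relative to thaw/freeze dates; non-freezing
stratified tropical lakes get none); large-lake areas receive episodic
fluxes scaled by the same factor as the continuous pathways (consistency);
the spring window deliberately straddles the thaw date — its early half
*is* the ice-out release — while a fall window longer than the open season
is clipped at the thaw date and renormalized, preserving closure; spring
accumulation is not additionally capped by the spring window length.

### Uncertainty

Six uncorrelated components combine in quadrature. The scenario
(finite-difference) convention, preferred over Monte Carlo as the default
because it is deterministic and fast:

- ε_t, ε_ai, ε_af (threshold 20 ± 2.5 °C, lags 60 ± 15 d): half the
  absolute spread of the global total between the two endpoint runs. The
  threshold component re-runs the full pipeline (the type map changes);
  the lag components evaluate on the linearized total model below.
- ε_ox, ε_sf (oxidation 0.5–0.99, large-lake factor 0–0.25): population
  standard deviation of totals over an 11-point evenly spaced sweep. How a
  stated range becomes a dispersion is not specified anywhere; the
  sweep-SD rule is this package's documented convention. The oxidation
  sweep moves both the spring and fall fractions together.
- ε_v: each type × pathway stratum's mean flux carries relative
  uncertainty CV_s = (sd of record annual means / √n) / mean; the global
  total responds linearly, so strata combine in quadrature as
  ε_v² = Σ (∂E/∂φ_s · CV_s)², with ebullition factors also scaling the
  (ebullition-derived) episodic source. Using the CV *of the mean* rather
  than of the raw measurements is a deliberate choice: the uncertain
  quantity propagated through the upscaling is the stratum mean.

The `TotalModel` response surface is rebuilt from full pipeline components
(per-stratum seasonal integrals, per-cell season arrays) and is tested to
reproduce the engine's baseline total to 10⁻⁹ relative; it makes the
1,000-draw joint Monte-Carlo cross-check cheap. In the Monte Carlo,
two-sided parameters are sampled at their endpoints with equal
probability (whose SD equals the half-spread convention exactly, even for
nonlinear response), range parameters uniformly, and stratum flux factors
normally with sd CV_s; quadrature and Monte Carlo agree within 15 % on the
test worlds, quantifying the independence approximation.

## The synthetic generator

The generator emulates the statistical structure the analysis assumes,
with ground truth embedded for recovery tests:

- **Flux records**: F = α(type, pathway)·exp(β_pathway·T_site,month)·m·ε,
  with m = 1/0.7 for daytime records, ε lognormal (median 1, σ = 0.8 by
  default — flux compilations are highly dispersed), β = 0.07 / 0.11 °C⁻¹
  for diffusion/ebullition (Q₁₀ ≈ 2 / 3), and α set so that the published
  per-type season-mean fluxes are reproduced at representative season
  temperatures, split ~60/40 ebullition/diffusion (35/65 for other boreal,
  where diffusion dominates observations). Counts default to the real
  compilation's 575 sites / 881 records; contamination (3 % indirect, 2 %
  beaver pond, 6 % missing metadata, 5 % component-mean records) exercises
  every filter with known tallies. No organic-lake records are generated,
  mirroring the real compilation and exercising the alias.
- **Climate**: annual mean air temperature 27 − 0.45·|lat| °C; monthly
  sinusoid of amplitude 2 + 0.35·|lat| peaking mid-July (north) /
  mid-January (south). Annual soil temperature equals annual mean air
  temperature, keeping classification and flux modeling consistent by
  construction.
- **Layers**: latitude bands set the thermal/permafrost regime; longitude
  stripes alternate ground ice and SOC so all seven type signatures occur
  on any sufficiently tall grid (an error tells the user to widen the
  extent otherwise).
- **Phenology**: season length 365 − 6·(|lat| − 40) d poleward of 40°
  (clipped at 60 d), centered on mid-summer; cells below 40° never freeze;
  13 years with 5-day Gaussian jitter; the lake-ice source lags the
  landscape source by 3 days on both dates.
- **Areas**: deterministic fractions of cell area (2 % primary source,
  0.8 % small-lake source, of which rivers and reservoirs mask 0.3
  percentage points); one longitude stripe of cells poleward of 20°
  carries ≥ 5,000 km² lakes (30 % of cell area), a wider stripe carries
  the ≥ 50 km² lakes with their own ice-phenology record.

A single seed drives per-component substreams
(`GeneratorConfig.stream(i)`), so any input regenerates independently and
bit-identically.

What the generator does **not** emulate: real geography and hydrography,
satellite retrieval error and gap structure, correlated flux errors within
lakes or campaigns, water temperature as distinct from air temperature,
and reporting biases beyond the planted contamination. Passing tests
therefore demonstrate that the *pipeline machinery* is correct under the
assumed statistical structure — not that the structure describes real
lakes.

## Problem sizes and numerics

The default test/validation worlds span latitudes −35…80° in a narrow
longitude band (≈ 4,400–18,000 cells), 400–881 records and 13 phenology
years, sized so the whole suite and the acceptance script each run in
seconds while exercising every branch (all seven types, both phenology
sources, both size classes, freezing and non-freezing cells). Grid closure
(global = Σ zones = Σ types = Σ pathways) is enforced at 10⁻⁶ relative
inside the engine; episodic mass closure is exact; the noise-free
end-to-end world (σ = 0, β = 0, common α, contamination off) matches its
closed form Σ area·flux·season + episodic to well within 0.1 % (observed:
machine precision). Ties and degenerate inputs: equal thaw/freeze dates
read as a full-year season; empty strata are hard errors when the type has
lake area (after aliasing); the OLS fit refuses under-determined designs
rather than returning garbage coefficients.

## Known limitations

- The exact regression coefficients of the original study's supplementary
  temperature–flux fits are not reproduced; the model is refitted from
  whatever compilation is supplied, so numerical agreement with those
  coefficients is not asserted.
- GIS extraction (polygon rasterization, river/reservoir vector masking)
  is out of scope; the pipeline consumes per-source gridded area fields.
- One season per cell: a cell mixing ≥ 50 km² and smaller lakes gets the
  lake-ice season for all its area.
- The uncertainty analysis reclassifies the grid under threshold
  perturbation but keeps record type labels fixed (labels are treated as
  data); shares of the total uncertainty depend on the compilation's CV
  structure and are not portable between worlds.
- Output is one climatological year; no transient or multi-year runs.
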