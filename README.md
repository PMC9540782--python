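# lakech4

Observation-driven upscaling of global lake methane (CH₄) emissions: a
tested, reusable pipeline from a flux-measurement compilation and gridded
geophysical/ice-phenology inputs to a daily 0.25° × 0.25° climatology of
lake CH₄ emissions by pathway, with propagated uncertainty.

## Who this is for

Researchers working on the global CH₄ budget, bottom-up biogeochemical
modeling, or inverse (top-down) flux estimation who need lake emissions as
spatially and temporally explicit fields rather than a single global
number — and who want the upscaling assumptions exposed as testable code.

## The model

Open-water lake CH₄ leaves by two continuous pathways, **diffusion** across
the air–water interface and **ebullition** (bubbling), plus two episodic
ones: the **ice-out / spring-turnover** pulse and the **fall-turnover**
pulse. The pipeline:

1. **Compilation** — aggregated flux measurements (mg CH₄ m⁻² d⁻¹) are
   filtered (direct methods only; month, sampling window and pathway
   required; beaver ponds removed), disaggregated where component values
   are reported, and daytime-only measurements are multiplied by the diel
   scaling factor 0.7 (daytime fluxes exceed the 24-h mean).
2. **Classification** — every 0.25° cell gets one of seven ecoclimatic lake
   types (thermokarst, glacial/postglacial, peat pond, organic, other
   boreal, temperate, tropical/subtropical) from a fixed-precedence
   decision tree over permafrost category, ground-ice content (10 %
   volume), soil organic carbon (10 kgC m⁻²) and annual soil temperature
   (tropical ≥ 20 °C). Lake area per cell merges a per-lake inventory with
   a river/reservoir-masked small-lake source, split at 5,000 km² lake size.
3. **Seasonality** — an exponential flux–temperature law per pathway,
   ln F = a + bT, is fitted to the corrected compilation and projects every
   measurement through its site's monthly air-temperature cycle:
   F(m) = F_obs · exp(b·(T_m − T_obs)). Type × pathway × month means are
   interpolated to 365 daily values with a periodic cubic spline.
4. **Emission seasons** — multi-year satellite thaw/freeze dates reduce to
   a climatological season grid (lake-ice phenology for cells with ≥50 km²
   lakes, landscape freeze/thaw otherwise); emissions run from the thaw
   date to the freeze date.
5. **Episodic fluxes** — an accumulation–oxidation model: production at
   deep-water temperature 5 °C, a 60-day O₂-depletion lag, 75 % (spring) /
   89 % (fall) oxidized, the rest emitted over ±7 days of thaw or the 7
   days before freeze.
6. **Engine** — area × daily curve × season mask, with ≥5,000 km² lake
   areas emitting at 10 % of the small-lake rate; aggregation to zonal,
   type, pathway and global totals with enforced closure.
7. **Uncertainty** — six uncorrelated components combined in quadrature,
   ε² = ε_v² + ε_t² + ε_ai² + ε_af² + ε_ox² + ε_sf², from scenario runs
   (threshold 20.0 ± 2.5 °C; lags 60 ± 15 d; oxidation swept 0.5–0.99;
   large-lake factor swept 0–0.25) and the flux-measurement CV; a joint
   Monte-Carlo propagation is available as a cross-check.

A synthetic-data module generates every input with known ground truth, so
the full pipeline runs and is validated without any downloads. Real-data
provenance (per-lake polygon inventories, remote-sensing inland-water and
freeze/thaw products, reanalysis temperature) is documented in
`docs/methods.md`; the pipeline consumes gridded fields and a CSV and does
no GIS extraction.

## Worked example

```sh
lakech4 simulate --seed 5 --out world/
lakech4 run --inputs world/ --output-dir out/
```

prints (seed 5, default synthetic study conditions):

```
wrote synthetic world (881 records) to world/
global total 16.007 Tg CH4 yr-1 ({'diffusion': 6.309, 'ebullition': 9.641,
'iceout_spring': 0.025, 'fall_turnover': 0.033})
```

The global total is the annual sum over all cells and days of area ×
flux × season, in Tg CH₄ yr⁻¹; the per-pathway dictionary splits it into
diffusion, ebullition and the two episodic pulses (a small share, as
expected: the episodic pathways only act on freezing cells). `out/`
contains the daily emission grid (`daily_emissions.nc`, g CH₄ per cell per
day), the season grid, the monthly flux table, daily flux curves, and zonal
CSV summaries. `lakech4 uncertainty --inputs world/ --out unc.json` adds
the six ε components and their quadrature total. The same library calls are
available in Python via `lakech4.generate_world`, `lakech4.run_pipeline`
and `lakech4.estimate_uncertainty`.

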