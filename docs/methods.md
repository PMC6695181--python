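# Methods

## Scope and assessment flow

The package quantifies, for one municipality and one assessment year, the
supply of two regulating ecosystem services by the urban forest (all trees
and shrubs inside the boundary) and the societal demand for them, then
classifies each supply–demand comparison. The stages are: (1) expand a
stratified random-plot survey to city-scale forest structure; (2) model
hourly dry deposition to get the annual air-quality improvement, and apply
the biomass factor chain to get carbon storage/sequestration; (3) encode
demand as authority limit values (air) and per-capita-downscaled national
GHG reduction targets (climate); (4) classify every authority × pollutant
pair and each GHG target as match / modest mismatch / significant mismatch.

## Survey expansion

Each plot contributes a density (trees per hectare). A stratum's total is
`area_ha × mean(plot densities)` with standard error
`area_ha × sd(densities)/√n_plots` (0 for a single plot); city totals add
strata, and the city SE adds in quadrature (strata are sampled
independently). The plain per-plot density estimator was chosen over a
ratio estimator because plots within a stratum share a nominal area in the
intended designs; the estimator function is isolated so an alternative can
be swapped in. A stratum with positive area but no plots is an error rather
than silently contributing zero — unsampled area would otherwise bias the
total downward.

## Carbon

Fresh above-ground biomass uses `B = a·(dbh²·h)^b` (kg; dbh cm, height m).
The exponent b defaults to 0.95 and the coefficient to 0.10 (hardwood) /
0.08 (conifer), giving ≈ 570/460 kg above-ground fresh biomass for a
30 cm × 10 m tree — mid-range for urban allometries. Coefficients are
per-species-overridable in `data/traits.yaml` because no single equation
fits all taxa. The factor chain is multiplicative and order-independent:
root-to-shoot 0.26, fresh→dry 0.48 (conifer) / 0.56 (hardwood), ×0.8 when
open-grown, carbon fraction 0.5. CO₂-equivalent = C × 44/12.

Sequestration is `storage(dbh + g·condition) − storage(dbh)` with g the
species' annual diameter increment at perfect condition (defaults 0.6 cm/yr
hardwood, 0.4 cm/yr conifer). Condition multiplies growth, not standing
biomass: a declining crown slows accumulation but does not erase measured
stems. Height is static by default (`height_growth_per_cm_dbh = 0`);
coupling it to diameter growth is a single config number. Negative growth
is accepted (senescence) and logged. Shrub records carry no DBH-based
carbon but remain in the inventory and its expansion. The
deciduous/evergreen flag is kept in the data model but does not enter the
carbon math (the carbon fraction is taken as 0.5 universally).

City scaling multiplies each sampled tree by its stratum expansion factor
(estimated stratum total / trees sampled there), so the structure estimate
and the service estimate stay consistent.

## Dry deposition

Per hour and pollutant: flux `F = v_d·C` (g m⁻² h⁻¹ after µg→g), column
mass `M_total = C·h_blh`, improvement for tree cover T_c

`I_total = (F·T_c/100)/(F·T_c/100 + M_total)·100`, and
`ΔC = C/(1 − I_total/100) − C` (the no-purification level is `C + ΔC`).

Defaults: boundary-layer height 1000 m (an annual-mean mixing depth;
configurable because it directly scales the improvement), deposition
velocities in m/h per pollutant with gas values near published annual
medians of big-leaf resistance models and a deliberately small CO velocity
(CO is biologically nearly inert to canopies).

PM2.5: when wind exceeds 4 m/s and precipitation is below 10⁻⁵ m/h,
a resuspension velocity `pm_resusp_rate × h_blh` (default 0.0025/h × 1000 m
= 2.5 m/h) is subtracted from v_d, so net flux can be negative — the
mechanism behind negative annual PM2.5 improvement in semi-arid, windy
climates. This is a deliberately minimal leaf-load-free parameterisation;
it reproduces the negative-removal regime without tracking per-leaf
accumulation.

Annual aggregation drops missing hours from all means consistently (no
imputation) and refuses a pollutant with more than 20% of hours missing.
Removal mass integrates `F × T_c/100` over the year and city area. Under
the model's own algebra `ΔC·h_blh` equals the canopy-intercepted flux
exactly, so flux-based and concentration-based annual masses agree — used
as an internal consistency test. Leap years (8784 h) are supported;
timestamps are local standard time without DST shifts.

## Demand

Limit values are a small YAML registry keyed by authority × pollutant ×
averaging window; a pair may hold several windows (e.g. 1-h and 8-h CO) or
none ("no standard", reported as `-`, distinct from a match). ppm and
mg/m³ limits convert to µg/m³ at 25 °C / 1 atm (molar volume 24.45 L/mol;
molar masses CO 28.01, O₃ 48.00, NO₂ 46.01, SO₂ 64.07). The bundled
registry reproduces the adopted standards table of the Tabriz assessment
verbatim, including entries that look like typographical artefacts (the
EPA O₃ value, and the EPA NO₂ limit stored as its printed 107 µg/m³
parenthetical); a user config can override any entry.

Short-window metrics use the hourly series when available (1-h: annual
maximum; 8-h: maximum complete 8-hour rolling mean). Without hourly data
the annual mean substitutes and the result is flagged *proxy* — the mode in
which the bundled case study runs, since only annual summaries are
packaged. City GHG demand is strictly per-capita:
`city_total = national_total × city_pop/national_pop`, times the target's
reduction fraction. No sectoral weighting is attempted.

## Classification

Compensation = improvement/exceedance × 100. Boundary choices: exactly 20%
is significant (the stated significant band is 0–20%); compensation above
100% while the metric still exceeds the limit is modest (demand is unmet,
so never a match); for GHG, exactly 100% contribution is modest
(right-closed band) and only > 100% is a match. When a cell aggregates
several windows, the severest class wins. Every cell carries its window,
proxy flag and compensation for provenance.

## Synthetic data

`CityScenario` generates both survey and monitoring data with known ground
truth: Poisson tree counts per plot at the stratum's true density,
log-normal DBH (median ≈ 16 cm, σ_log 0.5 — a young-ish urban population),
loosely allometric heights, uniform condition 0.6–1.0; hourly
concentrations as annual mean + seasonal and diurnal sinusoids + AR(1)
noise (coefficient 0.7, reflecting strong hourly autocorrelation of urban
pollution), clipped at zero; diurnal wind and Bernoulli rain so the PM2.5
resuspension switch exercises both regimes. The generators emulate
sampling noise and regime switching, not spatial gradients, instrument
drift or phenology — so recovery tests demonstrate estimator correctness,
not field realism. Everything is a pure function of (scenario, seed).

Problem sizes in the tests and acceptance script — 500 replicate surveys of
5 plots for estimator bias, single 8760-h years for deposition recovery,
10⁴ sampled points of the classifier grid — were chosen as the smallest
sizes at which the Monte-Carlo standard errors are well below the asserted
tolerances.

## Known limitations

* The deposition model is a velocity parameterisation, not a full
  resistance/energy-balance model: no leaf-area phenology, no wet
  deposition, no intra-urban dispersion.
* Allometric defaults are genus-agnostic beyond the conifer/hardwood split;
  site-calibrated equations should be supplied for production carbon
  accounting.
* The published case-study summaries embed minor internal inconsistencies
  (one improvement amount and one percentage column do not match their own
  table's means/totals); the package stores the printed values verbatim and
  computes classifications, which are insensitive to them, rather than
  reconciling the numbers.
* Annual-proxy evaluation of short-window standards understates
  exceedances of 1-h/8-h limits; cells computed that way are flagged.
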