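# uresmatch

Supply–demand (mis)match assessment for two urban regulating ecosystem
services delivered by a city's trees and shrubs:

* **air-quality improvement** — pollutant removal (PM2.5, O₃, NO₂, SO₂, CO)
  by dry deposition onto the canopy, and
* **climate regulation** — carbon storage and annual sequestration in tree
  biomass.

It is written for urban-forestry and environmental-planning analysts who
have (a) a stratified random-plot tree survey, (b) a year of hourly pollutant
and weather monitoring (or just its annual summary), and (c) published
air-quality standards and greenhouse-gas reduction targets, and who want a
defensible answer to: *does the urban forest's service supply meet the
city's demand, and where are the mismatches?*

## The model

**Supply.** Hourly canopy removal uses deposition-velocity flux, F = v_d·C.
The hourly air-quality improvement attributable to the whole tree cover
T_c (%) is

```
I_total = (F·T_c/100) / (F·T_c/100 + M_total) · 100 ,      M_total = C·h_blh
```

with M_total the pollutant mass in the boundary-layer column (height h_blh)
per m² of ground. The concentration change the canopy causes is
ΔC = C/(1 − I_total/100) − C, so the hypothetical *no-purification* level is
C + ΔC. PM2.5 deposition is mechanical: under strong wind and no rain,
deposited particles resuspend, and the net flux — and the annual
improvement — can be negative. Tree carbon comes from power-law allometry on
DBH and height with the standard factor chain (root-to-shoot 0.26,
fresh→dry 0.48/0.56 for conifers/hardwoods, ×0.8 for open-grown trees,
carbon = 0.5 × dry biomass); sequestration is the storage difference after
one year of diameter growth, and CO₂-equivalents use 44/12.

**Demand.** Air-quality demand is the set of limit values of four
authorities (WHO, EU, EPA, Iran) per pollutant and averaging window;
climate demand is the city's per-capita share of national GHG emissions
times the national reduction targets (4% unconditional / 12% conditional by
2030).

**Matching.** For each authority × pollutant pair, an exceedance of the
limit by the with-purification metric is compared with the canopy's
improvement: compensation ≤ 20% of the exceedance ⇒ *significant mismatch*,
> 20% ⇒ *modest mismatch*, no exceedance ⇒ *match*, no standard ⇒ not
assessed. The forest's sequestration likewise compensates the GHG reduction
demand (< 20% significant, 20–100% modest, > 100% match).

## Worked example

The bundled Tabriz, Iran case study (24,480 ha, 9.4% tree cover, 2015
monitoring year) runs entirely from packaged annual summaries:

```python
from uresmatch import URESAssessment
from uresmatch.datasets import (TABRIZ_CITY_AREA_HA, load_tabriz_air_quality,
                                load_tabriz_emissions)

report, _ = load_tabriz_air_quality()
city, seq_c = load_tabriz_emissions()
results = URESAssessment(
    city_area_ha=TABRIZ_CITY_AREA_HA,
    air_report=report,                      # annual-proxy mode
    emissions=city,
    sequestration_co2eq_t_yr=seq_c * 44 / 12,
).fit()
print(results.matrix.to_frame())
print("air-quality mismatches:", results.n_mismatch)
```

prints

```
     CO NO2 O3 PM2.5 SO2
WHO   -   S  M     S   M
EU    M   S  M     S   S
EPA   M   M  M     S   M
IRAN  M   M  S     S   M
air-quality mismatches: 8
```

Reading the NO₂/WHO cell: the annual mean with purification is 86.79 µg/m³
against a 40 µg/m³ limit, a 46.79 µg/m³ exceedance; the canopy's 4.985 µg/m³
improvement compensates only ≈ 10.7% of it, below 20%, hence a significant
mismatch (`S`). PM2.5 is `S` everywhere because its improvement is negative
(net resuspension in this semi-arid, windy climate). Both GHG targets are
significant mismatches. A command-line pipeline (`uresmatch assess
--config run.yaml`, plus `structure`, `carbon`, `airquality`, `demand` and
`simulate` subcommands) wraps the same chain and writes CSV/JSON/Markdown
reports.

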