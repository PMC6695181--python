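{
  "description": "Emissions profile for the Tabriz assessment: Iranian national GHG total for 2015 (PBL trends report era) downscaled per capita. Units: t CO2-eq/yr, persons, hectares.",
  "national_total_tco2eq": 820000000,
  "national_pop": 78500000,
  "city_pop": 1560000,
  "city_area_ha": 24480,
  "sequestration_t_c_yr": 29200
}
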