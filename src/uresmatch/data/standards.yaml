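# Default environmental quality standards (EQS) registry: WHO guidelines,
# EU Air Quality Directive, US EPA NAAQS and the Iranian national standard,
# as adopted in the Tabriz assessment.  Absent pairs (WHO-CO) mean "no
# standard" and are assessed as "-".  The EPA O3 value is kept verbatim from
# the adopted standards table; override via a user config if desired.
standards:
  - {authority: WHO,  pollutant: PM2.5, limit: 10,    units: ug/m3, window: annual}
  - {authority: EU,   pollutant: PM2.5, limit: 25,    units: ug/m3, window: annual}
  - {authority: EPA,  pollutant: PM2.5, limit: 12,    units: ug/m3, window: annual}
  - {authority: IRAN, pollutant: PM2.5, limit: 10,    units: ug/m3, window: annual}

  - {authority: WHO,  pollutant: O3,    limit: 100,   units: ug/m3, window: 8h}
  - {authority: EU,   pollutant: O3,    limit: 120,   units: ug/m3, window: daily_8h_max}
  - {authority: EPA,  pollutant: O3,    limit: 159,   units: ppm,   window: 8h}
  - {authority: IRAN, pollutant: O3,    limit: 12,    units: ug/m3, window: annual}

  - {authority: WHO,  pollutant: NO2,   limit: 40,    units: ug/m3, window: annual}
  - {authority: EU,   pollutant: NO2,   limit: 40,    units: ug/m3, window: annual}
  # printed as 0.053 ppm (107 ug/m3); the parenthetical ug/m3 value is stored
  - {authority: EPA,  pollutant: NO2,   limit: 107,   units: ug/m3, window: annual}
  - {authority: IRAN, pollutant: NO2,   limit: 100,   units: ug/m3, window: annual}

  - {authority: WHO,  pollutant: SO2,   limit: 50,    units: ug/m3, window: annual}
  - {authority: EU,   pollutant: SO2,   limit: 20,    units: ug/m3, window: annual}
  - {authority: EPA,  pollutant: SO2,   limit: 79,    units: ug/m3, window: annual}
  - {authority: IRAN, pollutant: SO2,   limit: 80,    units: ug/m3, window: annual}

  # WHO publishes no CO guideline in this set ("-" in the matrix)
  - {authority: EU,   pollutant: CO,    limit: 10,    units: mg/m3, window: daily_8h_max}
  - {authority: EPA,  pollutant: CO,    limit: 9,     units: ppm,   window: 8h}
  - {authority: EPA,  pollutant: CO,    limit: 35,    units: ppm,   window: 1h}
  - {authority: IRAN, pollutant: CO,    limit: 9,     units: ppm,   window: 8h}
  - {authority: IRAN, pollutant: CO,    limit: 35,    units: ppm,   window: 1h}
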