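{
  "description": "Tabriz 2015 annual air-quality summary: observed annual means with purification by the urban forest, the modelled no-purification levels, the reported average hourly improvement percentages, and the reported improvement amounts. Units ug/m3. Note: the published PM2.5 row is internally inconsistent (25.703 - 25.93 = -0.227, reported amount -0.754); both values are kept verbatim and the sign, which drives classification, agrees.",
  "mean_with": {"CO": 2089.0, "NO2": 86.79, "O3": 38.39, "PM2.5": 25.93, "SO2": 39.34},
  "mean_without": {"CO": 2090.03, "NO2": 91.775, "O3": 41.523, "PM2.5": 25.703, "SO2": 42.476},
  "avg_pct_improvement": {"CO": 0.0005, "NO2": 0.0575, "O3": 0.0817, "PM2.5": -0.029, "SO2": 0.0798},
  "reported_improvement_amount": {"CO": 1.02955, "NO2": 4.985, "O3": 3.1375, "PM2.5": -0.754, "SO2": 3.136}
}
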