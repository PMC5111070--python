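{
  "comment": "Published regional bookkeeping used for internal-consistency checks: suitability class areas and occupancy areas (km^2).",
  "suitable_class_areas_km2": {
    "high": 9017,
    "medium": 81473,
    "marginal": 114860
  },
  "ajo_km2": 35441,
  "ajo_with_near_records_km2": 37825,
  "apjo_km2": 16420
}
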