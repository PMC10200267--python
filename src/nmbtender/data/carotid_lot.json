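{
  "lot_id": "carotid-stents-2021",
  "horizon_months": 12,
  "baseline_utility": 0.93,
  "wtp_per_qaly": 60000,
  "starting_price": 600,
  "days_per_year": 365,
  "currency_label": "euro",
  "_comment": "Endpoint disutility/duration/cost values are NON-AUTHORITATIVE back-solved calibration artifacts (the original lot's fixed parameters were never published); see carotid_notes.md.",
  "endpoints": [
    {
      "endpoint_id": "minor_stroke",
      "label": "minor stroke",
      "disutility": 0.30,
      "duration_months": 2,
      "cost_per_event": 170500.0
    },
    {
      "endpoint_id": "major_stroke",
      "label": "major stroke",
      "disutility": 0.55,
      "duration_months": 12,
      "cost_per_event": 15000.0
    },
    {
      "endpoint_id": "death",
      "label": "death",
      "disutility": 0.93,
      "duration_months": 12,
      "cost_per_event": 693637.8571428572
    }
  ]
}
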