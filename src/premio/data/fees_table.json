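{
  "entries": [
    {"setting": "supervised_individual", "duration_min": 60, "unit_fee_eur": 100.0},
    {"setting": "supervised_individual", "duration_min": 45, "unit_fee_eur": 75.0},
    {"setting": "supervised_individual", "duration_min": 30, "unit_fee_eur": 50.0},
    {"setting": "supervised_group5", "duration_min": 60, "unit_fee_eur": 20.0},
    {"setting": "supervised_group5", "duration_min": 45, "unit_fee_eur": 15.0},
    {"setting": "supervised_group5", "duration_min": 30, "unit_fee_eur": 10.0},
    {"setting": "unsupervised_facility", "duration_min": null, "unit_fee_eur": 10.0},
    {"setting": "unsupervised_home", "duration_min": null, "unit_fee_eur": 0.0},
    {"setting": "contact", "duration_min": null, "unit_fee_eur": 10.0}
  ],
  "equipment_fee_eur": 0.0
}
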