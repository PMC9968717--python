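{
  "regimens": [
    {"label": "q24h 0.25 (8am)", "dose": 0.25, "interval": 24.0, "first_dose_clock": 8.0},
    {"label": "q24h 0.25 (8pm)", "dose": 0.25, "interval": 24.0, "first_dose_clock": 20.0},
    {"label": "q12h 0.25", "dose": 0.25, "interval": 12.0, "first_dose_clock": 8.0},
    {"label": "q12h 0.5", "dose": 0.5, "interval": 12.0, "first_dose_clock": 8.0}
  ],
  "n_individuals": 500,
  "horizon_days": 25.0,
  "n_grid": 500,
  "burn_in_days": 10.0,
  "auec_window": [480.0, 504.0],
  "seed": 1,
  "bodyweight_kg": 10.0
}
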