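{
  "slope": 0.8796860603828233,
  "intercept": 0.1412787311606185,
  "mean_ratio": 0.889529186218728,
  "mape": 6.751483383148676,
  "window_percentages": {
    "below": 55.0,
    "within": 40.0,
    "above": 5.0,
    "outside": 60.0
  }
}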