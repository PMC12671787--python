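# Demo configuration: a small synthetic world that runs in under a minute.
seed: 1
n_lon: 8
n_lat: 8
scales: [1, 3]
thresholds: [-0.5, -1.0]
model_scale: 3
model_threshold: -0.5
bandwidth: auto
response: binomial
calibration: self
scenarios:
  - {name: SSP126, trend: -0.3}
  - {name: SSP585, trend: 1.5}
n_ensemble_members: 2
future_years: 30
future_periods:
  near: {start: 2022, end: 2040}
  medium: {start: 2041, end: 2051}
forest_mask_threshold: 0.5
out_dir: runs/demo
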