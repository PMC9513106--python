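{
  "grid_shape": [32, 32, 56],
  "grid_spacing": 0.65,
  "time_axis": [0.0],
  "stenosis": {
    "severity": 0.75,
    "eccentricity": 0.05,
    "diameter": 10.0,
    "throat_position": 0.8,
    "downstream_length": 2.6,
    "stenosis_length": 1.0
  },
  "inlet": {"mean_Re": 1000.0, "peak_Re": 4000.0},
  "turbulence": {"tke_peak": 120.0, "anisotropy": 2.0, "peak_offset": 1.0},
  "conditions": [[1.5, 5.0], [2.5, 5.0]],
  "alpha": 1.68,
  "venc_levels": [6.0, 3.0, 1.5],
  "noise_averages": 2,
  "seed": 1
}
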