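# Spatial-to-temporal encoding: each engram source in turn receives a
# sustained drive; engram identity is decoded from the oscillator spectrum.
experiment:
  kind: s2t
  n_engrams: 3
  n_seeds: 10
  n_calibration_seeds: 5
  base_seed: 0
simulation:
  dt: 0.1
  baseline_ms: 500.0
  drive_ms: 3000.0
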