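# Calibration sweep: mono/di weight ratio -> oscillator peak frequency/power.
experiment:
  kind: sweep
  ratios: [0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
  n_seeds: 5
  base_seed: 0
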