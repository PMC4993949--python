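# Temporal-to-spatial routing: oscillatory Input1 (di-synaptic) + constant
# Input2 (mono-synaptic) onto the router oscillator's I cells; three engram
# readout parts follow the low/medium/high drive bands.
experiment:
  kind: t2s
  conditions: [19.0, 25.0, 32.0]
  n_seeds: 10
  base_seed: 0
simulation:
  dt: 0.1
  baseline_ms: 1000.0
  drive_ms: 3000.0
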