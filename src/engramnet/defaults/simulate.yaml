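# Raw run of the default router with a 25 Hz oscillatory di-synaptic drive.
experiment:
  kind: simulate
  seed: 0
network:
  builder: router
simulation:
  dt: 0.1
  duration: 2000.0
drives:
  explicit:
    - target: oscillator_I
      kind: sinusoid
      amplitude: 2.4
      frequency: 25.0
      onset: 500.0
      pathway: di_synaptic
      relay: relay
    - target: oscillator_I
      kind: constant
      amplitude: 0.4
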