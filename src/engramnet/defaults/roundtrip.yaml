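# Round trip: encode engram k as an oscillation frequency, replay it to the
# router, check that part k wins. n_seeds is trials per engram.
experiment:
  kind: roundtrip
  n_seeds: 20
  base_seed: 0
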