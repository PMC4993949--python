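# engramnet

Stochastic spiking network simulator for the conversion between *spatial*
and *temporal* neural codes in memory-engram circuits.

Memory engrams are sparse neuron populations whose reactivation drives
recall — a spatial code: *which* cells are active.  Population rhythms in
excitation–inhibition (E–I) circuits carry a temporal code: the frequency
and power of the oscillation.  `engramnet` implements a leaky
integrate-and-fire (LIF) circuit model in which the two codes convert into
each other:

* **Encoder (spatial → temporal).**  Engram source populations project
  onto an E–I oscillator, each reaching the inhibitory cells both
  mono-synaptically and di-synaptically through an excitatory relay.  With
  the total synaptic budget `Q` fixed, an engram's mono/di weight ratio
  `r` splits it as `w_mono = Q·r/(1+r)` and `w_di = Q/(1+r)`; sustained
  activation of engram `k` then evokes an oscillation whose peak frequency
  and power are set by `r_k` (strictly monotone map, ≈31 Hz at `r = 0.1`
  down to ≈19 Hz at `r = 8`).
* **Router (temporal → spatial).**  An oscillatory Input1 (half-rectified
  sinusoid, di-synaptic via a relay) and a constant mono-synaptic Input2
  drive the oscillator's inhibitory cells; the entrained oscillator
  projects onto three engram readout parts — small interconnected E–I
  pairs — with per-part weight pairs `(w_e,k, w_i,k)`.  Distinct weight
  pairs make parts 1/2/3 ignite selectively for low/medium/high drive
  frequencies (19/25/32 Hz), within ~150 ms of drive onset.

Every neuron is a current-based LIF unit (forward Euler, `dt = 0.1 ms`)
with exponential synapses, Dale-law signs, absolute refractoriness and
per-neuron Poisson background noise; all randomness derives from a single
seed, so every raster and report is reproducible bit for bit.  See
`docs/methods.md` for the full model description and calibration.

## Worked example

```python
import numpy as np
from engramnet import (S2TConfig, T2SConfig,
                       run_spatial_to_temporal, run_temporal_to_spatial)

# spatial -> temporal: activate each engram source, read the spectrum
enc = run_spatial_to_temporal(S2TConfig(n_seeds=4, n_calibration_seeds=2))
for k, (f, p) in enumerate(zip(enc.aggregate["peak_frequency_hz"],
                               enc.aggregate["peak_power"]), start=1):
    print(f"engram {k}: peak {f:.1f} Hz, power {p:.2f}")
print(f"decode accuracy (held-out seeds): {enc.aggregate['decode_accuracy']:.2f}")

# temporal -> spatial: drive the router at each band, see which part wins
rtr = run_temporal_to_spatial(T2SConfig(n_seeds=3))
print(np.round(rtr.aggregate["selectivity"], 2))
print("winners:", [w + 1 for w in rtr.aggregate["winners"]])
print("matched activation delays (ms):", rtr.aggregate["matched_delay_ms"])
```

prints (a couple of minutes on one CPU):

```
engram 1: peak 19.5 Hz, power 0.31
engram 2: peak 25.8 Hz, power 0.43
engram 3: peak 32.0 Hz, power 0.46
decode accuracy (held-out seeds): 1.00
[[0.6  0.4  0.  ]
 [0.11 0.5  0.39]
 [0.08 0.17 0.75]]
winners: [1, 2, 3]
matched activation delays (ms): [170.0, 126.66666666666667, 160.0]
```

Each engram maps onto a distinct, decodable oscillation; each drive band
ignites its matching engram part (diagonal winners in the row-normalized
selectivity matrix) about 130–170 ms after drive onset.

The same experiments run from the shell, each reading one YAML config and
writing an `ExperimentReport` JSON plus the fully resolved config:

```bash
engramnet t2s --seed 0 --out-dir out/t2s        # routing experiment
engramnet s2t --seed 0 --out-dir out/s2t        # encoding experiment
engramnet roundtrip --seed 0 --out-dir out/rt   # composition of the two
engramnet sweep --seed 0 --out-dir out/sweep    # ratio -> frequency map
engramnet simulate --config my_run.yaml         # raw raster run
engramnet validate-config my_run.yaml
```

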