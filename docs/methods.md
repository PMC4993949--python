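# Methods

`engramnet` simulates a hypothesis about memory circuits: that sparse
engram (memory-trace) cell populations and excitation–inhibition (E–I)
oscillator circuits can convert between a *spatial* code (which engram
population is active) and a *temporal* code (the frequency and power of a
population oscillation), in both directions.  This note records the model,
its parameters, the calibration that fixed the defaults, and what the
simulations do and do not show.

## Neuron and synapse model

All neurons are current-based leaky integrate-and-fire (LIF) units,

    dV/dt = (v_rest − V)/tau_m + I_syn(t) + I_drive(t),

integrated with forward Euler at `dt = 0.1 ms`.  A neuron crossing
`v_thresh` at the end of a step is reset to `v_reset` and held there for
the absolute refractory period `t_ref`, during which it ignores input.
Defaults: `v_rest = v_reset = −70 mV`, `v_thresh = −54 mV`; excitatory
cells `tau_m = 10 ms`, `t_ref = 2 ms`; oscillator inhibitory cells
`tau_m = 8 ms`, `t_ref = 1 ms`.

A synaptic event arriving after its axonal delay injects an exponentially
decaying current with time constant `tau_syn` whose integral equals the
connection weight, so a weight of `w` mV moves the postsynaptic membrane
by `w` mV in total; for `tau_syn ≪ tau_m` the peak deviation is close to
`w`.  Signs follow Dale's law from the presynaptic cell type.  Connectivity
is random (independent Bernoulli per pair at the connection's
`probability`, no autapses) and is re-realized from the simulation seed, so
every seed is a fresh network instance *and* noise instance.

Background noise is an independent homogeneous Poisson train per neuron;
each event jumps the membrane instantaneously by `background_weight`.
Event-based noise was chosen over Gaussian current noise because it
composes with the synaptic machinery already required.

The integration loop exists twice: a vectorized numpy reference and a
numba-compiled scalar loop.  Both consume identical pre-generated noise
and connectivity and perform the same floating-point operations in the
same order, so they produce bit-identical rasters (this is tested).  All
randomness derives from one `numpy` `SeedSequence`, making every run
exactly reproducible; simultaneous threshold crossings are reported in
population-concatenation index order, which only affects tie order in the
raster, not the dynamics.

## The oscillator

The oscillator motif is a PING-style pair: 400 excitatory (E) and 100
inhibitory (I) neurons with all four recurrent connection classes (E→E,
E→I, I→E, I→I).  Two calibrated operating points are shipped:

* **Encoder operating point** (`OscillatorParams()` defaults): strong I→E
  (4 mV, `tau_inh = 12 ms`).  Under sustained excitatory drive the E
  population fires in synchronized volleys whose frequency grows with the
  net drive to E — roughly 19 Hz near rheobase up to ~33 Hz, where the
  inhibition time constant caps the rhythm.
* **Router operating point** (`default_router_oscillator()`): weaker I→E
  (2 mV, `tau_inh = 8 ms`) and sub-threshold background, so the circuit is
  silent without input and follows an external rhythmic drive one volley
  per cycle (~1 spike per E neuron per cycle) across 12–36 Hz.

A central empirical finding of the calibration, which shaped the design:
in this class of balanced circuits the oscillation frequency tracks the
net drive to the *E* population and is nearly invariant to tonic drive to
the *I* population (the network re-balances; extra I drive lowers E rate
and oscillation power but not frequency).  Frequency coding therefore has
to route through E-side excitation.

## Encoder (spatial → temporal)

Each engram source population (20 neurons) projects to the oscillator's E
cells (fixed weight) and to its I cells twice: directly (mono-synaptic)
and through a dedicated 10-neuron excitatory relay (di-synaptic, 2 ms per
hop, so the di path is strictly slower than the mono path).  The relay
projects to the oscillator's I cells and sends collaterals to its E cells.

The engram's identity is carried purely by its mono/di weight ratio `r`:
with the output budget `Q = 2 mV` fixed, the mono-synaptic source→I weight
is `Q·r/(1+r)` and the di-synaptic budget `Q/(1+r)` scales the relay's
output synapses.  A relay-dominated engram (small `r`) therefore delivers
mostly relayed excitation and drives a fast, strong rhythm; a
mono-dominated engram (large `r`) recruits direct inhibition and yields a
slow, weaker one.  The calibration sweep (`calibrate_weight_frequency_map`,
7 ratios × 5 seeds) gives a strictly monotone map, about 31 Hz at
`r = 0.1` down to 19 Hz at `r = 8`, with peak power co-varying.  The
default three-engram ratios (8, 1, 0.1) place the engrams at ~19.5, ~25.7
and ~32 Hz.

## Router (temporal → spatial)

Input1 (half-rectified sinusoid — the simplest non-negative periodic
current with a single spectral peak) reaches the oscillator's I population
di-synaptically through a 20-neuron input relay; Input2 is a constant
mono-synaptic current on the same I cells, holding them near threshold so
that Input1's peaks gate the rhythm.  The input relay also sends
collaterals onto the oscillator E cells: each drive cycle releases one E
volley, so the oscillator's mean E rate R is essentially linear in the
drive frequency f over 12–36 Hz (measured R ≈ 14, 19, 25, 32 Hz at f = 12,
19, 25, 32 Hz, with seed-to-seed SD ≈ 0.1–0.7 Hz), and the baseline
(Input2 only) is silent.

Each engram readout part is a small interconnected E–I pair (40 E, 10 I)
acting as a *rate-band detector* on R:

* the part's E cells integrate the oscillator through a slow excitatory
  synapse (`tau_input_e = 35 ms`, membrane 15 ms); the input weight `w_e`
  sets the lower cutoff (steady drive crosses threshold only above
  R ≈ 5.3/w_e);
* the part's I cells integrate the same signal even more smoothly
  (`tau_input_i = 80 ms`, membrane 15 ms) through `w_i` and veto the E
  cells with strong inhibition (10 mV, `tau = 30 ms`) once R exceeds the
  upper cutoff; the I pathway leads the E pathway by ~3.5 ms of delay so
  the veto engages promptly;
* a weak recurrent E→E loop (0.2 mV) stabilizes firing once the band
  matches.

The calibrated weight sets — (0.32, 0.22), (0.24, 0.17), (0.19, 0.13) for
parts 1–3 — tile R so parts 1/2/3 follow the low/medium/high drive bands
(19/25/32 Hz).  At defaults (10 seeds per condition) the selectivity
matrix has diagonal winners with positive winner margins in 10/10 seeds
per row, and the matched part ignites 120–200 ms after drive onset
(seed-averaged ≈ 150 ms).  Activation is defined as the first run of 3
consecutive 10-ms bins at ≥ 3× the pre-onset baseline rate, floored at
10 Hz so an empty baseline does not make stray spikes count.

## Stimuli

Drives are deterministic per-step current vectors (mV/ms), exactly zero
outside their `[onset, offset)` window; mono-synaptic drives inject into
the target population, di-synaptic drives into their relay.  Only the
background noise is stochastic.

## Analysis

Population rate: spike count / (bin width × population size), 1 ms bins
for spectra, 10 ms for activation.  Spectra: Welch on the z-scored rate
trace, 1 s Hann segments, 50 % overlap, analysis band 2–80 Hz (≈1 Hz
resolution).  The experiment pipeline smooths the rate trace with a 3 ms
Gaussian first, which damps volley harmonics so the detected peak is the
fundamental, and flags windows with mean rate < 1 Hz or peaks below 5× the
in-band median power as "no oscillation".

Engram decoding is nearest-reference in (peak frequency, peak power)
space.  References are per-engram means over calibration seeds; features
are whitened by the pooled within-engram dispersion of those calibration
runs (frequency SD ≈ 0.5 Hz dominates the metric, as it should — power's
between-engram gaps are small relative to its seed noise).  Decoding of
held-out seeds at defaults is 100 % correct (≥ 90 % is the package's
acceptance bar).

## Experiment protocols and problem sizes

* Temporal→spatial: 3 conditions × 10 seeds, 1 s baseline + 3 s drive.
* Spatial→temporal: 3 engrams × 10 seeds (5 calibration + 5 held out),
  0.5 s baseline + 3 s drive.
* Round trip: 3 engrams × 20 trials; each trial simulates the encoder,
  replays the measured dominant frequency as a clean Input1 to the router
  (isolating the frequency code; the raw rate trace is deliberately not
  replayed), and scores whether the matching part wins.  Defaults give
  60/60 correct (bar: ≥ 90 % and above chance at binomial p < 0.01).
* Sweep: 7 ratios × 5 seeds.

Per-trial seeds are derived from the experiment base seed by a fixed
affine rule (`trial_seed`), so reports are reproducible byte for byte.
These scales keep a full experiment under about a minute on one CPU while
leaving ≥ 3 s of rhythm for 1 Hz spectral resolution and ≥ 8 positive-
margin seeds out of 10 per row.

## What the model does and does not show

The synthetic circuits emulate: sparse engram populations as labelled
sub-populations, PING-style rhythm generation, mono/di-synaptic routing of
engram output onto inhibition, and frequency-selective ignition of
readout populations.  They do not emulate: synaptic plasticity or
consolidation dynamics (weight sets are fixed by construction),
conductance-based or multi-compartment neurons, anatomically mapped
connectivity, heterogeneous cell parameters within a population, or
cross-part (winner-take-all) inhibition — adding the latter would sharpen
selectivity further.

Known limitations worth stating plainly:

* **Frequency range.** The oscillator covers ~19–33 Hz (beta/low gamma).
  Theta-range rhythms are outside the reachable span of this operating
  point, so the "low/medium/high" bands are 19/25/32 Hz, not 5/20/40 Hz.
* **Out-of-band drive aliases.** Far-above-band Input1 (e.g. 70 Hz) does
  not silence the router: the rectified drive's mean plus subharmonic
  following regress the oscillator toward a genuine ~17–19 Hz rhythm,
  which the low-band part correctly treats as low-frequency oscillation.
  Selectivity claims therefore hold *within* the calibrated band, not as
  a band-stop filter against arbitrary inputs.
* **Mechanism of selectivity.** Band selectivity is mediated by the
  monotone frequency→mean-rate transfer of the gated oscillator plus
  two-threshold rate detectors, not by phase-locking resonance.  It is
  one admissible realization of the proposed conversion, reconstructed
  from the circuit's stated architecture; the original model's equations
  are not public.
* Passing tests show the two conversions work in this synthetic,
  stationary, noise-controlled setting; they are not evidence about
  biological engram circuits.
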