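"""Stochastic leaky integrate-and-fire population dynamics.

The simulator advances current-based LIF neurons with forward Euler at a
fixed step ``dt``.  Each neuron obeys

    dV/dt = (v_rest - V) / tau_m + I_syn(t) + I_drive(t)        [mV/ms]

and emits a spike when ``V >= v_thresh`` at the end of a step, after which
``V`` is clamped to ``v_reset`` for the absolute refractory period.
Synaptic events arrive after their axonal delay and inject an exponentially
decaying current whose time integral equals the connection weight, so a
weight of ``w`` mV moves the membrane by ``w`` mV in total (and by ~``w`` at
the peak when ``tau_syn << tau_m``).  Background noise is a homogeneous
Poisson train per neuron; each event jumps the membrane instantaneously by
``background_weight``.

All randomness (connectivity realization and background noise) derives from
``SimulationConfig.seed`` through a :class:`numpy.random.SeedSequence`, so a
given (network, drives, config) triple reproduces its raster bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterator, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .circuits import NetworkSpec
    from .stimuli import DriveSpec

__all__ = [
    "PopulationSpec",
    "ConnectionSpec",
    "SimulationConfig",
    "SpikeRaster",
    "SimulationAbort",
    "step_lif",
    "poisson_background",
    "run_simulation",
    "lif_first_passage_time",
    "write_raster",
    "read_raster",
]


class SimulationAbort(RuntimeError):
    """Raised when the integrator detects non-finite membrane potentials."""


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    """A homogeneous population of LIF neurons.

    Parameters
    ----------
    name
        Unique population identifier.
    size
        Number of neurons (>= 1).
    cell_type
        ``"excitatory"`` or ``"inhibitory"``; fixes the sign of every
        outgoing connection (Dale's law).
    tau_m
        Membrane time constant, ms.
    v_rest, v_thresh, v_reset
        Resting, threshold and post-spike reset potentials, mV
        (``v_reset < v_thresh`` required).
    t_ref
        Absolute refractory period, ms.
    background_rate
        Poisson noise rate per neuron, Hz.
    background_weight
        Membrane jump per background event, mV.
    """

    name: str
    size: int
    cell_type: str
    tau_m: float = 10.0
    v_rest: float = -70.0
    v_thresh: float = -54.0
    v_reset: float = -70.0
    t_ref: float = 2.0
    background_rate: float = 0.0
    background_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_type not in ("excitatory", "inhibitory"):
            raise ValueError(
                f"population {self.name!r}: cell_type must be 'excitatory' or "
                f"'inhibitory', got {self.cell_type!r}"
            )
        if self.size < 1:
            raise ValueError(f"population {self.name!r}: size must be >= 1")
        if self.tau_m <= 0:
            raise ValueError(f"population {self.name!r}: tau_m must be > 0")
        if not self.v_reset < self.v_thresh:
            raise ValueError(
                f"population {self.name!r}: v_reset must be below v_thresh"
            )
        if self.t_ref < 0:
            raise ValueError(f"population {self.name!r}: t_ref must be >= 0")
        if self.background_rate < 0:
            raise ValueError(
                f"population {self.name!r}: background_rate must be >= 0"
            )

    @property
    def is_excitatory(self) -> bool:
        return self.cell_type == "excitatory"


@dataclass(frozen=True)
class ConnectionSpec:
    """A synaptic projection between two populations.

    ``weight`` is the unsigned per-spike potential transfer in mV; the
    effective sign is taken from the source population's cell type.
    ``probability`` is the independent connection probability per
    (source, target) pair; ``delay`` (ms) must be at least one integration
    step; ``tau_syn`` (ms) sets the exponential decay of the injected
    current.
    """

    source: str
    target: str
    weight: float
    probability: float = 1.0
    delay: float = 1.0
    tau_syn: float = 4.0

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError(
                f"connection {self.source}->{self.target}: weight must be >= 0 "
                "(the sign comes from the source cell type)"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(
                f"connection {self.source}->{self.target}: probability must be "
                "in [0, 1]"
            )
        if self.delay <= 0:
            raise ValueError(
                f"connection {self.source}->{self.target}: delay must be > 0"
            )
        if self.tau_syn <= 0:
            raise ValueError(
                f"connection {self.source}->{self.target}: tau_syn must be > 0"
            )


@dataclass(frozen=True)
class SimulationConfig:
    """Integration step, duration, seed and recording flags."""

    dt: float = 0.1
    duration: float = 1000.0
    seed: int = 0
    record_voltages: bool = False

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.duration < self.dt:
            raise ValueError("duration must be >= dt")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


# --------------------------------------------------------------------------
# raster
# --------------------------------------------------------------------------

@dataclass
class SpikeRaster:
    """Spike events of a simulated run, grouped by population.

    Events are stored per population as parallel ``(neuron_index, time_ms)``
    arrays sorted by time.  ``events()`` yields the merged, time-sorted
    stream.  Two rasters compare equal iff they hold identical events.
    """

    duration: float
    populations: dict[str, int]
    neuron_ids: dict[str, np.ndarray] = field(default_factory=dict)
    times: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.populations:
            self.neuron_ids.setdefault(name, np.empty(0, dtype=np.int32))
            self.times.setdefault(name, np.empty(0, dtype=np.float64))

    def spikes(self, population: str) -> tuple[np.ndarray, np.ndarray]:
        """(neuron indices, spike times ms) for one population."""
        if population not in self.populations:
            raise KeyError(f"unknown population {population!r}")
        return self.neuron_ids[population], self.times[population]

    def n_spikes(self, population: str | None = None) -> int:
        if population is not None:
            return len(self.times[population])
        return sum(len(t) for t in self.times.values())

    def events(self) -> Iterator[tuple[str, int, float]]:
        """All events merged across populations, sorted by time then by
        population order then neuron index."""
        chunks = []
        for pi, name in enumerate(self.populations):
            ids, ts = self.neuron_ids[name], self.times[name]
            chunks.append((ts, np.full(len(ts), pi), ids))
        if not chunks:
            return iter(())
        ts = np.concatenate([c[0] for c in chunks])
        ps = np.concatenate([c[1] for c in chunks])
        ns = np.concatenate([c[2] for c in chunks])
        order = np.lexsort((ns, ps, ts))
        names = list(self.populations)
        return (
            (names[int(ps[i])], int(ns[i]), float(ts[i])) for i in order
        )

    def validate(self) -> None:
        """Assert the raster invariants (times in range, sorted, indices in
        range).  Raises ``ValueError`` on the first violation."""
        for name, size in self.populations.items():
            ids, ts = self.neuron_ids[name], self.times[name]
            if len(ids) != len(ts):
                raise ValueError(f"{name}: index/time length mismatch")
            if len(ts) == 0:
                continue
            if ts.min() < 0 or ts.max() > self.duration:
                raise ValueError(f"{name}: spike time outside [0, duration]")
            if np.any(np.diff(ts) < 0):
                raise ValueError(f"{name}: spike times not sorted")
            if ids.min() < 0 or ids.max() >= size:
                raise ValueError(f"{name}: neuron index out of range")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        if self.duration != other.duration or self.populations != other.populations:
            return False
        for name in self.populations:
            if not np.array_equal(self.neuron_ids[name], other.neuron_ids[name]):
                return False
            if not np.array_equal(self.times[name], other.times[name]):
                return False
        return True


def write_raster(raster: SpikeRaster, path_or_buf, header: dict | None = None) -> None:
    """Write a raster as delimited text: ``population<TAB>neuron<TAB>time_ms``.

    Header comment lines carry the duration, population sizes and any extra
    key/value pairs (typically seed and config hash).
    """
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf, "w") if own else path_or_buf
    try:
        fh.write(f"# duration_ms={raster.duration!r}\n")
        sizes = ",".join(f"{n}:{s}" for n, s in raster.populations.items())
        fh.write(f"# populations={sizes}\n")
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        for pop, idx, t in raster.events():
            fh.write(f"{pop}\t{idx}\t{t!r}\n")
    finally:
        if own:
            fh.close()


def read_raster(path_or_buf) -> SpikeRaster:
    """Inverse of :func:`write_raster` (header extras are ignored)."""
    own = isinstance(path_or_buf, (str, bytes)) or hasattr(path_or_buf, "__fspath__")
    fh = open(path_or_buf) if own else path_or_buf
    try:
        duration = 0.0
        populations: dict[str, int] = {}
        ids: dict[str, list[int]] = {}
        ts: dict[str, list[float]] = {}
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("duration_ms="):
                    duration = float(body.split("=", 1)[1])
                elif body.startswith("populations="):
                    for item in body.split("=", 1)[1].split(","):
                        if item:
                            name, size = item.rsplit(":", 1)
                            populations[name] = int(size)
                            ids[name] = []
                            ts[name] = []
                continue
            pop, idx, t = line.split("\t")
            ids[pop].append(int(idx))
            ts[pop].append(float(t))
        raster = SpikeRaster(duration=duration, populations=populations)
        for name in populations:
            order_ids = np.asarray(ids[name], dtype=np.int32)
            order_ts = np.asarray(ts[name], dtype=np.float64)
            raster.neuron_ids[name] = order_ids
            raster.times[name] = order_ts
        return raster
    finally:
        if own:
            fh.close()


# --------------------------------------------------------------------------
# single-step reference semantics
# --------------------------------------------------------------------------

def step_lif(
    state: dict,
    input_current: np.ndarray,
    pop: PopulationSpec,
    config: SimulationConfig,
) -> tuple[dict, np.ndarray]:
    """Advance one population one Euler step; reference implementation.

    ``state`` holds ``v`` (mV, shape ``(size,)``) and ``ref`` (remaining
    refractory steps, int).  Neurons in refractory ignore input and stay at
    ``v_reset``.  Returns the updated state and the indices of neurons that
    crossed threshold this step (reported in index order).

    The batched simulation loop in :func:`run_simulation` implements exactly
    these semantics; tests hold the two to account.
    """
    v = np.asarray(state["v"], dtype=np.float64).copy()
    ref = np.asarray(state["ref"], dtype=np.int64).copy()
    if v.shape != (pop.size,) or ref.shape != (pop.size,):
        raise ValueError("state dimensions do not match population size")
    input_current = np.asarray(input_current, dtype=np.float64)
    if input_current.shape != (pop.size,):
        raise ValueError("input_current shape does not match population size")

    active = ref == 0
    dv = config.dt * ((pop.v_rest - v) / pop.tau_m + input_current)
    v = np.where(active, v + dv, pop.v_reset)
    if not np.all(np.isfinite(v)):
        raise SimulationAbort(
            f"non-finite membrane potential in population {pop.name!r}"
        )
    ref = np.maximum(ref - 1, 0)
    spiking = np.flatnonzero(active & (v >= pop.v_thresh))
    ref_steps = int(round(pop.t_ref / config.dt))
    v[spiking] = pop.v_reset
    ref[spiking] = ref_steps
    return {"v": v, "ref": ref}, spiking


def lif_first_passage_time(
    drive: float, pop: PopulationSpec
) -> float:
    """Closed-form time-to-threshold of a LIF neuron under constant current.

    For constant drive ``I`` (mV/ms) starting from rest, the membrane
    approaches ``v_rest + I * tau_m`` and crosses threshold at

        t* = tau_m * ln( I tau_m / (I tau_m - (v_thresh - v_rest)) )

    Returns ``inf`` for subthreshold drive.
    """
    i_eff = drive * pop.tau_m
    gap = pop.v_thresh - pop.v_rest
    if i_eff <= gap:
        return math.inf
    return pop.tau_m * math.log(i_eff / (i_eff - gap))


# --------------------------------------------------------------------------
# background noise
# --------------------------------------------------------------------------

def poisson_background(
    rate: float, size: int, duration: float, seed: int | np.random.Generator
) -> list[tuple[int, float]]:
    """Independent homogeneous Poisson event trains, one per neuron.

    Returns ``(neuron_index, time_ms)`` pairs sorted by time.  Event times
    are drawn by cumulative exponential gaps with mean ``1000 / rate`` ms.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if rate == 0 or size == 0 or duration <= 0:
        return []
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mean_gap = 1000.0 / rate
    events: list[tuple[int, float]] = []
    for neuron in range(size):
        t = 0.0
        # draw in blocks to amortize RNG calls
        expected = max(8, int(duration / mean_gap * 1.5))
        gaps = rng.exponential(mean_gap, size=expected)
        cursor = 0
        while True:
            if cursor >= len(gaps):
                gaps = rng.exponential(mean_gap, size=expected)
                cursor = 0
            t += gaps[cursor]
            cursor += 1
            if t >= duration:
                break
            events.append((neuron, t))
    events.sort(key=lambda e: (e[1], e[0]))
    return events


# --------------------------------------------------------------------------
# full simulation
# --------------------------------------------------------------------------

def _compile_network(network: "NetworkSpec", config: SimulationConfig, rng):
    """Flatten a NetworkSpec into dense kernel arrays.

    Populations are concatenated in declaration order.  Connections sharing
    a (delay, tau_syn) pair are merged into one synapse class with a dense
    signed weight matrix; weights are divided by tau_syn so the injected
    exponential current integrates to the connection weight.
    """
    pops = list(network.populations)
    names = [p.name for p in pops]
    offsets: dict[str, tuple[int, int]] = {}
    cursor = 0
    for p in pops:
        offsets[p.name] = (cursor, cursor + p.size)
        cursor += p.size
    n_total = cursor

    def per_neuron(attr):
        return np.concatenate(
            [np.full(p.size, getattr(p, attr), dtype=np.float64) for p in pops]
        )

    tau_m = per_neuron("tau_m")
    v_rest = per_neuron("v_rest")
    v_thresh = per_neuron("v_thresh")
    v_reset = per_neuron("v_reset")
    bg_rate = per_neuron("background_rate")
    bg_weight = per_neuron("background_weight")
    ref_steps = np.concatenate(
        [
            np.full(p.size, int(round(p.t_ref / config.dt)), dtype=np.int64)
            for p in pops
        ]
    )

    pop_by_name = {p.name: p for p in pops}
    classes: dict[tuple[int, float], np.ndarray] = {}
    for conn in network.connections:
        src = pop_by_name[conn.source]
        lo_s, hi_s = offsets[conn.source]
        lo_t, hi_t = offsets[conn.target]
        delay_steps = max(1, int(round(conn.delay / config.dt)))
        key = (delay_steps, float(conn.tau_syn))
        if key not in classes:
            classes[key] = np.zeros((n_total, n_total), dtype=np.float64)
        sign = 1.0 if src.is_excitatory else -1.0
        block = np.full(
            (hi_t - lo_t, hi_s - lo_s), sign * conn.weight / conn.tau_syn
        )
        if conn.probability < 1.0:
            mask = rng.random(block.shape) < conn.probability
            block = block * mask
        if conn.source == conn.target:
            np.fill_diagonal(block, 0.0)  # no autapses
        classes[key][lo_t:hi_t, lo_s:hi_s] += block

    keys = sorted(classes)
    w = (
        np.stack([classes[k] for k in keys])
        if keys
        else np.zeros((0, n_total, n_total))
    )
    delays = np.array([k[0] for k in keys], dtype=np.int64)
    decays = np.array(
        [math.exp(-config.dt / k[1]) for k in keys], dtype=np.float64
    )
    return names, offsets, n_total, dict(
        tau_m=tau_m,
        v_rest=v_rest,
        v_thresh=v_thresh,
        v_reset=v_reset,
        ref_steps=ref_steps,
        bg_rate=bg_rate,
        bg_weight=bg_weight,
        w=w,
        delays=delays,
        decays=decays,
    )


def run_simulation(
    network: "NetworkSpec",
    drives: Sequence["DriveSpec"],
    config: SimulationConfig,
) -> SpikeRaster | tuple[SpikeRaster, np.ndarray]:
    """Simulate a network under external drives.

    Mono-synaptic drives inject their rendered current into every neuron of
    the target population; di-synaptic drives inject into the pathway's
    relay population (the relay's projection onto the target carries the
    second hop).  Returns the spike raster, plus the ``(n_steps, n_neurons)``
    voltage array when ``config.record_voltages`` is set.

    Raises ``SimulationAbort`` if the integrator produces non-finite
    potentials (pathological weights), and ``ValueError`` for drives naming
    unknown populations (checked before any stepping).
    """
    from .circuits import validate_network
    from .stimuli import render_drive

    violations = validate_network(network)
    if violations:
        raise ValueError("invalid network: " + "; ".join(violations))

    pop_names = {p.name for p in network.populations}
    for drv in drives:
        eff = drv.effective_target()
        if eff not in pop_names:
            raise ValueError(
                f"drive targets unknown population {eff!r} "
                "(configuration error, nothing simulated)"
            )

    ss = np.random.SeedSequence(config.seed)
    conn_ss, bg_ss = ss.spawn(2)
    names, offsets, n_total, arrs = _compile_network(
        network, config, np.random.default_rng(conn_ss)
    )

    n_steps = config.n_steps
    bg_rng = np.random.default_rng(bg_ss)
    lam = arrs["bg_rate"] * config.dt / 1000.0  # events per step
    if np.any(lam > 0):
        bg_counts = bg_rng.poisson(lam, size=(n_steps, n_total)).astype(np.float64)
    else:
        bg_counts = np.zeros((n_steps, n_total), dtype=np.float64)

    drive_traces = np.zeros((max(len(drives), 1), n_steps), dtype=np.float64)
    drive_lo = np.zeros(max(len(drives), 1), dtype=np.int64)
    drive_hi = np.zeros(max(len(drives), 1), dtype=np.int64)
    for i, drv in enumerate(drives):
        drive_traces[i] = render_drive(drv, config)
        drive_lo[i], drive_hi[i] = offsets[drv.effective_target()]

    from ._kernel import simulate

    spk_steps, spk_ids, volts, status = simulate(
        n_steps=n_steps,
        dt=config.dt,
        tau_m=arrs["tau_m"],
        v_rest=arrs["v_rest"],
        v_thresh=arrs["v_thresh"],
        v_reset=arrs["v_reset"],
        ref_steps=arrs["ref_steps"],
        w=arrs["w"],
        delays=arrs["delays"],
        decays=arrs["decays"],
        bg_counts=bg_counts,
        bg_weight=arrs["bg_weight"],
        drive_traces=drive_traces,
        drive_lo=drive_lo,
        drive_hi=drive_hi,
        n_drives=len(drives),
        record_voltages=config.record_voltages,
    )
    if status != 0:
        raise SimulationAbort(
            "non-finite membrane potential during integration; check weights "
            "and drive amplitudes"
        )

    raster = SpikeRaster(
        duration=config.duration,
        populations={p.name: p.size for p in network.populations},
    )
    spk_times = (spk_steps + 1) * config.dt  # crossing detected at step end
    for name in names:
        lo, hi = offsets[name]
        sel = (spk_ids >= lo) & (spk_ids < hi)
        raster.neuron_ids[name] = (spk_ids[sel] - lo).astype(np.int32)
        raster.times[name] = spk_times[sel]
    raster.validate()
    if config.record_voltages:
        return raster, volts
    return raster
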