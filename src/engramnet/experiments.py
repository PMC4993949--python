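"""Turn-key experiment drivers.

Four reproducible protocols built on the circuit builders:

* ``run_temporal_to_spatial`` — drive the router's oscillator with an
  oscillatory Input1 (di-synaptic, via the input relay) plus a constant
  Input2 (mono-synaptic) at several frequencies and measure which engram
  part ignites (selectivity matrix + activation delays).
* ``run_spatial_to_temporal`` — activate one engram source of the encoder
  at a time with sustained drive and measure the oscillator's spectral
  peak per engram, then decode engram identity from held-out spectra.
* ``run_round_trip`` — compose the two: encode an engram into an
  oscillation frequency, replay that frequency to the router, and score
  whether the matching part wins.
* ``calibrate_weight_frequency_map`` — sweep the mono/di weight ratio and
  record the seed-averaged (peak frequency, peak power) transfer map with
  its largest strictly monotone regime.

Per-trial seeds are derived deterministically from the experiment's base
seed (see :func:`trial_seed`), so every report is exactly reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as _stats

from . import circuits
from .analysis import (
    activation_delay,
    decode_engram,
    population_rate,
    power_spectrum,
    selectivity_matrix,
)
from .circuits import (
    EngramPartParams,
    EngramWeightSet,
    EncoderParams,
    OscillatorParams,
    RouterParams,
)
from .dynamics import SimulationConfig, run_simulation
from .stimuli import DI, PathwaySpec, make_constant_drive, make_oscillatory_drive

__all__ = [
    "ExperimentReport",
    "TransferMap",
    "T2SConfig",
    "S2TConfig",
    "RoundTripConfig",
    "SweepConfig",
    "trial_seed",
    "run_temporal_to_spatial",
    "run_spatial_to_temporal",
    "run_round_trip",
    "calibrate_weight_frequency_map",
]

log = logging.getLogger("engramnet.experiments")


def trial_seed(base_seed: int, condition_index: int, repeat: int) -> int:
    """Deterministic per-trial seed below 2**31."""
    return (
        base_seed * 1_000_003 + condition_index * 10_007 + repeat * 101 + 12_345
    ) % (2**31)


@dataclass
class ExperimentReport:
    """Outcome of one experiment driver.

    ``aggregate`` values are always recomputable from ``per_seed`` entries;
    ``passes`` holds the experiment's acceptance-property flags.
    """

    name: str
    config: dict
    config_hash: str
    seeds: list[int]
    per_seed: list[dict]
    aggregate: dict
    passes: dict[str, bool]

    @property
    def all_passed(self) -> bool:
        return all(self.passes.values())


@dataclass
class TransferMap:
    """Seed-averaged (control value -> peak frequency, peak power) map."""

    control: list[float]  # strictly increasing control values
    peak_frequency: list[float]
    peak_power: list[float]
    regime: tuple[int, int]  # [lo, hi] index bounds of the monotone regime

    def regime_controls(self) -> list[float]:
        lo, hi = self.regime
        return self.control[lo : hi + 1]


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

@dataclass
class AnalysisSettings:
    band: tuple[float, float] = (2.0, 80.0)
    rate_bin_ms: float = 1.0
    segment_ms: float = 1000.0
    # Gaussian smoothing of the rate trace before the spectrum; damps the
    # harmonics of sharp population volleys so the peak is the fundamental
    smooth_ms: float = 3.0
    # below this mean population rate the window is treated as silent:
    # a population oscillation requires population activity
    min_rate_hz: float = 1.0
    delay_bin_ms: float = 10.0
    delay_threshold_factor: float = 3.0
    delay_consecutive_bins: int = 3
    delay_rate_floor: float = 10.0

    @property
    def resolution(self) -> float:
        """Spectral resolution in Hz."""
        return 1000.0 / self.segment_ms


@dataclass
class T2SConfig:
    """Temporal-to-spatial routing experiment settings."""

    conditions: tuple[float, ...] = (19.0, 25.0, 32.0)  # Hz: low/medium/high
    n_seeds: int = 10
    base_seed: int = 0
    baseline_ms: float = 1000.0
    drive_ms: float = 3000.0
    dt: float = 0.1
    input1_amplitude: float = 2.4
    input2_amplitude: float = 0.4
    weight_sets: Optional[list[EngramWeightSet]] = None
    osc_params: Optional[OscillatorParams] = None
    part_params: Optional[EngramPartParams] = None
    router_params: Optional[RouterParams] = None
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    @property
    def duration(self) -> float:
        return self.baseline_ms + self.drive_ms


@dataclass
class S2TConfig:
    """Spatial-to-temporal encoding experiment settings."""

    n_engrams: int = 3
    ratios: Optional[list[float]] = None
    n_seeds: int = 10
    n_calibration_seeds: int = 5
    base_seed: int = 0
    baseline_ms: float = 500.0
    drive_ms: float = 3000.0
    dt: float = 0.1
    source_amplitude: float = 2.2
    osc_params: Optional[OscillatorParams] = None
    enc_params: Optional[EncoderParams] = None
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    @property
    def duration(self) -> float:
        return self.baseline_ms + self.drive_ms


@dataclass
class RoundTripConfig:
    """Composition of the encoder and router experiments."""

    n_seeds: int = 20  # trials per engram
    base_seed: int = 0
    encoder: S2TConfig = field(default_factory=S2TConfig)
    router: T2SConfig = field(default_factory=T2SConfig)


@dataclass
class SweepConfig:
    """Mono/di ratio sweep settings for the calibration transfer map."""

    ratios: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    n_seeds: int = 5
    base_seed: int = 0
    encoder: S2TConfig = field(default_factory=S2TConfig)


def _config_dict(cfg) -> dict:
    return asdict(cfg)


def _config_hash(cfg_dict: dict) -> str:
    from .io_cli import config_hash

    return config_hash(cfg_dict)


# --------------------------------------------------------------------------
# temporal -> spatial (router)
# --------------------------------------------------------------------------

def _router_drives(cfg: T2SConfig, frequency: float):
    input1 = make_oscillatory_drive(
        frequency=frequency,
        amplitude=cfg.input1_amplitude,
        onset=cfg.baseline_ms,
        offset=cfg.duration,
        pathway=PathwaySpec(kind=DI, relay="input_relay"),
        target="osc_I",
    )
    input2 = make_constant_drive(
        amplitude=cfg.input2_amplitude,
        onset=0.0,
        offset=cfg.duration,
        target="osc_I",
    )
    return [input1, input2]


def _simulate_router_condition(cfg: T2SConfig, frequency: float, seed: int):
    net = circuits.build_router(
        cfg.osc_params, cfg.weight_sets, cfg.part_params, cfg.router_params
    )
    sim = SimulationConfig(dt=cfg.dt, duration=cfg.duration, seed=seed)
    raster = run_simulation(net, _router_drives(cfg, frequency), sim)
    return net, raster


def run_temporal_to_spatial(cfg: T2SConfig | None = None) -> ExperimentReport:
    """Frequency-selective routing: which part follows which drive band.

    For every drive-frequency condition and seed the router is rebuilt
    (fresh connectivity + noise), stimulated with Input1/Input2, and scored:
    evoked activation per part (drive window minus baseline) and the
    activation delay of every part.  Aggregates are seed-averaged; pass
    flags assert diagonal row winners, positive winner margins in >= 8/10
    seeds per row, and matched-part delays at or below 200 ms.
    """
    cfg = cfg or T2SConfig()
    if len(cfg.conditions) < 2:
        raise ValueError("need at least two frequency conditions")
    sets = cfg.weight_sets or circuits.default_weight_sets()
    n_parts = len(sets)
    a = cfg.analysis

    per_seed: list[dict] = []
    seeds_used: list[int] = []
    window = (cfg.baseline_ms, cfg.duration)
    for ci, freq in enumerate(cfg.conditions):
        for rep in range(cfg.n_seeds):
            seed = trial_seed(cfg.base_seed, ci, rep)
            log.debug("t2s condition %s Hz repeat %d -> seed %d", freq, rep, seed)
            seeds_used.append(seed)
            net, raster = _simulate_router_condition(cfg, freq, seed)
            parts = [pe for pe, _ in net.engram_part_roles()]
            sel = selectivity_matrix(
                {freq: raster}, parts, window, bin_width=a.delay_bin_ms
            )
            delays = []
            for pe in parts:
                dm = activation_delay(
                    raster,
                    pe,
                    onset=cfg.baseline_ms,
                    threshold_factor=a.delay_threshold_factor,
                    n_consecutive=a.delay_consecutive_bins,
                    bin_width=a.delay_bin_ms,
                    rate_floor=a.delay_rate_floor,
                )
                delays.append(dm.delay)
            row = sel.matrix[0]
            matched = ci if ci < n_parts else None
            margin = None
            if matched is not None and not sel.silent_rows[0]:
                others = np.delete(row, matched)
                margin = float(row[matched] - others.max()) if len(others) else 1.0
            per_seed.append(
                dict(
                    condition=freq,
                    condition_index=ci,
                    seed=seed,
                    raw_activation=[float(x) for x in sel.raw[0]],
                    normalized=[float(x) for x in row],
                    winner=sel.winners[0],
                    silent=sel.silent_rows[0],
                    delays_ms=delays,
                    matched_margin=margin,
                )
            )

    # seed-averaged selectivity matrix
    raw_mean = np.zeros((len(cfg.conditions), n_parts))
    for ci in range(len(cfg.conditions)):
        rows = [e["raw_activation"] for e in per_seed if e["condition_index"] == ci]
        raw_mean[ci] = np.mean(rows, axis=0)
    norm = np.zeros_like(raw_mean)
    winners: list[Optional[int]] = []
    for ci in range(len(cfg.conditions)):
        tot = raw_mean[ci].sum()
        if tot > 0:
            norm[ci] = raw_mean[ci] / tot
            winners.append(int(np.argmax(raw_mean[ci])))
        else:
            winners.append(None)

    matched_delays: list[Optional[float]] = []
    response_fraction: list[float] = []
    margin_positive: list[int] = []
    for ci in range(min(len(cfg.conditions), n_parts)):
        entries = [e for e in per_seed if e["condition_index"] == ci]
        ds = [e["delays_ms"][ci] for e in entries if e["delays_ms"][ci] is not None]
        matched_delays.append(float(np.mean(ds)) if ds else None)
        response_fraction.append(len(ds) / len(entries))
        margin_positive.append(
            sum(1 for e in entries if (e["matched_margin"] or 0) > 0)
        )

    diag = list(range(min(len(cfg.conditions), n_parts)))
    passes = {
        "row_winners_match_parts": winners[: len(diag)] == diag,
        "matched_delay_le_200ms": all(
            d is not None and d <= 200.0 for d in matched_delays
        ),
        "margin_positive_in_8_of_10": all(
            m >= int(np.ceil(0.8 * cfg.n_seeds)) for m in margin_positive
        ),
    }
    cfg_dict = _config_dict(cfg)
    return ExperimentReport(
        name="temporal_to_spatial",
        config=cfg_dict,
        config_hash=_config_hash(cfg_dict),
        seeds=seeds_used,
        per_seed=per_seed,
        aggregate=dict(
            conditions=list(cfg.conditions),
            selectivity_raw=raw_mean.tolist(),
            selectivity=norm.tolist(),
            winners=winners,
            matched_delay_ms=matched_delays,
            response_fraction=response_fraction,
            margin_positive_count=margin_positive,
            mean_matched_delay_ms=(
                float(np.mean([d for d in matched_delays if d is not None]))
                if any(d is not None for d in matched_delays)
                else None
            ),
        ),
        passes=passes,
    )


# --------------------------------------------------------------------------
# spatial -> temporal (encoder)
# --------------------------------------------------------------------------

def _simulate_encoder_engram(cfg: S2TConfig, engram_index: int, seed: int):
    """Simulate the encoder with only one engram source driven."""
    ratios = cfg.ratios or circuits.default_ratios()[: cfg.n_engrams]
    net = circuits.build_encoder(cfg.n_engrams, ratios, cfg.osc_params, cfg.enc_params)
    drive = make_constant_drive(
        amplitude=cfg.source_amplitude,
        onset=cfg.baseline_ms,
        offset=cfg.duration,
        target=net.role(f"engram_source_{engram_index + 1}"),
    )
    sim = SimulationConfig(dt=cfg.dt, duration=cfg.duration, seed=seed)
    raster = run_simulation(net, [drive], sim)
    return net, raster


def _oscillator_spectrum(net, raster, cfg, a: AnalysisSettings):
    from scipy.ndimage import gaussian_filter1d

    from .analysis import RateTrace

    trace = population_rate(raster, net.role("oscillator_E"), a.rate_bin_ms)
    t = trace.times
    sel = (t >= cfg.baseline_ms) & (t < cfg.duration)
    rates = trace.rates[sel]
    if rates.mean() < a.min_rate_hz:
        from .analysis import SpectrumResult

        return SpectrumResult(
            np.array(a.band), np.zeros(2), np.nan, 0.0, no_peak=True
        )
    if a.smooth_ms > 0:
        rates = gaussian_filter1d(rates, a.smooth_ms / a.rate_bin_ms)
    drive_trace = RateTrace(trace.population, trace.bin_width, rates)
    return power_spectrum(drive_trace, band=a.band, segment_ms=a.segment_ms)


def run_spatial_to_temporal(cfg: S2TConfig | None = None) -> ExperimentReport:
    """Engram identity -> oscillation frequency/power.

    Each engram source in turn receives a sustained constant drive; the
    oscillator's rate spectrum is measured per seed.  References built from
    the first ``n_calibration_seeds`` seeds decode the remaining held-out
    seeds' engram identity by nearest (frequency, power).  Pass flags
    assert pairwise peak separation beyond the spectral resolution and
    held-out decoding accuracy >= 90%.
    """
    cfg = cfg or S2TConfig()
    if cfg.n_engrams < 2:
        raise ValueError("need at least two engram sources")
    if not 0 < cfg.n_calibration_seeds < cfg.n_seeds:
        raise ValueError("n_calibration_seeds must split the seed range")
    a = cfg.analysis

    per_seed: list[dict] = []
    seeds_used: list[int] = []
    for k in range(cfg.n_engrams):
        for rep in range(cfg.n_seeds):
            seed = trial_seed(cfg.base_seed, k, rep)
            log.debug("s2t engram %d repeat %d -> seed %d", k + 1, rep, seed)
            seeds_used.append(seed)
            net, raster = _simulate_encoder_engram(cfg, k, seed)
            spec = _oscillator_spectrum(net, raster, cfg, a)
            per_seed.append(
                dict(
                    engram=k + 1,
                    repeat=rep,
                    seed=seed,
                    peak_frequency=(
                        None if spec.no_peak else float(spec.peak_frequency)
                    ),
                    peak_power=float(spec.peak_power),
                    no_peak=bool(spec.no_peak),
                )
            )

    def entries(k):
        return [e for e in per_seed if e["engram"] == k + 1]

    mean_freq, mean_power, sd_freq = [], [], []
    for k in range(cfg.n_engrams):
        fs = [e["peak_frequency"] for e in entries(k) if not e["no_peak"]]
        ps = [e["peak_power"] for e in entries(k) if not e["no_peak"]]
        mean_freq.append(float(np.mean(fs)) if fs else None)
        sd_freq.append(float(np.std(fs)) if fs else None)
        mean_power.append(float(np.mean(ps)) if ps else None)

    resolution = a.resolution
    seps = []
    for i in range(cfg.n_engrams):
        for j in range(i + 1, cfg.n_engrams):
            if mean_freq[i] is None or mean_freq[j] is None:
                seps.append(0.0)
            else:
                seps.append(abs(mean_freq[i] - mean_freq[j]))
    separable = bool(seps) and min(seps) > resolution

    # held-out decoding against calibration-seed references; features are
    # whitened by the pooled within-engram dispersion of the calibration runs
    calibration = {}
    devs_f: list[float] = []
    devs_p: list[float] = []
    for k in range(cfg.n_engrams):
        cal = [
            e
            for e in entries(k)
            if e["repeat"] < cfg.n_calibration_seeds and not e["no_peak"]
        ]
        if cal:
            mf = float(np.mean([e["peak_frequency"] for e in cal]))
            mp = float(np.mean([e["peak_power"] for e in cal]))
            calibration[k + 1] = (mf, mp)
            devs_f += [e["peak_frequency"] - mf for e in cal]
            devs_p += [e["peak_power"] - mp for e in cal]
    scale = None
    if len(devs_f) > len(calibration):
        scale = (
            max(float(np.std(devs_f)), 1e-9),
            max(float(np.std(devs_p)), 1e-9),
        )
    n_correct = n_eval = 0
    from .analysis import SpectrumResult

    for e in per_seed:
        if e["repeat"] < cfg.n_calibration_seeds:
            continue
        n_eval += 1
        if e["no_peak"] or not calibration:
            continue
        spec = SpectrumResult(
            frequencies=np.empty(0),
            power=np.empty(0),
            peak_frequency=e["peak_frequency"],
            peak_power=e["peak_power"],
        )
        if decode_engram(spec, calibration, scale=scale).engram_id == e["engram"]:
            n_correct += 1
    accuracy = n_correct / n_eval if n_eval else 0.0

    passes = {
        "peaks_pairwise_separated": separable,
        "decode_accuracy_ge_90": accuracy >= 0.9,
    }
    cfg_dict = _config_dict(cfg)
    return ExperimentReport(
        name="spatial_to_temporal",
        config=cfg_dict,
        config_hash=_config_hash(cfg_dict),
        seeds=seeds_used,
        per_seed=per_seed,
        aggregate=dict(
            peak_frequency_hz=mean_freq,
            peak_frequency_sd=sd_freq,
            peak_power=mean_power,
            min_pairwise_separation_hz=(min(seps) if seps else None),
            spectral_resolution_hz=resolution,
            calibration=
            {str(k): list(v) for k, v in calibration.items()},
            decode_accuracy=accuracy,
            n_heldout=n_eval,
        ),
        passes=passes,
    )


# --------------------------------------------------------------------------
# round trip
# --------------------------------------------------------------------------

def run_round_trip(cfg: RoundTripConfig | None = None) -> ExperimentReport:
    """Spatial -> temporal -> spatial identity recovery.

    Per trial: drive engram source k in the encoder, take the oscillator's
    dominant frequency, replay it as a clean oscillatory Input1 to the
    router, and check that engram part k wins the selectivity row.  An
    encoder run that produces no oscillation counts as a failed trial.
    Pass flags: accuracy >= 90% and above chance with binomial p < 0.01.
    """
    cfg = cfg or RoundTripConfig()
    enc, rtr = cfg.encoder, cfg.router
    n_engrams = enc.n_engrams
    a = rtr.analysis
    window = (rtr.baseline_ms, rtr.duration)

    per_seed: list[dict] = []
    seeds_used: list[int] = []
    for k in range(n_engrams):
        for rep in range(cfg.n_seeds):
            enc_seed = trial_seed(cfg.base_seed, k, rep)
            rtr_seed = trial_seed(cfg.base_seed + 7_919, k, rep)
            seeds_used += [enc_seed, rtr_seed]
            net_e, raster_e = _simulate_encoder_engram(enc, k, enc_seed)
            spec = _oscillator_spectrum(net_e, raster_e, enc, enc.analysis)
            entry = dict(
                engram=k + 1,
                repeat=rep,
                encoder_seed=enc_seed,
                router_seed=rtr_seed,
                encoded_frequency=(
                    None if spec.no_peak else float(spec.peak_frequency)
                ),
                no_oscillation=bool(spec.no_peak),
                winner=None,
                correct=False,
            )
            if not spec.no_peak:
                net_r, raster_r = _simulate_router_condition(
                    rtr, float(spec.peak_frequency), rtr_seed
                )
                parts = [pe for pe, _ in net_r.engram_part_roles()]
                sel = selectivity_matrix(
                    {0: raster_r}, parts, window, bin_width=a.delay_bin_ms
                )
                entry["winner"] = (
                    None if sel.winners[0] is None else sel.winners[0] + 1
                )
                entry["correct"] = entry["winner"] == k + 1
            per_seed.append(entry)

    n_trials = len(per_seed)
    n_correct = sum(e["correct"] for e in per_seed)
    accuracy = n_correct / n_trials if n_trials else 0.0
    chance = 1.0 / n_engrams
    pvalue = float(
        _stats.binomtest(n_correct, n_trials, chance, alternative="greater").pvalue
    )
    per_engram_acc = [
        float(
            np.mean([e["correct"] for e in per_seed if e["engram"] == k + 1])
        )
        for k in range(n_engrams)
    ]
    passes = {
        "accuracy_ge_90": accuracy >= 0.9,
        "above_chance_p_lt_0.01": pvalue < 0.01,
    }
    cfg_dict = _config_dict(cfg)
    return ExperimentReport(
        name="round_trip",
        config=cfg_dict,
        config_hash=_config_hash(cfg_dict),
        seeds=seeds_used,
        per_seed=per_seed,
        aggregate=dict(
            n_trials=n_trials,
            n_correct=n_correct,
            accuracy=accuracy,
            per_engram_accuracy=per_engram_acc,
            chance_level=chance,
            binomial_pvalue=pvalue,
        ),
        passes=passes,
    )


# --------------------------------------------------------------------------
# calibration sweep
# --------------------------------------------------------------------------

def _longest_monotone_regime(values: Sequence[float]) -> tuple[int, int]:
    """Index bounds of the longest strictly monotone contiguous run."""
    best = (0, 0)
    n = len(values)
    i = 0
    while i < n - 1:
        for direction in (1, -1):
            j = i
            while (
                j < n - 1
                and values[j + 1] is not None
                and values[j] is not None
                and direction * (values[j + 1] - values[j]) > 0
            ):
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
        i += 1
    return best


def calibrate_weight_frequency_map(
    cfg: SweepConfig | None = None,
) -> tuple[TransferMap, ExperimentReport]:
    """Sweep the mono/di ratio of a single-engram encoder.

    Returns the seed-averaged transfer map (ratio -> peak frequency and
    power) with its largest strictly monotone frequency regime, plus a full
    report.  The default weight sets and drive bands of the other
    experiments were chosen from this map's monotone regime.
    """
    cfg = cfg or SweepConfig()
    if len(cfg.ratios) < 1:
        raise ValueError("sweep needs at least one ratio value")
    if len(set(cfg.ratios)) != len(cfg.ratios) or list(cfg.ratios) != sorted(
        cfg.ratios
    ):
        raise ValueError("sweep ratios must be strictly increasing")
    if cfg.n_seeds < 1:
        raise ValueError("sweep needs at least one seed per point")

    enc = cfg.encoder
    per_seed: list[dict] = []
    seeds_used: list[int] = []
    for ci, ratio in enumerate(cfg.ratios):
        one = S2TConfig(
            n_engrams=1,
            ratios=[ratio],
            n_seeds=cfg.n_seeds,
            n_calibration_seeds=1,
            base_seed=cfg.base_seed,
            baseline_ms=enc.baseline_ms,
            drive_ms=enc.drive_ms,
            dt=enc.dt,
            source_amplitude=enc.source_amplitude,
            osc_params=enc.osc_params,
            enc_params=enc.enc_params,
            analysis=enc.analysis,
        )
        for rep in range(cfg.n_seeds):
            seed = trial_seed(cfg.base_seed, ci, rep)
            seeds_used.append(seed)
            net, raster = _simulate_encoder_engram(one, 0, seed)
            spec = _oscillator_spectrum(net, raster, one, enc.analysis)
            per_seed.append(
                dict(
                    ratio=float(ratio),
                    repeat=rep,
                    seed=seed,
                    peak_frequency=(
                        None if spec.no_peak else float(spec.peak_frequency)
                    ),
                    peak_power=float(spec.peak_power),
                    no_peak=bool(spec.no_peak),
                )
            )

    freqs, powers = [], []
    for ratio in cfg.ratios:
        fs = [
            e["peak_frequency"]
            for e in per_seed
            if e["ratio"] == ratio and not e["no_peak"]
        ]
        ps = [
            e["peak_power"]
            for e in per_seed
            if e["ratio"] == ratio and not e["no_peak"]
        ]
        freqs.append(float(np.mean(fs)) if fs else None)
        powers.append(float(np.mean(ps)) if ps else None)
    regime = _longest_monotone_regime(freqs)
    tmap = TransferMap(
        control=list(cfg.ratios),
        peak_frequency=freqs,
        peak_power=powers,
        regime=regime,
    )
    lo, hi = regime
    passes = {
        "monotone_regime_ge_5_points": hi - lo + 1 >= min(5, len(cfg.ratios)),
    }
    cfg_dict = _config_dict(cfg)
    report = ExperimentReport(
        name="weight_frequency_sweep",
        config=cfg_dict,
        config_hash=_config_hash(cfg_dict),
        seeds=seeds_used,
        per_seed=per_seed,
        aggregate=dict(
            control=tmap.control,
            peak_frequency_hz=tmap.peak_frequency,
            peak_power=tmap.peak_power,
            regime=list(regime),
        ),
        passes=passes,
    )
    return tmap, report
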