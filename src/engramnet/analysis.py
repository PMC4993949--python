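"""Quantification of simulated activity.

Population rates, Welch power spectra of the rate signal, oscillation peak
frequency/power, engram activation delay, condition-by-part selectivity
matrices, and spectrum-based decoding of engram identity.

Spectra are computed on the z-scored population-rate signal (1 ms bins by
default) with Welch's method — 1 s Hann segments at 50% overlap — over an
analysis band of 2-80 Hz, giving ~1 Hz resolution on runs of a few
seconds.  A spectrum whose peak does not rise clearly above the in-band
median power is flagged as showing no oscillation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import signal as _signal

from .dynamics import SpikeRaster

__all__ = [
    "RateTrace",
    "SpectrumResult",
    "DelayMeasurement",
    "SelectivityMatrix",
    "DecodeResult",
    "population_rate",
    "power_spectrum",
    "activation_delay",
    "selectivity_matrix",
    "decode_engram",
]


@dataclass
class RateTrace:
    """Binned population firing rate (Hz)."""

    population: str
    bin_width: float  # ms
    rates: np.ndarray  # Hz, one per bin

    @property
    def times(self) -> np.ndarray:
        """Bin-start times, ms."""
        return np.arange(len(self.rates)) * self.bin_width

    def window(self, t0: float, t1: float) -> np.ndarray:
        """Rates of bins whose start lies in [t0, t1)."""
        t = self.times
        return self.rates[(t >= t0) & (t < t1)]


@dataclass
class SpectrumResult:
    """Welch spectrum of a rate trace with its dominant in-band peak."""

    frequencies: np.ndarray  # Hz, strictly increasing
    power: np.ndarray
    peak_frequency: float
    peak_power: float
    no_peak: bool = False


@dataclass
class DelayMeasurement:
    """Latency from drive onset to sustained firing of a population."""

    population: str
    onset: float
    response_time: Optional[float]  # ms, None when the criterion is never met
    threshold: float  # Hz used for the criterion

    @property
    def responded(self) -> bool:
        return self.response_time is not None

    @property
    def delay(self) -> Optional[float]:
        if self.response_time is None:
            return None
        return self.response_time - self.onset


@dataclass
class SelectivityMatrix:
    """Drive-condition x engram-part activation table.

    Entries are evoked rates (mean in-window rate minus baseline, floored
    at zero), row-normalized to sum to one; rows with no evoked activity
    anywhere are flagged silent.  ``winners`` holds the argmax column per
    row (ties flagged).
    """

    conditions: list
    parts: list[str]
    matrix: np.ndarray  # normalized, rows x parts
    raw: np.ndarray  # evoked rates before normalization, Hz
    winners: list[Optional[int]]
    silent_rows: list[bool]
    tied_rows: list[bool] = field(default_factory=list)

    def winner_margin(self, row: int) -> float:
        """Winner minus runner-up normalized activation of one row."""
        vals = np.sort(self.matrix[row])[::-1]
        if len(vals) < 2:
            return float(vals[0]) if len(vals) else 0.0
        return float(vals[0] - vals[1])


@dataclass
class DecodeResult:
    """Outcome of nearest-reference engram decoding."""

    engram_id: Optional[object]
    distance: Optional[float]
    no_oscillation: bool = False


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def population_rate(
    raster: SpikeRaster, population: str, bin_width: float = 1.0
) -> RateTrace:
    """Binned population rate: count / (bin_width * size), in Hz."""
    if population not in raster.populations:
        raise KeyError(f"population {population!r} not in raster")
    size = raster.populations[population]
    n_bins = int(round(raster.duration / bin_width))
    _, times = raster.spikes(population)
    counts, _ = np.histogram(
        times, bins=n_bins, range=(0.0, n_bins * bin_width)
    )
    rates = counts / (bin_width / 1000.0) / size
    return RateTrace(population=population, bin_width=bin_width, rates=rates)


def power_spectrum(
    trace: RateTrace,
    band: tuple[float, float] = (2.0, 80.0),
    segment_ms: float = 1000.0,
    snr_floor: float = 5.0,
) -> SpectrumResult:
    """Welch PSD of the z-scored rate trace over an analysis band.

    DC is excluded by the z-scoring and the band's lower edge.  The peak is
    the in-band maximum; when the trace is flat or the peak fails to exceed
    ``snr_floor`` times the in-band median power, the result is flagged
    ``no_peak`` (no detectable oscillation).
    """
    fs = 1000.0 / trace.bin_width  # Hz
    nyquist = fs / 2.0
    if not 0 <= band[0] < band[1]:
        raise ValueError("band must satisfy 0 <= low < high")
    if band[1] > nyquist:
        raise ValueError(
            f"band upper edge {band[1]} Hz exceeds the Nyquist frequency "
            f"{nyquist} Hz of a {trace.bin_width} ms binning"
        )
    x = np.asarray(trace.rates, dtype=np.float64)
    sd = x.std()
    if sd == 0.0 or len(x) < 4:
        freqs = np.array([band[0], band[1]])
        return SpectrumResult(freqs, np.zeros(2), np.nan, 0.0, no_peak=True)
    z = (x - x.mean()) / sd
    nperseg = min(len(z), int(round(segment_ms / trace.bin_width)))
    freqs, pxx = _signal.welch(
        z, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2
    )
    sel = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    freqs, pxx = freqs[sel], pxx[sel]
    if len(freqs) == 0:
        return SpectrumResult(freqs, pxx, np.nan, 0.0, no_peak=True)
    ipk = int(np.argmax(pxx))
    peak_f, peak_p = float(freqs[ipk]), float(pxx[ipk])
    floor = float(np.median(pxx))
    no_peak = floor <= 0.0 or peak_p < snr_floor * floor
    return SpectrumResult(freqs, pxx, peak_f, peak_p, no_peak=no_peak)


def activation_delay(
    raster: SpikeRaster,
    population: str,
    onset: float,
    threshold_factor: float = 3.0,
    n_consecutive: int = 3,
    bin_width: float = 10.0,
    rate_floor: float = 10.0,
) -> DelayMeasurement:
    """Latency from ``onset`` to the first sustained-rate response.

    The response time is the start of the first run of ``n_consecutive``
    bins (width ``bin_width`` ms) at or above ``threshold_factor`` times the
    pre-onset baseline rate, but never below ``rate_floor`` Hz (so silent
    baselines do not make single stray spikes count as ignition).  Raising
    either criterion can only postpone the measured response.
    """
    if onset <= 0 or onset >= raster.duration:
        raise ValueError(
            "onset must leave a pre-onset baseline window within the run"
        )
    trace = population_rate(raster, population, bin_width)
    t = trace.times
    baseline = trace.rates[t < onset]
    base_rate = float(baseline.mean()) if len(baseline) else 0.0
    threshold = max(threshold_factor * base_rate, rate_floor)
    post = trace.rates[t >= onset]
    post_t = t[t >= onset]
    hit = post >= threshold
    run = 0
    for i, h in enumerate(hit):
        run = run + 1 if h else 0
        if run >= n_consecutive:
            start = post_t[i - n_consecutive + 1]
            return DelayMeasurement(population, onset, float(start), threshold)
    return DelayMeasurement(population, onset, None, threshold)


def selectivity_matrix(
    rasters: Mapping[object, SpikeRaster],
    parts: Sequence[str],
    window: tuple[float, float],
    baseline_window: tuple[float, float] | None = None,
    bin_width: float = 10.0,
) -> SelectivityMatrix:
    """Condition-by-part table of normalized evoked activation.

    For every (condition, part): mean rate inside ``window`` minus the mean
    rate inside ``baseline_window`` (default: everything before the window),
    floored at zero.  Rows are normalized to sum to one; the per-row winner
    is the argmax (ties and all-silent rows flagged).
    """
    if not rasters or not parts:
        raise ValueError("need at least one condition and one part")
    t0, t1 = window
    if baseline_window is None:
        baseline_window = (0.0, t0)
    conditions = list(rasters)
    raw = np.zeros((len(conditions), len(parts)))
    for r, cond in enumerate(conditions):
        raster = rasters[cond]
        if t1 > raster.duration + 1e-9:
            raise ValueError(
                f"window {window} exceeds raster duration {raster.duration}"
            )
        for c, part in enumerate(parts):
            trace = population_rate(raster, part, bin_width)
            evoked = trace.window(t0, t1).mean() if t1 > t0 else 0.0
            base = trace.window(*baseline_window)
            base_rate = base.mean() if len(base) else 0.0
            raw[r, c] = max(0.0, float(evoked - base_rate))
    matrix = np.zeros_like(raw)
    winners: list[Optional[int]] = []
    silent: list[bool] = []
    tied: list[bool] = []
    for r in range(len(conditions)):
        total = raw[r].sum()
        if total <= 0:
            winners.append(None)
            silent.append(True)
            tied.append(False)
            continue
        matrix[r] = raw[r] / total
        top = raw[r].max()
        is_tied = int((raw[r] == top).sum()) > 1
        winners.append(None if is_tied else int(np.argmax(raw[r])))
        silent.append(False)
        tied.append(is_tied)
    return SelectivityMatrix(
        conditions=conditions,
        parts=list(parts),
        matrix=matrix,
        raw=raw,
        winners=winners,
        silent_rows=silent,
        tied_rows=tied,
    )


def decode_engram(
    spectrum: SpectrumResult,
    calibration: Mapping[object, tuple[float, float]],
    scale: Optional[tuple[float, float]] = None,
) -> DecodeResult:
    """Nearest-reference decoding of engram identity from a spectrum.

    ``calibration`` maps engram ids to reference (peak_frequency,
    peak_power) pairs.  Distances are Euclidean in a standardized feature
    space: each feature is centred on the calibration entries' mean and
    divided by ``scale`` when given (typically the within-engram dispersion
    estimated from calibration runs, which whitens the features), otherwise
    by the between-reference standard deviation.  A no-peak spectrum is
    refused: decoding an oscillation requires one.
    """
    if not calibration:
        raise ValueError("calibration must be non-empty")
    if spectrum.no_peak or not np.isfinite(spectrum.peak_frequency):
        return DecodeResult(None, None, no_oscillation=True)
    ids = list(calibration)
    refs = np.array([calibration[i] for i in ids], dtype=np.float64)
    mu = refs.mean(axis=0)
    sd = np.asarray(scale, dtype=np.float64) if scale is not None else refs.std(axis=0)
    sd = np.where(sd <= 0, 1.0, sd)
    query = (np.array([spectrum.peak_frequency, spectrum.peak_power]) - mu) / sd
    zrefs = (refs - mu) / sd
    dists = np.linalg.norm(zrefs - query, axis=1)
    best = int(np.argmin(dists))
    return DecodeResult(ids[best], float(dists[best]))
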