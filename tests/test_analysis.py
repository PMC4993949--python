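"""Rates, spectra, delays, selectivity and decoding."""

import numpy as np
import pytest

from engramnet.analysis import (
    RateTrace,
    SpectrumResult,
    activation_delay,
    decode_engram,
    population_rate,
    power_spectrum,
    selectivity_matrix,
)
from engramnet.dynamics import SpikeRaster, poisson_background


def make_raster(duration, pops, events):
    """events: {pop: [(neuron, t), ...]}"""
    raster = SpikeRaster(duration=duration, populations=dict(pops))
    for pop, evs in events.items():
        evs = sorted(evs, key=lambda e: e[1])
        raster.neuron_ids[pop] = np.array([e[0] for e in evs], dtype=np.int32)
        raster.times[pop] = np.array([e[1] for e in evs], dtype=np.float64)
    return raster


class TestPopulationRate:
    def test_empty_raster_all_zero(self):
        raster = make_raster(100.0, {"p": 10}, {})
        trace = population_rate(raster, "p", 10.0)
        assert np.all(trace.rates == 0.0)
        assert len(trace.rates) == 10

    def test_definition_arithmetic(self):
        # 100 neurons each spiking once inside one 10 ms bin -> 100 Hz
        events = {"p": [(n, 42.0 + 0.05 * n) for n in range(100)]}
        raster = make_raster(100.0, {"p": 100}, events)
        trace = population_rate(raster, "p", 10.0)
        assert trace.rates[4] == pytest.approx(100.0)
        assert trace.rates.sum() == pytest.approx(100.0)

    def test_unknown_population_rejected(self):
        raster = make_raster(10.0, {"p": 1}, {})
        with pytest.raises(KeyError):
            population_rate(raster, "q")

    def test_poisson_rate_recovered(self):
        rate, size, duration = 40.0, 50, 5000.0
        events = poisson_background(rate, size, duration, seed=11)
        raster = make_raster(
            duration, {"p": size}, {"p": [(n, t) for n, t in events]}
        )
        trace = population_rate(raster, "p", 10.0)
        se = np.sqrt(rate * 1000.0 / (size * duration))  # SE of the mean rate
        assert abs(trace.rates.mean() - rate) <= 3 * se * np.sqrt(len(trace.rates))

    @pytest.mark.parametrize("bin_width", [1.0, 7.0, 25.0])
    def test_rate_conservation(self, bin_width, rng):
        times = np.sort(rng.uniform(0, 1000.0, size=333))
        ids = rng.integers(0, 20, size=333)
        raster = make_raster(1000.0, {"p": 20}, {"p": list(zip(ids, times))})
        trace = population_rate(raster, "p", bin_width)
        total = np.sum(trace.rates * bin_width / 1000.0 * 20)
        assert total == pytest.approx(333, abs=1e-9)


class TestPowerSpectrum:
    def _sin_trace(self, freqs_amps, duration_s=4.0, bin_ms=1.0, noise=0.0, seed=0):
        t = np.arange(0, duration_s, bin_ms / 1000.0)
        x = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
        if noise:
            x = x + np.random.default_rng(seed).normal(0, noise, len(t))
        return RateTrace("p", bin_ms, x + 50.0)

    def test_pure_tone_peak(self):
        spec = power_spectrum(self._sin_trace([(40.0, 5.0)]))
        assert not spec.no_peak
        assert spec.peak_frequency == pytest.approx(40.0, abs=1.0)

    def test_constant_trace_flagged_no_peak(self):
        spec = power_spectrum(RateTrace("p", 1.0, np.full(4000, 17.0)))
        assert spec.no_peak
        assert spec.peak_power == 0.0

    def test_two_tone_picks_larger(self):
        spec = power_spectrum(self._sin_trace([(10.0, 5.0), (40.0, 2.0)]))
        assert spec.peak_frequency == pytest.approx(10.0, abs=1.0)

    @pytest.mark.parametrize("f", [8.0, 23.0, 57.0])
    def test_peak_within_resolution_at_snr_10(self, f):
        # amplitude 5, noise sd 1.58 -> variance ratio 10
        spec = power_spectrum(
            self._sin_trace([(f, 5.0)], noise=np.sqrt(25.0 / 2 / 10), seed=3)
        )
        assert not spec.no_peak
        assert abs(spec.peak_frequency - f) <= 1.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            power_spectrum(self._sin_trace([(10.0, 1.0)]), band=(2.0, 600.0))

    def test_frequencies_strictly_increasing_and_peak_attains_max(self):
        spec = power_spectrum(self._sin_trace([(20.0, 5.0)]))
        assert np.all(np.diff(spec.frequencies) > 0)
        assert spec.peak_power == spec.power.max()


class TestActivationDelay:
    def _burst_raster(self, start, duration=2000.0, size=20, rate=60.0):
        events = []
        gap = 1000.0 / rate
        t = start
        n = 0
        while t < duration:
            events.append((n % size, t))
            n += 1
            t += gap / size
        return make_raster(duration, {"p": size}, {"p": events})

    def test_burst_at_onset_gives_zero_delay(self):
        raster = self._burst_raster(start=1000.0)
        dm = activation_delay(raster, "p", onset=1000.0)
        assert dm.responded and dm.delay == 0.0

    def test_silent_population_no_response(self):
        raster = make_raster(2000.0, {"p": 10}, {})
        dm = activation_delay(raster, "p", onset=1000.0)
        assert not dm.responded and dm.delay is None

    def test_delayed_burst_measured(self):
        raster = self._burst_raster(start=1300.0)
        dm = activation_delay(raster, "p", onset=1000.0)
        assert dm.responded
        assert dm.delay == pytest.approx(300.0, abs=10.0)

    def test_raising_threshold_never_decreases_delay(self, rng):
        times = np.sort(rng.uniform(1000.0, 2000.0, 400))
        ids = rng.integers(0, 10, 400)
        raster = make_raster(2000.0, {"p": 10}, {"p": list(zip(ids, times))})
        delays = []
        for k in (1.0, 2.0, 3.0, 5.0):
            dm = activation_delay(raster, "p", onset=1000.0, threshold_factor=k)
            delays.append(np.inf if dm.delay is None else dm.delay)
        assert all(a <= b for a, b in zip(delays, delays[1:]))

    def test_onset_without_baseline_rejected(self):
        raster = make_raster(100.0, {"p": 1}, {})
        with pytest.raises(ValueError, match="baseline"):
            activation_delay(raster, "p", onset=0.0)


class TestSelectivityMatrix:
    def _raster_with_rates(self, rates, duration=2000.0, window=(1000.0, 2000.0)):
        """One raster with given per-part in-window rates (Hz), 10 neurons."""
        pops = {f"part{i}": 10 for i in range(len(rates))}
        events = {}
        for i, r in enumerate(rates):
            n_spk = int(r * 10 * (window[1] - window[0]) / 1000.0)
            ts = np.linspace(window[0], window[1] - 0.01, max(n_spk, 0))
            events[f"part{i}"] = [(j % 10, t) for j, t in enumerate(ts)]
        return make_raster(duration, pops, events)

    def test_rows_normalize_and_winner_is_argmax(self):
        raster = self._raster_with_rates([5.0, 20.0, 2.0])
        sel = selectivity_matrix(
            {"c": raster}, ["part0", "part1", "part2"], (1000.0, 2000.0)
        )
        assert sel.matrix[0].sum() == pytest.approx(1.0)
        assert sel.winners == [1]
        assert not sel.silent_rows[0]
        assert sel.winner_margin(0) > 0

    def test_all_silent_row_flagged(self):
        raster = self._raster_with_rates([0.0, 0.0])
        sel = selectivity_matrix({"c": raster}, ["part0", "part1"], (1000.0, 2000.0))
        assert sel.silent_rows == [True]
        assert sel.winners == [None]
        assert np.all(sel.matrix == 0.0)

    def test_window_exceeding_duration_rejected(self):
        raster = self._raster_with_rates([1.0])
        with pytest.raises(ValueError, match="window"):
            selectivity_matrix({"c": raster}, ["part0"], (1000.0, 5000.0))

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            selectivity_matrix({}, ["p"], (0.0, 1.0))


class TestDecodeEngram:
    CAL = {1: (19.0, 0.3), 2: (25.0, 0.4), 3: (32.0, 0.45)}

    def _spec(self, f, p, no_peak=False):
        return SpectrumResult(np.array([f]), np.array([p]), f, p, no_peak=no_peak)

    def test_exact_reference_decodes_with_zero_distance(self):
        res = decode_engram(self._spec(25.0, 0.4), self.CAL)
        assert res.engram_id == 2
        assert res.distance == pytest.approx(0.0)

    def test_single_entry_calibration_always_that_id(self):
        res = decode_engram(self._spec(99.0, 9.0), {7: (20.0, 0.3)})
        assert res.engram_id == 7
        assert res.distance is not None

    def test_no_peak_refused(self):
        res = decode_engram(self._spec(np.nan, 0.0, no_peak=True), self.CAL)
        assert res.no_oscillation and res.engram_id is None

    def test_empty_calibration_rejected(self):
        with pytest.raises(ValueError):
            decode_engram(self._spec(20.0, 0.3), {})

    def test_scale_reweights_features(self):
        # query halfway in frequency but matching engram 1's power exactly:
        # with frequency made cheap and power expensive, power decides
        query = self._spec(22.0, 0.3)
        by_freq = decode_engram(query, self.CAL, scale=(0.1, 100.0))
        by_power = decode_engram(query, self.CAL, scale=(100.0, 0.01))
        assert by_power.engram_id == 1
        assert by_freq.engram_id in (1, 2)
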