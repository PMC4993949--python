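"""LIF integrator: closed-form oracles, refractoriness, determinism, noise."""

import numpy as np
import pytest

import engramnet._kernel as kernel
from engramnet.circuits import NetworkSpec
from engramnet.dynamics import (
    ConnectionSpec,
    PopulationSpec,
    SimulationAbort,
    SimulationConfig,
    SpikeRaster,
    lif_first_passage_time,
    poisson_background,
    read_raster,
    run_simulation,
    step_lif,
    write_raster,
)
from engramnet.stimuli import make_constant_drive

from conftest import two_pop_net


class TestStepLif:
    def test_rest_is_fixed_point(self, single_neuron, short_config):
        state = {"v": np.full(1, single_neuron.v_rest), "ref": np.zeros(1, int)}
        new, spikes = step_lif(state, np.zeros(1), single_neuron, short_config)
        assert new["v"][0] == single_neuron.v_rest
        assert len(spikes) == 0

    def test_init_above_threshold_spikes_immediately(self, single_neuron, short_config):
        state = {"v": np.full(1, -50.0), "ref": np.zeros(1, int)}
        new, spikes = step_lif(state, np.zeros(1), single_neuron, short_config)
        assert list(spikes) == [0]
        assert new["v"][0] == single_neuron.v_reset
        assert new["ref"][0] == round(single_neuron.t_ref / short_config.dt)

    def test_refractory_ignores_input(self, single_neuron, short_config):
        state = {"v": np.full(1, single_neuron.v_reset), "ref": np.full(1, 5)}
        new, spikes = step_lif(state, np.full(1, 100.0), single_neuron, short_config)
        assert len(spikes) == 0
        assert new["v"][0] == single_neuron.v_reset
        assert new["ref"][0] == 4

    def test_dimension_mismatch_rejected(self, single_neuron, short_config):
        state = {"v": np.zeros(2), "ref": np.zeros(2, int)}
        with pytest.raises(ValueError):
            step_lif(state, np.zeros(2), single_neuron, short_config)


class TestFirstPassageOracle:
    """Simulated spike times against the closed-form time-to-threshold."""

    @pytest.mark.parametrize("tau_m", [5.0, 10.0, 20.0])
    @pytest.mark.parametrize("drive", [2.0, 3.5, 8.0])
    def test_first_spike_matches_closed_form(self, tau_m, drive):
        pop = PopulationSpec(name="n", size=1, cell_type="excitatory",
                             tau_m=tau_m, t_ref=2.0)
        net = NetworkSpec(populations=[pop], connections=[], labels={})
        config = SimulationConfig(dt=0.1, duration=300.0, seed=0)
        drv = make_constant_drive(amplitude=drive, onset=0.0, target="n")
        raster = run_simulation(net, [drv], config)
        _, times = raster.spikes("n")
        t_star = lif_first_passage_time(drive, pop)
        if np.isinf(t_star):  # drive below rheobase for this tau_m
            assert len(times) == 0
        else:
            assert len(times) > 0
            assert abs(times[0] - t_star) <= config.dt + 1e-9

    def test_subthreshold_never_spikes(self):
        pop = PopulationSpec(name="n", size=1, cell_type="excitatory")
        net = NetworkSpec(populations=[pop], connections=[], labels={})
        drv = make_constant_drive(amplitude=1.0, target="n")  # 10 mV < 16 mV gap
        raster = run_simulation(net, [drv], SimulationConfig(duration=2000.0, seed=0))
        assert raster.n_spikes() == 0
        assert lif_first_passage_time(1.0, pop) == np.inf

    @pytest.mark.parametrize("drive", [2.5, 6.0])
    def test_isi_equals_passage_time_plus_refractory(self, drive):
        pop = PopulationSpec(name="n", size=1, cell_type="excitatory",
                             tau_m=10.0, t_ref=2.0)
        net = NetworkSpec(populations=[pop], connections=[], labels={})
        config = SimulationConfig(dt=0.1, duration=1000.0, seed=0)
        drv = make_constant_drive(amplitude=drive, target="n")
        raster = run_simulation(net, [drv], config)
        _, times = raster.spikes("n")
        isis = np.diff(times)
        expected = lif_first_passage_time(drive, pop) + pop.t_ref
        assert len(isis) >= 3
        # one extra dt: the refractory release and the threshold crossing
        # are each quantized to the grid
        assert np.all(np.abs(isis - expected) <= 2 * config.dt + 1e-9)


class TestRunSimulation:
    def test_no_input_empty_raster(self, single_neuron_net):
        raster = run_simulation(
            single_neuron_net, [], SimulationConfig(duration=500.0, seed=1)
        )
        assert raster.n_spikes() == 0

    def test_unknown_drive_target_rejected_before_stepping(self, single_neuron_net):
        drv = make_constant_drive(amplitude=1.0, target="ghost")
        with pytest.raises(ValueError, match="ghost"):
            run_simulation(single_neuron_net, [drv], SimulationConfig(seed=0))

    def test_determinism_same_seed(self):
        pop = PopulationSpec(name="p", size=30, cell_type="excitatory",
                             background_rate=8000.0, background_weight=0.3)
        net = NetworkSpec(populations=[pop], connections=[], labels={})
        config = SimulationConfig(duration=500.0, seed=42)
        r1 = run_simulation(net, [], config)
        r2 = run_simulation(net, [], config)
        assert r1 == r2
        r3 = run_simulation(net, [], SimulationConfig(duration=500.0, seed=43))
        assert r1 != r3

    def test_refractory_enforced_under_strong_noise(self):
        pop = PopulationSpec(name="p", size=20, cell_type="excitatory",
                             t_ref=2.0, background_rate=20000.0,
                             background_weight=0.5)
        net = NetworkSpec(populations=[pop], connections=[], labels={})
        raster = run_simulation(net, [], SimulationConfig(duration=1000.0, seed=7))
        ids, times = raster.spikes("p")
        assert len(times) > 100
        for n in np.unique(ids):
            isis = np.diff(times[ids == n])
            assert np.all(isis >= pop.t_ref - 1e-9)

    def test_subthreshold_psp_linearity(self):
        """With the threshold effectively disabled, doubling one input
        spike's weight doubles the peak PSP deviation from rest."""
        peaks = []
        for w in (0.5, 1.0):
            net = two_pop_net(weight=w, thresh_b=1e6)
            drv = make_constant_drive(amplitude=8.0, onset=0.0, offset=3.0,
                                      target="A")
            config = SimulationConfig(duration=100.0, seed=0,
                                      record_voltages=True)
            raster, volts = run_simulation(net, [drv], config)
            assert raster.n_spikes("A") == 1  # exactly one presynaptic spike
            peaks.append(np.max(volts[:, 1] - net.population("B").v_rest))
        assert peaks[1] == pytest.approx(2 * peaks[0], rel=1e-9)

    def test_synaptic_delay_respected(self):
        net = two_pop_net(weight=30.0)  # suprathreshold single EPSP
        drv = make_constant_drive(amplitude=8.0, onset=0.0, offset=3.0, target="A")
        raster = run_simulation(net, [drv], SimulationConfig(duration=60.0, seed=0))
        _, ta = raster.spikes("A")
        _, tb = raster.spikes("B")
        assert len(ta) == 1 and len(tb) >= 1
        assert tb[0] >= ta[0] + 1.0  # the 1 ms axonal delay

    def test_nonfinite_potential_aborts(self):
        pop = PopulationSpec(name="p", size=1, cell_type="excitatory",
                             v_thresh=float("inf"), v_reset=-70.0)
        net = NetworkSpec(populations=[pop], connections=[], labels={})
        drv = make_constant_drive(amplitude=1e308, target="p")
        with pytest.raises(SimulationAbort):
            run_simulation(net, [drv], SimulationConfig(duration=50.0, seed=0))


class TestKernelEquivalence:
    def test_numpy_and_numba_paths_agree(self, monkeypatch):
        if not kernel._HAVE_NUMBA:
            pytest.skip("numba not installed; only one kernel available")
        pop_e = PopulationSpec(name="E", size=40, cell_type="excitatory",
                               background_rate=4000.0, background_weight=0.3)
        pop_i = PopulationSpec(name="I", size=10, cell_type="inhibitory",
                               tau_m=8.0, t_ref=1.0, background_rate=2000.0,
                               background_weight=0.2)
        conns = [
            ConnectionSpec("E", "I", 0.5, 0.5, 1.0, 4.0),
            ConnectionSpec("I", "E", 1.5, 0.5, 1.0, 8.0),
            ConnectionSpec("E", "E", 0.2, 0.5, 1.5, 4.0),
            ConnectionSpec("I", "I", 0.4, 0.5, 1.0, 8.0),
        ]
        net = NetworkSpec(populations=[pop_e, pop_i], connections=conns, labels={})
        config = SimulationConfig(duration=400.0, seed=3)
        fast = run_simulation(net, [], config)
        monkeypatch.setattr(kernel, "_HAVE_NUMBA", False)
        slow = run_simulation(net, [], config)
        assert fast.n_spikes() > 0
        assert fast == slow


class TestPoissonBackground:
    def test_counts_within_three_sigma_of_oracle(self, rng):
        """Check against an independent cumulative-exponential sampler."""
        rate, size, duration = 10.0, 100, 10_000.0
        events = poisson_background(rate, size, duration, seed=5)
        expected = rate * size * duration / 1000.0
        sigma = np.sqrt(expected)
        assert abs(len(events) - expected) <= 3 * sigma

        # independent oracle: per-neuron inverse-CDF gap sampling
        oracle_total = 0
        for _ in range(size):
            t = 0.0
            while True:
                t += -1000.0 / rate * np.log(rng.random())
                if t >= duration:
                    break
                oracle_total += 1
        assert abs(len(events) - oracle_total) <= 6 * sigma

    def test_zero_rate_no_events(self):
        assert poisson_background(0.0, 50, 1000.0, seed=0) == []

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            poisson_background(-1.0, 10, 100.0, seed=0)

    def test_fixed_seed_reproducible(self):
        a = poisson_background(20.0, 5, 500.0, seed=9)
        b = poisson_background(20.0, 5, 500.0, seed=9)
        assert a == b
        assert all(0 <= t <= 500.0 for _, t in a)
        assert [t for _, t in a] == sorted(t for _, t in a)


class TestRasterIO:
    def test_round_trip(self, tmp_path):
        raster = SpikeRaster(duration=100.0, populations={"a": 3, "b": 2})
        raster.neuron_ids["a"] = np.array([0, 2, 1], dtype=np.int32)
        raster.times["a"] = np.array([1.5, 20.0, 99.0])
        raster.neuron_ids["b"] = np.array([1], dtype=np.int32)
        raster.times["b"] = np.array([50.25])
        path = tmp_path / "raster.tsv"
        write_raster(raster, path, header={"seed": 7})
        back = read_raster(path)
        assert back == raster
        assert "seed=7" in path.read_text()

    def test_validate_catches_out_of_range_index(self):
        raster = SpikeRaster(duration=10.0, populations={"a": 2})
        raster.neuron_ids["a"] = np.array([5], dtype=np.int32)
        raster.times["a"] = np.array([1.0])
        with pytest.raises(ValueError, match="index"):
            raster.validate()
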