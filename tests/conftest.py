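import numpy as np
import pytest

from engramnet.circuits import NetworkSpec
from engramnet.dynamics import ConnectionSpec, PopulationSpec, SimulationConfig


@pytest.fixture
def single_neuron():
    """One excitatory LIF neuron, no background noise."""
    return PopulationSpec(
        name="cell",
        size=1,
        cell_type="excitatory",
        tau_m=10.0,
        v_rest=-70.0,
        v_thresh=-54.0,
        v_reset=-70.0,
        t_ref=2.0,
    )


@pytest.fixture
def single_neuron_net(single_neuron):
    """A one-population network carrying the single neuron."""
    return NetworkSpec(populations=[single_neuron], connections=[], labels={})


@pytest.fixture
def short_config():
    return SimulationConfig(dt=0.1, duration=200.0, seed=0)


def two_pop_net(weight: float, tau_syn: float = 4.0, thresh_b: float = -54.0):
    """Driver population A (1 neuron) synapsing onto B (1 neuron)."""
    a = PopulationSpec(name="A", size=1, cell_type="excitatory", tau_m=10.0,
                       t_ref=2.0)
    b = PopulationSpec(name="B", size=1, cell_type="excitatory", tau_m=10.0,
                       v_thresh=thresh_b, t_ref=2.0)
    conn = ConnectionSpec("A", "B", weight, probability=1.0, delay=1.0,
                          tau_syn=tau_syn)
    return NetworkSpec(populations=[a, b], connections=[conn], labels={})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
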