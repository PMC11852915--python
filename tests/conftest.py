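import numpy as np
import pytest

from comsnn.dynamics import (
    Network,
    PlasticityParams,
    SimConfig,
    build_network,
    simulate,
)
from comsnn.topology import TopologyConfig, generate


@pytest.fixture(scope="session")
def tiny_graph():
    """20-node weighted growth graph used across unit tests."""
    return generate(TopologyConfig("bbv", 20, m0=4, me=3, seed=11))


@pytest.fixture(scope="session")
def tiny_config():
    return SimConfig(duration=100.0, seed=5)


@pytest.fixture(scope="session")
def tiny_network(tiny_graph, tiny_config):
    return build_network(tiny_graph, tiny_config, PlasticityParams(), seed=2)


@pytest.fixture(scope="session")
def tiny_run(tiny_network, tiny_config):
    return simulate(tiny_network, tiny_config)


def make_isolated_network(n: int, inhibitory=()) -> Network:
    """A network of n unconnected neurons for controlled-drive tests."""
    is_inh = np.zeros(n, dtype=bool)
    is_inh[list(inhibitory)] = True
    a = np.where(is_inh, 0.02, 0.02)
    b = np.where(is_inh, 0.25, 0.20)
    c = np.full(n, -65.0)
    d = np.where(is_inh, 2.0, 8.0)
    empty_i = np.empty(0, dtype=int)
    empty_f = np.empty(0)
    return Network(
        n=n, is_inhibitory=is_inh, a=a, b=b, c=c, d=d,
        pre=empty_i, post=empty_i, delay_ms=empty_f,
        is_es=np.empty(0, dtype=bool), g_init=empty_f,
        plasticity=PlasticityParams(),
    )


def make_two_neuron_network(
    delay_ms: float, plasticity: PlasticityParams | None = None, es: bool = True
) -> Network:
    """Two neurons joined by a single directed synapse 0 -> 1."""
    if plasticity is None:
        plasticity = PlasticityParams()
    is_inh = np.array([not es, False])
    return Network(
        n=2,
        is_inhibitory=is_inh,
        a=np.full(2, 0.02),
        b=np.where(is_inh, 0.25, 0.20),
        c=np.full(2, -65.0),
        d=np.where(is_inh, 2.0, 8.0),
        pre=np.array([0]),
        post=np.array([1]),
        delay_ms=np.array([delay_ms]),
        is_es=np.array([es]),
        g_init=np.array([plasticity.g_max]),
        plasticity=plasticity,
    )
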