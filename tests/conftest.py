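import numpy as np
import pytest

from critmem.network import (
    PatternSet,
    Topology,
    build_small_world,
    embed_native,
    make_patterns,
    wire_input,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_net(rng):
    """N=200, k=10 network with one native memory and a wired input."""
    topo = build_small_world(200, 10, 0.1, rng)
    patterns = make_patterns(200, 1, 20, rng)
    net = embed_native(topo, patterns)
    return wire_input(net, patterns, 3.0), patterns


@pytest.fixture
def triangle():
    """Hand-checkable 3-node full digraph with two fixed patterns.

    xi_1 = (+,+,-), xi_2 = (+,-,-): the outer-product couplings are
    J_12 = J_21 = 0, J_13 = J_31 = -1, J_23 = J_32 = 0 ... computed by hand.
    """
    sources = np.array([[1, 2], [0, 2], [0, 1]])
    topo = Topology(n_neurons=3, in_degree=2, rewire_prob=0.0, sources=sources)
    native = np.array([[1, 1, -1], [1, -1, -1]], dtype=np.int8)
    patterns = PatternSet(
        native=native,
        new=np.array([1, 1, 1], dtype=np.int8),
        input_set=np.array([], dtype=np.intp),
    )
    return topo, patterns
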