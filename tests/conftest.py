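import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from netmarker.network import Network


def build_network(edges, nodes=()):
    net = Network()
    for v in nodes:
        net.add_node(v)
    for a, b in edges:
        net.add_edge(a, b, source="test")
    return net


@pytest.fixture
def k4():
    return build_network([(a, b) for i, a in enumerate("ABCD") for b in "ABCD"[i + 1:]])


@pytest.fixture
def path5():
    return build_network([("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")])


@pytest.fixture
def k4_with_pendant_path():
    # K4 on a,b,c,d plus pendant path d-e-f
    net = build_network([(x, y) for i, x in enumerate("abcd") for y in "abcd"[i + 1:]])
    net.add_edge("d", "e", source="test")
    net.add_edge("e", "f", source="test")
    return net


@pytest.fixture
def demo_spots():
    from netmarker.datasets import load_demo_spots

    return load_demo_spots()


@pytest.fixture
def demo_selection():
    from netmarker.datasets import load_demo_centrality

    return load_demo_centrality()
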