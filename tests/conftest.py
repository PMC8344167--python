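from __future__ import annotations

import random
import string

import pytest

from netprior import Network, load_fixture


def random_graph(n: int, p: float, rng: random.Random) -> Network:
    """Erdős–Rényi draw with letter labels, possibly disconnected."""
    labels = list(string.ascii_uppercase[:n]) if n <= 26 else [f"N{i}" for i in range(n)]
    net = Network(nodes=set(labels))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                net.add_edge(labels[i], labels[j])
    return net


def random_connected_graph(n: int, rng: random.Random) -> Network:
    """Random spanning tree plus random extra edges: always connected."""
    labels = list(string.ascii_uppercase[:n])
    net = Network(nodes=set(labels))
    shuffled = labels[:]
    rng.shuffle(shuffled)
    for i in range(1, n):
        net.add_edge(shuffled[i], shuffled[rng.randrange(i)])
    extra = rng.randrange(0, n)
    for _ in range(extra):
        a, b = rng.sample(labels, 2)
        net.add_edge(a, b)
    return net


@pytest.fixture(scope="session")
def paper_tables():
    return load_fixture()


@pytest.fixture
def triangle() -> Network:
    net = Network()
    net.add_edge("A", "B")
    net.add_edge("B", "C")
    net.add_edge("A", "C")
    return net


@pytest.fixture
def star5() -> Network:
    """Star with center X and four leaves."""
    net = Network()
    for leaf in "ABCD":
        net.add_edge("X", leaf)
    return net


@pytest.fixture
def path3() -> Network:
    net = Network()
    net.add_edge("A", "B")
    net.add_edge("B", "C")
    return net
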