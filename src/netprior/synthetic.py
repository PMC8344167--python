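"""Seeded generators for synthetic networks and annotations.

The reference study's 63-node PPI component is not recoverable, so tests and
simulations run on synthetic stand-ins that emulate its salient features: a
single dominant component, a heavy-tailed degree distribution with a handful
of strong hubs, and gene-set annotations in which one term is genuinely
over-represented in a designated query.

Every generator is a pure function of its configuration: the same config and
seed always yield the identical network or annotation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .graph_core import AnnotationSet, Network

TOPOLOGIES = ("preferential-attachment", "erdos-renyi", "planted-hub")


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic network draw.

    Defaults emulate the reference component: 63 nodes grown by preferential
    attachment with m=2 edges per arriving node (122 edges, max degree
    typically around 20-30).
    """

    n_nodes: int = 63
    topology: str = "preferential-attachment"
    m: int = 2                 # attachment edges per new node
    p: float = 0.0624          # ER edge probability (matches m=2 edge count at n=63)
    n_hubs: int = 5            # planted-hub topology only
    hub_coverage: tuple[float, float] = (0.4, 0.6)  # fraction of nodes each hub touches
    seed: int = 0

    def validate(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("need at least 3 nodes")
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.topology == "preferential-attachment" and self.m >= self.n_nodes:
            raise ValueError(f"attachment m={self.m} must be < n_nodes={self.n_nodes}")
        if self.topology == "erdos-renyi" and not (0.0 <= self.p <= 1.0):
            raise ValueError("edge probability outside [0, 1]")
        if self.topology == "planted-hub" and self.n_hubs >= self.n_nodes:
            raise ValueError("more hubs than nodes")


def _labels(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(cfg: SimulationConfig) -> Network:
    """Draw a synthetic network; see :class:`SimulationConfig`.

    ``preferential-attachment``: start from m isolated seed nodes; each new
    node attaches to m distinct existing nodes with probability proportional
    to degree (+1 smoothing so the seed nodes are reachable).  The result is
    connected with exactly m*(n-m) edges.

    ``erdos-renyi``: each pair is an edge independently with probability p.

    ``planted-hub``: n_hubs designated hubs are each wired to a uniformly
    chosen 40-60% of all nodes; no other edges.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    labels = _labels(cfg.n_nodes)
    net = Network(nodes=set(labels))

    if cfg.topology == "preferential-attachment":
        degree = np.zeros(cfg.n_nodes, dtype=float)
        for new in range(cfg.m, cfg.n_nodes):
            weights = degree[:new] + 1.0
            targets = rng.choice(new, size=cfg.m, replace=False, p=weights / weights.sum())
            for t in targets:
                net.add_edge(labels[new], labels[int(t)])
                degree[new] += 1
                degree[int(t)] += 1
    elif cfg.topology == "erdos-renyi":
        for i, j in combinations(range(cfg.n_nodes), 2):
            if rng.random() < cfg.p:
                net.add_edge(labels[i], labels[j])
    else:  # planted-hub
        lo, hi = cfg.hub_coverage
        hubs = rng.choice(cfg.n_nodes, size=cfg.n_hubs, replace=False)
        for h in hubs:
            frac = rng.uniform(lo, hi)
            k = max(1, int(round(frac * (cfg.n_nodes - 1))))
            others = np.array([i for i in range(cfg.n_nodes) if i != h])
            for t in rng.choice(others, size=k, replace=False):
                net.add_edge(labels[int(h)], labels[int(t)])

    net.validate()
    return net


def planted_hubs(cfg: SimulationConfig) -> frozenset[str]:
    """The hub labels a planted-hub draw will use (same RNG stream prefix)."""
    if cfg.topology != "planted-hub":
        raise ValueError("planted hubs are only defined for the planted-hub topology")
    rng = np.random.default_rng(cfg.seed)
    labels = _labels(cfg.n_nodes)
    hubs = rng.choice(cfg.n_nodes, size=cfg.n_hubs, replace=False)
    return frozenset(labels[int(h)] for h in hubs)


def generate_annotation(
    genes,
    n_terms: int = 50,
    size_range: tuple[int, int] = (5, 30),
    planted: tuple[frozenset[str], int, int] | None = None,
    seed: int = 0,
) -> AnnotationSet:
    """Random gene-set annotation over ``genes`` with optional planted signal.

    Decoy terms draw their sizes uniformly from ``size_range`` and their
    members uniformly from the background.  ``planted`` is
    ``(query, overlap, term_size)``: one extra term ``PLANTED`` is forced to
    share exactly ``overlap`` genes with ``query``, padding with non-query
    genes.
    """
    genes = sorted(set(genes))
    rng = np.random.default_rng(seed)
    lo, hi = size_range
    if hi > len(genes):
        raise ValueError("term sizes exceed the background size")
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    width = max(3, len(str(n_terms)))
    for i in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(genes), size=size, replace=False)
        tid = f"T{i:0{width}d}"
        terms[tid] = (f"decoy term {i}", frozenset(genes[int(j)] for j in members))
    if planted is not None:
        query, overlap, term_size = planted
        query = sorted(set(query) & set(genes))
        if overlap > len(query):
            raise ValueError("requested overlap exceeds the query size")
        if overlap > term_size:
            raise ValueError("requested overlap exceeds the planted term size")
        inside = rng.choice(len(query), size=overlap, replace=False)
        members = {query[int(j)] for j in inside}
        pool = [g for g in genes if g not in set(query)]
        pad = term_size - overlap
        if pad > len(pool):
            raise ValueError("background too small to pad the planted term")
        for j in rng.choice(len(pool), size=pad, replace=False):
            members.add(pool[int(j)])
        terms["PLANTED"] = ("planted enriched term", frozenset(members))
    ann = AnnotationSet(terms=terms, background=frozenset(genes))
    ann.validate()
    return ann
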