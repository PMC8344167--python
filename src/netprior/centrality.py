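"""The four centrality indices: degree, betweenness, closeness, stress.

All indices treat the graph as unweighted and undirected (edge confidences
are ignored once thresholding has happened).  Conventions follow Cytoscape's
NetworkAnalyzer, which is what published PPI prioritization studies report:

- *degree* is the raw incident-edge count;
- *betweenness* of v sums sigma_st(v)/sigma_st over unordered pairs
  {s, t} (s != t != v) within v's component and is normalized by
  (n-1)(n-2)/2, so it lies in [0, 1];
- *closeness* of v is (n_c - 1) / sum_u d(v, u), the reciprocal of the mean
  shortest-path distance within v's component (0 for singletons);
- *stress* of v is the raw number of shortest paths through v counted over
  ordered pairs (s, t), hence always even on an undirected graph.

Betweenness and stress share one Brandes dependency-accumulation pass per
source (O(|V||E|) total); closeness reuses the same BFS distances.
"""

from __future__ import annotations

from collections import deque

import pandas as pd

from .graph_core import Network, connected_components

METRICS = ("degree", "betweenness", "closeness", "stress")


def degree_centrality(net: Network) -> dict[str, int]:
    """Incident edge count per node."""
    deg = {v: 0 for v in net.nodes}
    for a, b in net.edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def _brandes_all(net: Network) -> tuple[dict[str, float], dict[str, int], dict[str, float]]:
    """One pass computing betweenness, stress and closeness together.

    Returns (betweenness, stress, closeness).  Betweenness is normalized per
    component; stress is the raw ordered-pair path count; closeness is
    computed within each component.
    """
    adj = net.adjacency()
    comp_of: dict[str, int] = {}
    comp_sizes: list[int] = []
    for i, comp in enumerate(connected_components(net)):
        comp_sizes.append(len(comp))
        for v in comp:
            comp_of[v] = i

    bet = {v: 0.0 for v in net.nodes}
    stress = {v: 0.0 for v in net.nodes}
    close = {v: 0.0 for v in net.nodes}

    for s in sorted(net.nodes):
        # single-source BFS with shortest-path counts (Brandes)
        dist = {s: 0}
        sigma = {s: 1.0}
        preds: dict[str, list[str]] = {s: []}
        order: list[str] = []
        q: deque[str] = deque([s])
        while q:
            v = q.popleft()
            order.append(v)
            for w in adj[v]:
                if w not in dist:
                    dist[w] = dist[v] + 1
                    sigma[w] = 0.0
                    preds[w] = []
                    q.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # closeness from this source's distances (symmetric, so fill row s)
        n_c = comp_sizes[comp_of[s]]
        if n_c > 1:
            total = sum(dist.values())
            close[s] = (n_c - 1) / total
        # dependency accumulation, reverse BFS order
        delta_b = {v: 0.0 for v in order}   # betweenness dependency
        delta_s = {v: 0.0 for v in order}   # stress dependency
        for w in reversed(order):
            for v in preds[w]:
                frac = sigma[v] / sigma[w]
                delta_b[v] += frac * (1.0 + delta_b[w])
                delta_s[v] += sigma[v] + frac * delta_s[w]
            if w != s:
                bet[w] += delta_b[w]
                stress[w] += delta_s[w]

    # betweenness: summed over ordered pairs -> halve, then normalize
    out_b: dict[str, float] = {}
    out_s: dict[str, int] = {}
    for v in net.nodes:
        n_c = comp_sizes[comp_of[v]]
        denom = (n_c - 1) * (n_c - 2) / 2.0
        out_b[v] = (bet[v] / 2.0) / denom if denom > 0 else 0.0
        out_s[v] = int(round(stress[v]))
    return out_b, out_s, close


def betweenness_centrality(net: Network) -> dict[str, float]:
    """Pair-normalized betweenness in [0, 1], per component."""
    return _brandes_all(net)[0]


def stress_centrality(net: Network) -> dict[str, int]:
    """Raw shortest-path counts through each node (ordered pairs)."""
    return _brandes_all(net)[1]


def closeness_centrality(net: Network) -> dict[str, float]:
    """Reciprocal mean shortest-path distance within each component."""
    return _brandes_all(net)[2]


def centrality_table(net: Network) -> pd.DataFrame:
    """All four indices as a DataFrame indexed by gene (lexicographic order).

    Columns: ``degree`` (int), ``betweenness``, ``closeness`` (floats in
    [0, 1]), ``stress`` (even int).
    """
    if not net.nodes:
        raise ValueError("cannot compute centralities on an empty network")
    deg = degree_centrality(net)
    bet, stress, close = _brandes_all(net)
    genes = sorted(net.nodes)
    return pd.DataFrame(
        {
            "degree": [deg[g] for g in genes],
            "betweenness": [bet[g] for g in genes],
            "closeness": [close[g] for g in genes],
            "stress": [stress[g] for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
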