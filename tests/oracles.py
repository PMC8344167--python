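"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (path enumeration, O(n^3) distance
matrices, O(m^2) step procedures, explicit combinatorial sums) and shares no
code with the package.
"""

from __future__ import annotations

import math
from itertools import combinations


def adjacency(nodes, edges):
    adj = {v: set() for v in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def all_simple_paths(adj, s, t, max_len):
    """Every simple s-t path of length <= max_len, by exhaustive DFS."""
    out = []
    stack = [(s, [s])]
    while stack:
        v, path = stack.pop()
        if v == t:
            out.append(path)
            continue
        if len(path) > max_len:
            continue
        for u in adj[v]:
            if u not in path:
                stack.append((u, path + [u]))
    return out


def shortest_paths(adj, s, t):
    """All shortest s-t paths by filtering the exhaustive enumeration."""
    paths = all_simple_paths(adj, s, t, max_len=len(adj))
    if not paths:
        return []
    d = min(len(p) for p in paths)
    return [p for p in paths if len(p) == d]


def brute_betweenness(nodes, edges):
    """Pair-normalized betweenness via explicit shortest-path enumeration.

    Assumes a connected graph (the tests only feed it connected ones).
    """
    adj = adjacency(nodes, edges)
    n = len(nodes)
    bet = {v: 0.0 for v in nodes}
    for s, t in combinations(sorted(nodes), 2):
        paths = shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in nodes:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            bet[v] += through / len(paths)
    denom = (n - 1) * (n - 2) / 2
    return {v: (bet[v] / denom if denom > 0 else 0.0) for v in nodes}


def brute_stress(nodes, edges):
    """Ordered-pair shortest-path counts through each node."""
    adj = adjacency(nodes, edges)
    stress = {v: 0 for v in nodes}
    for s, t in combinations(sorted(nodes), 2):
        for p in shortest_paths(adj, s, t):
            for v in p[1:-1]:
                stress[v] += 2  # (s,t) and (t,s)
    return stress


def brute_closeness(nodes, edges):
    """Reciprocal mean distance via a Floyd-Warshall distance matrix."""
    order = sorted(nodes)
    idx = {v: i for i, v in enumerate(order)}
    n = len(order)
    INF = float("inf")
    d = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    for a, b in edges:
        d[idx[a]][idx[b]] = 1
        d[idx[b]][idx[a]] = 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i][k] + d[k][j] < d[i][j]:
                    d[i][j] = d[i][k] + d[k][j]
    out = {}
    for v in order:
        i = idx[v]
        dists = [d[i][j] for j in range(n) if j != i and d[i][j] < INF]
        out[v] = (len(dists) / sum(dists)) if dists else 0.0
    return out


def union_find_components(nodes, edges):
    parent = {v: v for v in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent[find(a)] = find(b)
    comps = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    return sorted(comps.values(), key=lambda c: (-len(c), min(c)))


def hypergeom_tail(k, n, K, N):
    """P(X >= k) by explicit combinatorial summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
        if n - i <= N - K
    ) / total


def naive_bonferroni(p):
    m = len(p)
    return [min(1.0, x * m) for x in p]


def naive_holm(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(1.0, running)
    return adj


def naive_bh(p):
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m - 1, -1, -1):
        i = order[rank]
        running = min(running, p[i] * m / (rank + 1))
        adj[i] = min(1.0, running)
    return adj


def brute_criteria(H, B, C, S):
    """The five importance criteria evaluated literally."""
    return {
        1: {g for g in H if g in B},
        2: {g for g in H if g in B and g in C and g in S},
        3: {g for g in H if g in C and g in S},
        4: {g for g in B if g in C and g in S},
        5: {g for g in (H | B) if g in C or g in S},
    }


def brute_kappa(set1, set2, background):
    """Cohen's kappa between two membership indicator vectors."""
    n = len(background)
    agree = sum(1 for g in background if (g in set1) == (g in set2))
    po = agree / n
    p1, p2 = len(set1) / n, len(set2) / n
    pe = p1 * p2 + (1 - p1) * (1 - p2)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1 - pe)
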