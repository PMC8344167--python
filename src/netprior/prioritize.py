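"""Gene prioritization: top-fraction rank sets, the five combination
criteria that define *important* genes, and the exclusion rule that yields
the *crucial* panel.

The workflow mirrors the hub/bottleneck prioritization scheme common in PPI
biomarker studies: take the top 20% of nodes by each of degree (hubs, H),
betweenness (bottlenecks, B), closeness (C) and stress (S), then call a gene
*important* if it satisfies at least one of

1. H ∩ B                (hub-bottleneck)
2. H ∩ B ∩ C ∩ S        (hub-bottleneck with high closeness and stress)
3. H ∩ C ∩ S            (hub with high closeness and stress)
4. B ∩ C ∩ S            (bottleneck with high closeness and stress)
5. (H ∪ B) ∩ (C ∪ S)    (hub or bottleneck with high closeness or stress)

Criteria 2-4 are subsets of criterion 5, so the important set equals
(H ∩ B) ∪ ((H ∪ B) ∩ (C ∪ S)); all five are still evaluated and recorded
per gene.  Important genes that are bottleneck-and-stress members but
neither hubs nor high-closeness (B ∩ S minus H ∪ C) are then *excluded* —
on the reference data these are exactly the peripherally connected genes —
and the remainder is the crucial panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .centrality import METRICS
from .graph_core import Network, induce_subgraph

CRITERIA = (1, 2, 3, 4, 5)


@dataclass(frozen=True)
class RankSets:
    """The four top-fraction membership sets on one component."""

    H: frozenset[str]
    B: frozenset[str]
    C: frozenset[str]
    S: frozenset[str]
    q: float = 0.2
    n: int = 0

    @property
    def union(self) -> frozenset[str]:
        return self.H | self.B | self.C | self.S

    def flags(self, gene: str) -> tuple[bool, bool, bool, bool]:
        return (gene in self.H, gene in self.B, gene in self.C, gene in self.S)


@dataclass
class PriorityRecord:
    """Per-gene classification outcome."""

    gene: str
    flags: tuple[bool, bool, bool, bool]  # (h, b, c, s)
    criteria: frozenset[int] = field(default_factory=frozenset)
    status: str = "none"  # none | important | crucial | excluded


def top_fraction(
    table: pd.DataFrame,
    metric: str,
    q: float = 0.2,
    keep_ties: bool = False,
) -> frozenset[str]:
    """The k = max(1, floor(q*n)) genes with the highest ``metric`` values.

    Ties at the cutoff are broken lexicographically by gene name; with
    ``keep_ties`` every gene tied with the k-th value is returned instead.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if not (0.0 < q <= 1.0):
        raise ValueError(f"fraction q={q} outside (0, 1]")
    if table.empty:
        raise ValueError("empty centrality table")
    n = len(table)
    k = max(1, int(q * n))
    ranked = sorted(table.index, key=lambda g: (-table.at[g, metric], g))
    if keep_ties:
        cutoff = table.at[ranked[k - 1], metric]
        return frozenset(g for g in table.index if table.at[g, metric] >= cutoff)
    return frozenset(ranked[:k])


def build_rank_sets(
    table: pd.DataFrame, q: float = 0.2, keep_ties: bool = False
) -> RankSets:
    """Hub/bottleneck/closeness/stress top-fraction sets from a centrality table."""
    return RankSets(
        H=top_fraction(table, "degree", q, keep_ties),
        B=top_fraction(table, "betweenness", q, keep_ties),
        C=top_fraction(table, "closeness", q, keep_ties),
        S=top_fraction(table, "stress", q, keep_ties),
        q=q,
        n=len(table),
    )


def criterion_sets(sets: RankSets) -> dict[int, frozenset[str]]:
    """The five combination criteria as explicit gene sets."""
    H, B, C, S = sets.H, sets.B, sets.C, sets.S
    return {
        1: H & B,
        2: H & B & C & S,
        3: H & C & S,
        4: B & C & S,
        5: (H | B) & (C | S),
    }


def classify_important(sets: RankSets) -> list[PriorityRecord]:
    """One record per gene in any rank set; status 'important' iff >=1 criterion."""
    crit = criterion_sets(sets)
    records = []
    for gene in sorted(sets.union):
        satisfied = frozenset(c for c in CRITERIA if gene in crit[c])
        records.append(
            PriorityRecord(
                gene=gene,
                flags=sets.flags(gene),
                criteria=satisfied,
                status="important" if satisfied else "none",
            )
        )
    return records


def select_crucial(
    records: list[PriorityRecord], sets: RankSets
) -> tuple[frozenset[str], frozenset[str]]:
    """Apply the exclusion rule and return (crucial, excluded).

    Excluded genes are the important genes lying in both the bottleneck and
    stress sets but in neither the hub nor the closeness set; the crucial
    panel is the remaining important genes.  Record statuses are updated in
    place to 'crucial' / 'excluded'.
    """
    important = {r.gene for r in records if r.status in ("important", "crucial", "excluded")}
    excluded = frozenset(
        g for g in important if g in sets.B and g in sets.S and g not in sets.H and g not in sets.C
    )
    crucial = frozenset(important) - excluded
    for r in records:
        if r.gene in excluded:
            r.status = "excluded"
        elif r.gene in crucial:
            r.status = "crucial"
    return crucial, excluded


def records_frame(records: list[PriorityRecord]) -> pd.DataFrame:
    """Records as a TSV-ready DataFrame (gene, h, b, c, s, criteria, status)."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in records],
            "h": [int(r.flags[0]) for r in records],
            "b": [int(r.flags[1]) for r in records],
            "c": [int(r.flags[2]) for r in records],
            "s": [int(r.flags[3]) for r in records],
            "criteria": [",".join(map(str, sorted(r.criteria))) for r in records],
            "status": [r.status for r in records],
        }
    )


def subnetwork_report(
    net: Network, genes: frozenset[str] | set[str], weak_degree: int = 2
) -> pd.DataFrame:
    """Within-subnetwork degree of each gene, flagging weakly connected ones.

    A diagnostic mirroring the visual screen of the important-gene
    subnetwork: genes whose degree inside ``induce_subgraph(net, genes)``
    falls below ``weak_degree`` are flagged.  Also reports the component id
    of each gene within the subnetwork.
    """
    from .graph_core import connected_components

    sub = induce_subgraph(net, genes)
    deg = {v: 0 for v in sub.nodes}
    for a, b in sub.edges:
        deg[a] += 1
        deg[b] += 1
    comp_of: dict[str, int] = {}
    for i, comp in enumerate(connected_components(sub)):
        for v in comp:
            comp_of[v] = i
    rows = sorted(sub.nodes)
    return pd.DataFrame(
        {
            "gene": rows,
            "subnet_degree": [deg[g] for g in rows],
            "weak": [deg[g] < weak_degree for g in rows],
            "component": [comp_of[g] for g in rows],
        }
    )
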