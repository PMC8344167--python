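"""Network data model and file I/O.

An interaction network is a simple undirected graph over gene symbols,
optionally carrying a per-edge confidence score in [0, 1].  Edge tables may
come as plain TSV (``node1<TAB>node2[<TAB>score]``), as STRING-style exports
(scores on an integer 0-1000 scale), or as SIF (``node1 interaction node2``).
Gene-set annotations use the MSigDB GMT convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

Edge = tuple[str, str]

DIALECTS = ("tsv", "string-export", "sif")


def _norm_edge(a: str, b: str) -> Edge:
    """Canonical unordered representation of an edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class Network:
    """Simple undirected graph of gene symbols with optional edge confidences.

    Invariants (enforced by :meth:`validate`): no self-loops, every edge
    endpoint is a node, edges are stored in canonical (sorted-pair) order,
    and any confidence score lies in [0, 1].
    """

    nodes: set[str] = field(default_factory=set)
    edges: set[Edge] = field(default_factory=set)
    confidence: dict[Edge, float] | None = None

    def validate(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-loop on node {a!r}")
            if (a, b) != _norm_edge(a, b):
                raise ValueError(f"edge {(a, b)!r} not in canonical order")
            if a not in self.nodes or b not in self.nodes:
                raise ValueError(f"edge {(a, b)!r} has endpoint outside node set")
        if self.confidence is not None:
            if set(self.confidence) != self.edges:
                raise ValueError("confidence map does not cover the edge set exactly")
            for e, s in self.confidence.items():
                if not (0.0 <= s <= 1.0):
                    raise ValueError(f"confidence {s} for edge {e!r} outside [0, 1]")

    def add_edge(self, a: str, b: str, score: float | None = None) -> None:
        """Add an undirected edge; multi-edges collapse keeping the max score."""
        if a == b:
            raise ValueError(f"self-loop on node {a!r}")
        e = _norm_edge(a, b)
        self.nodes.update(e)
        self.edges.add(e)
        if score is not None:
            if self.confidence is None:
                self.confidence = {}
            prev = self.confidence.get(e)
            self.confidence[e] = score if prev is None else max(prev, score)

    def neighbors(self, node: str) -> set[str]:
        return {b if a == node else a for a, b in self.edges if node in (a, b)}

    def adjacency(self) -> dict[str, list[str]]:
        """Adjacency lists with deterministic (lexicographic) ordering."""
        adj: dict[str, set[str]] = {v: set() for v in self.nodes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return {v: sorted(adj[v]) for v in sorted(adj)}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass
class AnnotationSet:
    """Gene-set annotation: term id -> (term name, gene set), plus background."""

    terms: dict[str, tuple[str, frozenset[str]]]
    background: frozenset[str]

    def validate(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValueError(f"term {tid!r} has an empty gene set")
            if not genes <= self.background:
                raise ValueError(f"term {tid!r} has genes outside the background")


def read_edge_table(
    path: str | Path,
    score_column: str | int | None = None,
    threshold: float = 0.0,
    dialect: str = "tsv",
    uppercase: bool = True,
) -> Network:
    """Read an edge list, keeping edges whose confidence is >= ``threshold``.

    ``dialect``:

    - ``tsv``: ``node1<TAB>node2[<TAB>score]`` with score already in [0, 1]
      (values > 1 are assumed to be on the STRING 0-1000 integer scale and
      divided by 1000);
    - ``string-export``: same columns, scores always divided by 1000 when > 1;
    - ``sif``: ``node1 interaction node2`` (whitespace separated, no score).

    A header line is skipped if its fields are non-numeric where a score is
    expected or it matches common column names.  Lines with a single field
    declare an isolated node.  Gene symbols are uppercased on read by default
    (HGNC-style symbols are case-insensitive in practice and source tables
    mix spellings such as C1orf56/C1ORF56).
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError(f"threshold {threshold} outside [0, 1]")
    path = Path(path)
    net = Network()
    with open(path) as fh:
        lines = fh.read().splitlines()
    header_names = {"node1", "node2", "source", "target", "gene1", "gene2",
                    "protein1", "protein2", "combined_score", "score"}
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if lineno == 1 and any(f.lower() in header_names for f in fields):
            continue
        if dialect == "sif":
            if len(fields) == 1:
                net.nodes.add(_sym(fields[0], uppercase))
                continue
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: SIF line needs 'node1 interaction node2'"
                )
            a, b = _sym(fields[0], uppercase), _sym(fields[2], uppercase)
            if a != b:
                net.add_edge(a, b)
            continue
        if len(fields) == 1:
            net.nodes.add(_sym(fields[0], uppercase))
            continue
        if len(fields) < 2:
            raise ValueError(f"{path.name}:{lineno}: expected at least two columns")
        a, b = _sym(fields[0], uppercase), _sym(fields[1], uppercase)
        score: float | None = None
        if score_column is not None or len(fields) >= 3:
            idx = 2
            if isinstance(score_column, int):
                idx = score_column
            try:
                score = float(fields[idx])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path.name}:{lineno}: cannot parse confidence score"
                ) from exc
            if score > 1.0 or dialect == "string-export":
                score /= 1000.0
            if not (0.0 <= score <= 1.0):
                raise ValueError(
                    f"{path.name}:{lineno}: score {score} outside [0, 1] after scaling"
                )
        if a == b:
            continue  # self-interactions are dropped
        if score is None or score >= threshold:
            net.add_edge(a, b, score)
    net.validate()
    return net


def _sym(s: str, uppercase: bool) -> str:
    s = s.strip()
    if not s:
        raise ValueError("empty gene symbol")
    return s.upper() if uppercase else s


def write_edge_table(net: Network, path: str | Path) -> None:
    """Write TSV ``node1 node2 [combined_score]`` in canonical sorted order."""
    with open(path, "w") as fh:
        if net.confidence is not None:
            fh.write("node1\tnode2\tcombined_score\n")
            for a, b in sorted(net.edges):
                fh.write(f"{a}\t{b}\t{net.confidence[(a, b)]:.3f}\n")
        else:
            fh.write("node1\tnode2\n")
            for a, b in sorted(net.edges):
                fh.write(f"{a}\t{b}\n")
        for v in sorted(net.nodes):
            if not net.neighbors(v):
                fh.write(f"{v}\n")


def write_sif(net: Network, path: str | Path, interaction: str = "pp") -> None:
    with open(path, "w") as fh:
        for a, b in sorted(net.edges):
            fh.write(f"{a}\t{interaction}\t{b}\n")
        for v in sorted(net.nodes):
            if not net.neighbors(v):
                fh.write(f"{v}\n")


def connected_components(net: Network) -> list[set[str]]:
    """Partition nodes into connected components.

    Returned in decreasing size order, ties broken by the lexicographically
    smallest member.
    """
    adj = net.adjacency()
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in sorted(net.nodes):
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if u not in comp:
                    comp.add(u)
                    stack.append(u)
        seen |= comp
        comps.append(comp)
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def main_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component."""
    if not net.nodes:
        raise ValueError("cannot take the main component of an empty network")
    return induce_subgraph(net, connected_components(net)[0])


def induce_subgraph(net: Network, genes: Iterable[str]) -> Network:
    """Induced subgraph on ``genes`` ∩ ``net.nodes``; absent genes warn."""
    genes = set(genes)
    missing = genes - net.nodes
    if missing:
        warnings.warn(
            f"{len(missing)} gene(s) not in the network were ignored: "
            + ", ".join(sorted(missing)[:5]),
            stacklevel=2,
        )
    keep = genes & net.nodes
    edges = {e for e in net.edges if e[0] in keep and e[1] in keep}
    conf = None
    if net.confidence is not None:
        conf = {e: net.confidence[e] for e in edges}
    sub = Network(nodes=keep, edges=edges, confidence=conf)
    sub.validate()
    return sub


def read_gmt(
    path: str | Path,
    background: Iterable[str] | None = None,
    uppercase: bool = True,
) -> AnnotationSet:
    """Read a GMT gene-set file (``id<TAB>description<TAB>gene...``).

    The background defaults to the union of all term genes unless one is
    supplied explicitly.
    """
    path = Path(path)
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line needs id, description and >=1 gene"
                )
            tid, desc = fields[0], fields[1]
            genes = frozenset(_sym(g, uppercase) for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path.name}:{lineno}: term {tid!r} has no genes")
            if tid in terms:
                raise ValueError(f"{path.name}:{lineno}: duplicate term id {tid!r}")
            terms[tid] = (desc, genes)
    if background is None:
        bg = frozenset().union(*(g for _, g in terms.values())) if terms else frozenset()
    else:
        bg = frozenset(_sym(g, uppercase) for g in background)
        bg = bg | frozenset().union(*(g for _, g in terms.values())) if terms else bg
    ann = AnnotationSet(terms=terms, background=bg)
    ann.validate()
    return ann


def write_gmt(ann: AnnotationSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for tid in sorted(ann.terms):
            desc, genes = ann.terms[tid]
            fh.write("\t".join([tid, desc, *sorted(genes)]) + "\n")
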