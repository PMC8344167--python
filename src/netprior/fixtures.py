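"""Packaged reference tables from the published PTSD network study.

The original STRING edge list was never deposited, so the study's printed
tables are the only machine-checkable ground truth.  Three TSVs ship inside
the package:

- ``table1.tsv`` — the four top-20% membership lists (degree/hub,
  betweenness/bottleneck, closeness, stress), 12 genes each, in printed
  rank order;
- ``table2.tsv`` — the 18 important genes with their printed centrality
  values and STRING disease score (the disease score is source data only,
  never computed here);
- ``table3.tsv`` — the 12 crucial genes with literature-derived regulation
  direction (``up``/``down``/``na`` where the source prose gives none) and
  citation tag; metadata only.

Gene symbols are uppercased on load (the source mixes C1orf56/C1ORF56); the
as-printed spelling is retained in ``table2.gene_as_printed``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .prioritize import RankSets

_CHECKSUMS = {
    "table1.tsv": "39f349825cd4ada422b154a2013f1d9bcdf0f9b9ec179102c38d91ce52d03947",
    "table2.tsv": "339cfa90b9b8aac78e90274f21794262d3b74c60da396740419822d959028d8e",
    "table3.tsv": "a9ec1a22d563869bb81d83ed549c618c49643494b6a22eadfb6ecbe9779ca2f9",
}

#: size of the main connected component the printed rank sets were drawn from
COMPONENT_SIZE = 63


@dataclass(frozen=True)
class PaperFixture:
    """The three reference tables, loaded and symbol-normalized."""

    table1: RankSets           # four 12-gene top-20% sets
    table1_order: dict[str, list[str]]  # printed rank order per column
    table2: pd.DataFrame       # 18 rows, indexed by gene
    table3: pd.DataFrame       # 12 rows, indexed by gene

    def validate(self) -> None:
        for name, s in (("H", self.table1.H), ("B", self.table1.B),
                        ("C", self.table1.C), ("S", self.table1.S)):
            if len(s) != 12:
                raise ValueError(f"rank set {name} has {len(s)} genes, expected 12")
        if len(self.table2) != 18:
            raise ValueError(f"centrality table has {len(self.table2)} rows, expected 18")
        if len(self.table3) != 12:
            raise ValueError(f"crucial panel has {len(self.table3)} rows, expected 12")
        t3 = set(self.table3.index)
        t2 = set(self.table2.index)
        if not t3 < t2:
            raise ValueError("crucial genes are not a proper subset of the important genes")
        if not t2 < set(self.table1.union):
            raise ValueError("important genes are not a proper subset of the rank-set union")


def _read_packaged(name: str) -> pd.DataFrame:
    ref = resources.files("netprior.data").joinpath(name)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise ValueError(f"packaged fixture {name} is corrupted (checksum mismatch)")
    with ref.open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_fixture() -> PaperFixture:
    """Load and validate the packaged reference tables."""
    t1 = _read_packaged("table1.tsv")
    order = {col: [g.upper() for g in t1[col]] for col in t1.columns}
    sets = RankSets(
        H=frozenset(order["degree"]),
        B=frozenset(order["betweenness"]),
        C=frozenset(order["closeness"]),
        S=frozenset(order["stress"]),
        q=0.2,
        n=COMPONENT_SIZE,
    )

    t2 = _read_packaged("table2.tsv")
    t2["gene_as_printed"] = t2["gene"]
    t2["gene"] = t2["gene"].str.upper()
    t2 = t2.set_index("gene")

    t3 = _read_packaged("table3.tsv")
    t3["gene"] = t3["gene"].str.upper()
    t3 = t3.set_index("gene")

    fx = PaperFixture(table1=sets, table1_order=order, table2=t2, table3=t3)
    fx.validate()
    return fx
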