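"""End-to-end prioritization pipeline and its configuration.

Two input modes:

- ``edges`` — a network edge table: read, threshold on confidence, restrict
  to the main connected component, compute the four centralities, build the
  top-q rank sets, classify and select the crucial panel, optionally enrich
  against a GMT annotation;
- ``sets`` — precomputed rank-set membership lists (a four-column TSV, one
  column per metric, like the published top-20% tables): skip the network
  and centrality stages and start at classification.

Every run writes TSV outputs plus a JSON manifest (tool version, config,
config hash, input checksum, summary counts) sufficient to reproduce the
output files exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .centrality import centrality_table
from .enrich import enrich, kappa_group
from .graph_core import main_component, read_edge_table, read_gmt
from .prioritize import (
    RankSets,
    build_rank_sets,
    classify_important,
    records_frame,
    select_crucial,
    subnetwork_report,
)

log = logging.getLogger("netprior")


@dataclass
class PipelineConfig:
    """Flat, file-round-trippable pipeline configuration."""

    input: str = ""
    mode: str = "edges"              # edges | sets
    dialect: str = "tsv"
    threshold: float = 0.4           # confidence cutoff, STRING default
    q: float = 0.2                   # top fraction per metric
    keep_ties: bool = False
    weak_degree: int = 2
    gmt: str = ""                    # optional annotation for enrichment
    background: str = ""             # optional background gene list file
    alpha: float = 0.01
    method: str = "holm"
    kappa: float = 0.4
    outdir: str = "netprior_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.mode not in ("edges", "sets"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.threshold <= 1.0):
            raise ValueError("confidence threshold outside [0, 1]")
        if not (0.0 < self.q <= 1.0):
            raise ValueError("top fraction q outside (0, 1]")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha outside (0, 1]")
        if not (0.0 <= self.kappa <= 1.0):
            raise ValueError("kappa threshold outside [0, 1]")

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name} = {getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key not in types:
                    raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
                cur = getattr(defaults, key)
                if isinstance(cur, bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                elif isinstance(cur, int):
                    kwargs[key] = int(value)
                elif isinstance(cur, float):
                    kwargs[key] = float(value)
                else:
                    kwargs[key] = value
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


@dataclass
class PipelineResult:
    """Summary of one pipeline run."""

    n_component: int
    n_important: int
    n_excluded: int
    n_crucial: int
    crucial: frozenset[str]
    excluded: frozenset[str]
    files: dict[str, str] = field(default_factory=dict)


def read_rank_set_table(path: str | Path) -> RankSets:
    """Read a four-column membership TSV (degree/betweenness/closeness/stress)."""
    df = pd.read_csv(path, sep="\t")
    required = {"degree", "betweenness", "closeness", "stress"}
    if set(df.columns) != required:
        raise ValueError(f"rank-set table must have exactly columns {sorted(required)}")

    def col(name: str) -> frozenset[str]:
        return frozenset(str(g).upper() for g in df[name].dropna())

    sets = RankSets(H=col("degree"), B=col("betweenness"),
                    C=col("closeness"), S=col("stress"),
                    q=0.2, n=0)
    return sets


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write all outputs under cfg.outdir."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}

    net = None
    if cfg.mode == "edges":
        try:
            full = read_edge_table(cfg.input, threshold=cfg.threshold, dialect=cfg.dialect)
            net = main_component(full)
        except Exception as exc:
            raise RuntimeError(f"stage 'read network': {exc}") from exc
        log.info("main component: %d of %d nodes, %d edges",
                 net.n_nodes, full.n_nodes, net.n_edges)
        try:
            table = centrality_table(net)
        except Exception as exc:
            raise RuntimeError(f"stage 'centrality': {exc}") from exc
        cpath = outdir / "centrality.tsv"
        table.sort_values(["degree", "gene"], ascending=[False, True],
                          key=None).to_csv(cpath, sep="\t", float_format="%.6f")
        files["centrality"] = str(cpath)
        sets = build_rank_sets(table, q=cfg.q, keep_ties=cfg.keep_ties)
        n_component = net.n_nodes
    else:
        try:
            sets = read_rank_set_table(cfg.input)
        except Exception as exc:
            raise RuntimeError(f"stage 'read rank sets': {exc}") from exc
        n_component = len(sets.union)

    records = classify_important(sets)
    crucial, excluded = select_crucial(records, sets)
    important = crucial | excluded
    if not crucial:
        log.warning("no crucial genes selected")
    ppath = outdir / "priority.tsv"
    records_frame(records).to_csv(ppath, sep="\t", index=False)
    files["priority"] = str(ppath)

    if net is not None and important:
        report = subnetwork_report(net, important, weak_degree=cfg.weak_degree)
        spath = outdir / "subnetwork.tsv"
        report.to_csv(spath, sep="\t", index=False)
        files["subnetwork"] = str(spath)

    if cfg.gmt:
        try:
            background = None
            if cfg.background:
                background = [
                    line.strip() for line in open(cfg.background) if line.strip()
                ]
            ann = read_gmt(cfg.gmt, background=background)
            terms = enrich(crucial, ann, alpha=cfg.alpha, method=cfg.method)
            kappa_group(terms, ann, threshold=cfg.kappa)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrichment': {exc}") from exc
        epath = outdir / "enrichment.tsv"
        pd.DataFrame(
            {
                "term_id": [t.term_id for t in terms],
                "name": [t.name for t in terms],
                "K": [t.K for t in terms],
                "k": [t.k for t in terms],
                "p_raw": [f"{t.p_raw:.6g}" for t in terms],
                "p_adj": [f"{t.p_adj:.6g}" for t in terms],
                "significant": [int(t.significant) for t in terms],
                "group": ["" if t.group is None else t.group for t in terms],
            }
        ).to_csv(epath, sep="\t", index=False)
        files["enrichment"] = str(epath)

    manifest = {
        "tool": "netprior",
        "version": __version__,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "input_sha256": hashlib.sha256(Path(cfg.input).read_bytes()).hexdigest(),
        "summary": {
            "component_size": n_component,
            "important": len(important),
            "excluded": len(excluded),
            "crucial": len(crucial),
            "crucial_genes": sorted(crucial),
            "excluded_genes": sorted(excluded),
        },
        "files": {k: Path(v).name for k, v in files.items()},
    }
    mpath = outdir / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    files["manifest"] = str(mpath)

    return PipelineResult(
        n_component=n_component,
        n_important=len(important),
        n_excluded=len(excluded),
        n_crucial=len(crucial),
        crucial=crucial,
        excluded=excluded,
        files=files,
    )
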