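"""End-to-end orchestration of the prioritization workflow.

``run_pipeline`` wires the stages together: read inputs, confidence-filter,
first-order expand, topology + backbone, MCL clustering, switch detection,
MCODE complexes, and over-representation analysis per GMT collection.  All
reports land in one output directory together with a machine-readable run
manifest (parameters, input checksums, tool version).  Reruns with
identical config and inputs are byte-identical except for the manifest
timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .build import BuildParams, filter_by_confidence, first_order_expand
from .community import MCLParams, find_switches, mcl
from .enrichment import kappa_term_clusters, ora
from .io import read_aliases, read_edge_table, read_gmt, read_seed_list, write_report
from .mcode import MCODEParams, mcode_complexes
from .topology import edge_enrichment, extract_backbone, topology_report

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "GMTInput", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class GMTInput:
    path: str
    universe_size: int


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs.  Defaults reproduce the published settings:
    tau 0.400, 50 first-shell interactors, inflation 3.0, kappa 0.3, six
    hubs, and two non-hub bottlenecks."""

    edges: str
    seeds: str
    out_dir: str
    dialect: str = "string1000"
    aliases: Optional[str] = None
    gmt: tuple[GMTInput, ...] = ()
    build: BuildParams = field(default_factory=BuildParams)
    mcl: MCLParams = field(default_factory=MCLParams)
    mcode: MCODEParams = field(default_factory=MCODEParams)
    min_overlap: int = 3
    kappa_threshold: float = 0.3
    n_hubs: int = 6
    n_bottlenecks: int = 2
    background_density: Optional[float] = None
    switch_top_k: int = 2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key, params_cls in (
            ("build", BuildParams),
            ("mcl", MCLParams),
            ("mcode", MCODEParams),
        ):
            if key in raw:
                raw[key] = params_cls(**raw[key])
        if "gmt" in raw:
            raw["gmt"] = tuple(GMTInput(**g) for g in raw["gmt"])
        return cls(**raw)


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and write all reports to ``config.out_dir``.

    Emits net.json, topo.json, backbone.tsv, clusters.tsv, switches.tsv,
    complexes.tsv, one enrichment-<collection>.tsv per GMT input, and
    manifest.json.  A stage failure aborts with the stage name; outputs
    written so far are retained alongside a ``.partial`` marker file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "read-inputs"
        aliases = read_aliases(config.aliases) if config.aliases else None
        background = read_edge_table(config.edges, dialect=config.dialect, aliases=aliases)
        seeds = read_seed_list(config.seeds, aliases=aliases)
        log.info("background: %d nodes, %d edges; %d seeds",
                 background.number_of_nodes(), background.number_of_edges(),
                 len(seeds.members))

        stage = "build"
        filtered = filter_by_confidence(background, config.build.tau)
        net = first_order_expand(filtered, seeds, config.build)
        log.info("first-order network: %d nodes, %d edges",
                 net.number_of_nodes(), net.number_of_edges())
        write_report(net, out / "net.json", "json")

        stage = "topology"
        topo = topology_report(net)
        write_report(topo, out / "topo.json", "json")
        backbone = extract_backbone(net, config.n_hubs, config.n_bottlenecks)
        write_report(backbone, out / "backbone.tsv", "tsv")
        if config.background_density is not None:
            write_report(
                edge_enrichment(net, config.background_density),
                out / "edge_enrichment.json",
                "json",
            )

        stage = "cluster"
        clustering = mcl(net, config.mcl)
        log.info("MCL: %d clusters in %d iterations", clustering.n_clusters,
                 clustering.iterations)
        write_report(clustering, out / "clusters.tsv", "tsv")

        stage = "switches"
        if clustering.n_clusters >= 2:
            switches = find_switches(
                net, clustering, seeds, 1, 2,
                tau=config.build.tau, top_k=config.switch_top_k,
            )
            write_report(switches, out / "switches.tsv", "tsv")
        else:
            (out / "switches.tsv").write_text(
                "node\tconn_a\tconn_b\tswitch_score\n"
            )

        stage = "mcode"
        complexes = mcode_complexes(net, config.mcode)
        write_report(complexes, out / "complexes.tsv", "tsv")

        stage = "enrichment"
        query = sorted(net.nodes())
        for gmt_in in config.gmt:
            collection = read_gmt(gmt_in.path, universe_size=gmt_in.universe_size)
            rows = ora(query, collection, min_overlap=config.min_overlap)
            name = Path(gmt_in.path).stem
            write_report(rows, out / f"enrichment-{name}.tsv", "tsv")
            if rows:
                clusters = kappa_term_clusters(rows, query, config.kappa_threshold)
                write_report(
                    [dataclasses.asdict(c) for c in clusters],
                    out / f"termclusters-{name}.json",
                    "json",
                )

        stage = "manifest"
        manifest = {
            "tool": "ppinet",
            "version": __version__,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "config": dataclasses.asdict(config),
            "inputs": {
                "edges_sha256": _sha256(config.edges),
                "seeds_sha256": _sha256(config.seeds),
                "gmt_sha256": {g.path: _sha256(g.path) for g in config.gmt},
            },
            "network": {
                "n_nodes": net.number_of_nodes(),
                "n_edges": net.number_of_edges(),
                "n_clusters": clustering.n_clusters,
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    except Exception as exc:
        (out / ".partial").write_text(f"failed at stage: {stage}\n")
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    partial = out / ".partial"
    if partial.exists():
        partial.unlink()
    return out
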