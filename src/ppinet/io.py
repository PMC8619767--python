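"""Readers and writers for every external format the pipeline touches.

Interaction tables are tab-separated ``node_a, node_b, score`` files in one
of two score dialects: ``"string1000"`` (integer combined scores 0-1000, the
STRING export convention) or ``"unit"`` (reals on [0, 1]).  Gene sets use the
GMT format; seed lists are plain text with ``#`` comments.  All identifiers
are canonicalized to stripped uppercase on the way in.

No computation happens here beyond parsing and validation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "SeedSet",
    "GeneSetTerm",
    "GeneSetCollection",
    "canonical",
    "new_network",
    "read_aliases",
    "read_edge_table",
    "read_seed_list",
    "read_gmt",
    "write_report",
    "read_report",
    "load_stroke_seeds",
]


class ParseError(ValueError):
    """A malformed line in an input file (message carries the line number)."""


def canonical(identifier: str, aliases: Optional[Mapping[str, str]] = None) -> str:
    """Normalize an identifier: strip whitespace, uppercase, apply aliases."""
    ident = identifier.strip().upper()
    if aliases:
        ident = aliases.get(ident, ident)
    return ident


@dataclass(frozen=True)
class SeedSet:
    """A named, ordered list of seed identifiers with an optional community label."""

    name: str
    members: tuple[str, ...]
    community: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"seed set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"seed set {self.name!r} has duplicate members")


@dataclass(frozen=True)
class GeneSetTerm:
    term_id: str
    description: str
    genes: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene-set terms plus a declared annotation-universe size.

    ``universe_size`` is always explicit: the enrichment tools this package
    mirrors use hidden universes, so a collection never carries a silent
    default.  ``universe`` optionally lists the universe members when they
    are known (e.g. for synthetic collections); ``None`` means membership is
    undecidable and every query gene is assumed in-universe.
    """

    source_name: str
    terms: tuple[GeneSetTerm, ...]
    universe_size: int
    universe: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        union: set[str] = set()
        for term in self.terms:
            if not term.genes:
                raise ValueError(f"term {term.term_id!r} has an empty gene set")
            union |= term.genes
        if self.universe_size < len(union):
            raise ValueError(
                f"universe_size {self.universe_size} smaller than the union of "
                f"all term gene sets ({len(union)})"
            )
        if self.universe is not None and not union <= self.universe:
            raise ValueError("term genes fall outside the declared universe")

    def __len__(self) -> int:
        return len(self.terms)


def new_network(
    edges: Iterable[tuple[str, str, float]] = (), nodes: Iterable[str] = ()
) -> nx.Graph:
    """Build an undirected confidence-weighted network.

    Edges are ``(node_a, node_b, confidence)`` with confidence on [0, 1];
    duplicate unordered pairs keep the maximum confidence and self-loops are
    rejected.  The returned graph is the in-memory container every pipeline
    stage operates on (edge attribute ``"confidence"``).
    """
    net = nx.Graph()
    net.add_nodes_from(nodes)
    for a, b, conf in edges:
        if a == b:
            raise ValueError(f"self-loop on {a!r}")
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"confidence {conf} outside [0, 1] on ({a}, {b})")
        if net.has_edge(a, b):
            conf = max(conf, net.edges[a, b]["confidence"])
        net.add_edge(a, b, confidence=float(conf))
    return net


def read_aliases(path: str | Path) -> dict[str, str]:
    """Read a two-column alias table (alias TAB canonical), '#' comments allowed."""
    aliases: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated fields")
        aliases[canonical(fields[0])] = canonical(fields[1])
    return aliases


def _parse_score(text: str, dialect: str, path, lineno: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise ParseError(f"{path}:{lineno}: non-numeric score {text!r}") from None
    if dialect == "string1000":
        if not value.is_integer() or not 0 <= value <= 1000:
            raise ValueError(
                f"{path}:{lineno}: string1000 score must be an integer in "
                f"[0, 1000], got {text!r}"
            )
        return value / 1000.0
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{path}:{lineno}: unit score {value} outside [0, 1]")
    return value


def read_edge_table(
    path: str | Path,
    dialect: str = "string1000",
    aliases: Optional[Mapping[str, str]] = None,
) -> nx.Graph:
    """Read a scored interaction table into a network.

    Expects >=3 tab/whitespace-separated columns (node_a, node_b, score).  A
    header line is auto-detected by a non-numeric third field.  Duplicate
    unordered pairs collapse to the maximum confidence; self-loops are
    dropped with a warning.
    """
    if dialect not in ("string1000", "unit"):
        raise ValueError(f"unknown dialect {dialect!r}")
    net = nx.Graph()
    lines = Path(path).read_text().splitlines()
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >=3 columns, got {len(fields)}")
        try:
            float(fields[2])
        except ValueError:
            if lineno == 1:  # header row
                continue
            raise ParseError(f"{path}:{lineno}: non-numeric score {fields[2]!r}") from None
        conf = _parse_score(fields[2], dialect, path, lineno)
        a = canonical(fields[0], aliases)
        b = canonical(fields[1], aliases)
        if a == b:
            log.warning("%s:%d: dropping self-loop on %s", path, lineno, a)
            net.add_node(a)
            continue
        if net.has_edge(a, b):
            conf = max(conf, net.edges[a, b]["confidence"])
        net.add_edge(a, b, confidence=conf)
    return net


def read_seed_list(
    path: str | Path,
    name: Optional[str] = None,
    community: Optional[str] = None,
    aliases: Optional[Mapping[str, str]] = None,
) -> SeedSet:
    """Read a one-identifier-per-line seed list ('#' comments allowed).

    Order is preserved; duplicates after case-normalization (and aliasing)
    are removed with a warning.  An empty list after filtering is an error.
    """
    members: list[str] = []
    seen: set[str] = set()
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        ident = canonical(line, aliases)
        if ident in seen:
            log.warning("%s: duplicate seed %s removed", path, ident)
            continue
        seen.add(ident)
        members.append(ident)
    if not members:
        raise ValueError(f"{path}: seed list empty after filtering")
    return SeedSet(name=name or Path(path).stem, members=tuple(members), community=community)


def read_gmt(
    path: str | Path,
    universe_size: int,
    universe: Optional[Iterable[str]] = None,
) -> GeneSetCollection:
    """Read a GMT gene-set file (term_id TAB description TAB gene...).

    Terms keep file order; genes are case-normalized; ``universe_size``
    (mandatory) is attached to the collection.  A repeated term_id or a
    universe smaller than the union of all gene sets is an error.
    """
    terms: list[GeneSetTerm] = []
    seen_ids: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
        term_id = fields[0].strip()
        if term_id in seen_ids:
            raise ParseError(f"{path}:{lineno}: duplicate term_id {term_id!r}")
        seen_ids.add(term_id)
        genes = frozenset(canonical(g) for g in fields[2:] if g.strip())
        terms.append(GeneSetTerm(term_id=term_id, description=fields[1].strip(), genes=genes))
    if not terms:
        log.warning("%s: empty GMT file, returning an empty collection", path)
    return GeneSetCollection(
        source_name=Path(path).stem,
        terms=tuple(terms),
        universe_size=int(universe_size),
        universe=frozenset(canonical(g) for g in universe) if universe is not None else None,
    )


# ---------------------------------------------------------------------------
# report serialization


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        d = {"kind": type(obj).__name__}
        d.update(dataclasses.asdict(obj))
        return _to_jsonable(d)
    if isinstance(obj, nx.Graph):
        return {
            "kind": "Network",
            "nodes": sorted(obj.nodes()),
            "edges": [
                [a, b, obj.edges[a, b]["confidence"]]
                for a, b in sorted(tuple(sorted(e)) for e in obj.edges())
            ],
        }
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, float) and (math.isnan(obj) or math.isinf(obj)):
        return repr(obj)
    return obj


def _rows_frame(report) -> pd.DataFrame:
    """Flatten a pipeline result into a table for TSV output."""
    from . import community, enrichment, mcode, topology  # local, avoids cycles

    if isinstance(report, community.Clustering):
        rows = sorted(report.assignment.items())
        return pd.DataFrame(rows, columns=["node", "cluster_id"])
    if isinstance(report, community.SwitchReport):
        return pd.DataFrame([dataclasses.asdict(r) for r in report.rows])
    if isinstance(report, topology.Backbone):
        hub_rows = [
            {"role": "hub", "node": n, "value": d} for n, d in report.hubs
        ]
        bn_rows = [
            {"role": "bottleneck", "node": n, "value": b}
            for n, b in report.non_hub_bottlenecks
        ]
        return pd.DataFrame(hub_rows + bn_rows)
    if isinstance(report, (list, tuple)) and report:
        first = report[0]
        if isinstance(first, enrichment.EnrichmentRow):
            frame = pd.DataFrame([dataclasses.asdict(r) for r in report])
            frame["overlap_genes"] = frame["overlap_genes"].map(lambda g: ",".join(g))
            return frame.sort_values("p", kind="mergesort").reset_index(drop=True)
        if isinstance(first, mcode.Complex):
            return pd.DataFrame(
                {
                    "seed_node": r.seed_node,
                    "size": len(r.members),
                    "score": r.score,
                    "members": ",".join(sorted(r.members)),
                }
                for r in report
            )
    if isinstance(report, (list, tuple)):
        return pd.DataFrame(list(report))
    if dataclasses.is_dataclass(report):
        flat = {
            k: v
            for k, v in dataclasses.asdict(report).items()
            if not isinstance(v, (dict, list, tuple))
        }
        return pd.DataFrame([flat])
    raise TypeError(f"cannot serialize {type(report).__name__} as TSV")


def write_report(report, path: str | Path, format: str = "json") -> None:
    """Serialize a pipeline result to JSON (nested, lossless) or TSV (flat).

    JSON output round-trips through :func:`read_report`; floats are written
    at full precision.  Enrichment-row lists are written sorted by p.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(report), indent=1, sort_keys=True) + "\n")
    elif format == "tsv":
        _rows_frame(report).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_report(path: str | Path):
    """Read a JSON report back; known dataclass kinds are reconstructed."""
    from . import community, enrichment, mcode, topology

    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        return data
    kind = data.pop("kind", None)
    registry = {
        "TopologyReport": topology.TopologyReport,
        "EdgeEnrichment": topology.EdgeEnrichment,
    }
    if kind == "Network":
        return new_network(
            ((a, b, c) for a, b, c in data["edges"]), nodes=data["nodes"]
        )
    if kind == "Backbone":
        return topology.Backbone(
            hubs=tuple((n, d) for n, d in data["hubs"]),
            non_hub_bottlenecks=tuple((n, b) for n, b in data["non_hub_bottlenecks"]),
        )
    if kind == "Clustering":
        return community.Clustering(
            assignment={k: int(v) for k, v in data["assignment"].items()},
            n_clusters=data["n_clusters"],
            converged=data["converged"],
            iterations=data["iterations"],
        )
    if kind in registry:
        return registry[kind](**data)
    if kind is not None:
        data["kind"] = kind
    return data


def load_stroke_seeds() -> dict[str, SeedSet]:
    """Load the shipped stroke seed fixtures.

    Returns the 15 differentially expressed proteins (``"dep15"``), the 10
    literature genes (``"genes10"``), and their 24-member union
    (``"combined"``; fibrinogen's protein label FBG and gene symbol FGB are
    merged via the shipped alias table).
    """
    pkg = resources.files("ppinet.data")
    with resources.as_file(pkg / "aliases.tsv") as p:
        aliases = read_aliases(p)
    with resources.as_file(pkg / "seeds_dep15.txt") as p:
        deps = read_seed_list(p, name="dep15", community=None, aliases=aliases)
    with resources.as_file(pkg / "seeds_genes10.txt") as p:
        genes = read_seed_list(p, name="genes10", community=None, aliases=aliases)
    combined: list[str] = list(deps.members)
    combined += [g for g in genes.members if g not in set(deps.members)]
    return {
        "dep15": deps,
        "genes10": genes,
        "combined": SeedSet(name="dep_plus_genes", members=tuple(combined)),
    }
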