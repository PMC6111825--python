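"""Pathway definitions as undirected, unweighted gene-gene graphs.

Pathway topology (e.g. from KEGG) is consumed in two plain-text forms: a
per-pathway edge-list TSV (the canonical interchange format of this package)
and a minimal dialect of KGML restricted to gene entries and their relations.
Either way the result is a :class:`PathwayGraph`: an undirected, unweighted
graph over bare gene symbols, with no self-loops and each edge stored once.
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "PathwayGraph",
    "load_pathway_edgelists",
    "write_pathway_edgelists",
    "parse_kgml_minimal",
]


@dataclass(frozen=True)
class PathwayGraph:
    """One pathway as an undirected, unweighted gene-gene graph.

    Parameters
    ----------
    pathway_id
        Identifier of the pathway (e.g. ``"path:04390"``).
    genes
        Gene symbols in the pathway. May include isolated nodes.
    edges
        Unordered gene pairs; each stored once as a sorted tuple.
    """

    pathway_id: str
    genes: frozenset[str] = field(default_factory=frozenset)
    edges: frozenset[tuple[str, str]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.pathway_id:
            raise ValueError("pathway_id must be a non-empty string")
        genes = frozenset(self.genes)
        for g in genes:
            if not isinstance(g, str) or not g:
                raise ValueError(f"invalid gene symbol {g!r} in {self.pathway_id}")
        canon = set()
        for e in self.edges:
            a, b = e
            if a == b:
                raise ValueError(f"self-loop {a!r} in pathway {self.pathway_id}")
            if a not in genes or b not in genes:
                raise ValueError(
                    f"edge {e!r} references gene outside pathway {self.pathway_id}"
                )
            canon.add((a, b) if a < b else (b, a))
        object.__setattr__(self, "genes", genes)
        object.__setattr__(self, "edges", frozenset(canon))

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def adjacency(self) -> dict[str, set[str]]:
        """Adjacency sets over all genes (isolated genes map to empty sets)."""
        adj: dict[str, set[str]] = {g: set() for g in self.genes}
        for a, b in self.edges:
            adj[a].add(b)
            adj[b].add(a)
        return adj

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.genes))
        g.add_edges_from(sorted(self.edges))
        g.graph["pathway_id"] = self.pathway_id
        return g

    @classmethod
    def from_edges(
        cls, pathway_id: str, edges: Iterable[tuple[str, str]],
        extra_genes: Iterable[str] = (),
    ) -> "PathwayGraph":
        edges = list(edges)
        genes = {g for e in edges for g in e} | set(extra_genes)
        return cls(pathway_id, frozenset(genes), frozenset(edges))


def load_pathway_edgelists(path: str | Path) -> list[PathwayGraph]:
    """Read pathway graphs from a 3-column TSV ``pathway_id  gene_a  gene_b``.

    Comment lines start with ``#``. Duplicate and reversed edges are collapsed;
    self-loops are dropped (the gene is kept as an isolated node) with a
    logged warning. Returns one graph per distinct pathway id, in order of
    first appearance; an empty file yields an empty list.
    """
    path = Path(path)
    edges: dict[str, set[tuple[str, str]]] = {}
    genes: dict[str, set[str]] = {}
    order: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, "
                    f"got {len(fields)}"
                )
            pid, a, b = (f.strip() for f in fields)
            if not pid or not a or not b:
                raise ValueError(f"{path}:{lineno}: empty field")
            if pid not in edges:
                edges[pid] = set()
                genes[pid] = set()
                order.append(pid)
            genes[pid].update((a, b))
            if a == b:
                logger.warning(
                    "%s:%d: self-loop on %s in %s dropped (gene kept as node)",
                    path, lineno, a, pid,
                )
                continue
            edges[pid].add((a, b) if a < b else (b, a))
    return [
        PathwayGraph(pid, frozenset(genes[pid]), frozenset(edges[pid]))
        for pid in order
    ]


def write_pathway_edgelists(
    graphs: Iterable[PathwayGraph], path: str | Path,
    header_lines: Iterable[str] = (),
) -> None:
    """Write graphs to the edge-list TSV format read by `load_pathway_edgelists`.

    Isolated genes are encoded as self-loop rows, which the loader converts
    back to isolated nodes, so a write/read round-trip is lossless.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("# pathway_id\tgene_a\tgene_b\n")
        for g in graphs:
            connected = {x for e in g.edges for x in e}
            for a, b in sorted(g.edges):
                fh.write(f"{g.pathway_id}\t{a}\t{b}\n")
            for iso in sorted(g.genes - connected):
                fh.write(f"{g.pathway_id}\t{iso}\t{iso}\n")


def _entry_symbols(entry: ET.Element) -> list[str]:
    """Gene symbols of a KGML entry: its name attribute split on commas/space."""
    raw = entry.get("name", "")
    parts = [p for chunk in raw.split(",") for p in chunk.split()]
    return [p for p in parts if p]


def parse_kgml_minimal(path: str | Path) -> PathwayGraph:
    """Parse the minimal KGML dialect: ``<entry type="gene">`` + ``<relation>``.

    Every relation between two gene entries yields one undirected edge between
    each pair of symbols of the two entries (multi-gene entries expand to all
    cross pairs). Entries of any other type ("map", "compound", "group", ...)
    and relations touching them are ignored, as are relation subtypes.
    """
    path = Path(path)
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise ValueError(f"{path}: not parseable as XML: {exc}") from exc
    root = tree.getroot()
    pathway_id = root.get("name") or root.get("title") or path.stem

    entry_genes: dict[str, list[str]] = {}
    for entry in root.iter("entry"):
        if entry.get("type") != "gene":
            continue
        symbols = _entry_symbols(entry)
        if symbols:
            entry_genes[entry.get("id", "")] = symbols

    if not entry_genes:
        logger.warning("%s: no gene entries; returning empty graph", path)
        return PathwayGraph(pathway_id)

    genes: set[str] = {s for syms in entry_genes.values() for s in syms}
    edges: set[tuple[str, str]] = set()
    for rel in root.iter("relation"):
        e1 = entry_genes.get(rel.get("entry1", ""))
        e2 = entry_genes.get(rel.get("entry2", ""))
        if e1 is None or e2 is None:
            continue  # relation touches a non-gene entry
        for a in e1:
            for b in e2:
                if a != b:
                    edges.add((a, b) if a < b else (b, a))
    return PathwayGraph(pathway_id, frozenset(genes), frozenset(edges))
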