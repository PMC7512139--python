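"""Reading and writing directed networks and gene lists.

Networks are held as :class:`networkx.DiGraph` wrapped in a small
container that records what was cleaned at load time.  The pattern
space has a zero diagonal and binary entries, so self-loops are dropped
(with a logged warning) and duplicate edges are collapsed on input.

Supported formats: two-column edge lists (TSV, ``#`` comments), minimal
KEGG KGML (entries and relations only), and plain-text gene lists.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "DirectedNetwork",
    "GeneSet",
    "read_edge_list",
    "read_kgml",
    "read_gene_set",
    "write_edge_list",
]


class NetworkFormatError(ValueError):
    """Malformed or empty network input."""


class EmptyGeneSetError(ValueError):
    """A gene list parsed to nothing."""


@dataclass
class DirectedNetwork:
    """A simple directed graph (no self-loops, no multi-edges)."""

    graph: nx.DiGraph
    dropped_self_loops: int = 0
    collapsed_duplicates: int = 0

    @classmethod
    def from_edges(cls, edges, nodes=()) -> "DirectedNetwork":
        g = nx.DiGraph()
        g.add_nodes_from(nodes)
        dropped = 0
        dup = 0
        for u, v in edges:
            if u == v:
                dropped += 1
                g.add_node(u)
                continue
            if g.has_edge(u, v):
                dup += 1
                continue
            g.add_edge(u, v)
        if dropped:
            logger.warning("dropped %d self-loop(s)", dropped)
        if dup:
            logger.info("collapsed %d duplicate edge(s)", dup)
        return cls(graph=g, dropped_self_loops=dropped, collapsed_duplicates=dup)

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set:
        return set(self.graph.edges)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class GeneSet:
    """A set of gene symbols, e.g. a driver-gene list."""

    labels: frozenset[str] = field(default_factory=frozenset)

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, label) -> bool:
        return label in self.labels


def read_edge_list(path) -> DirectedNetwork:
    """Parse a two-column (source, target) TSV/whitespace edge list.

    Lines starting with ``#`` are comments; extra columns are ignored.
    """
    path = Path(path)
    edges = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) < 2:
                raise NetworkFormatError(
                    f"{path}:{lineno}: expected at least 2 fields, got {len(fields)}"
                )
            edges.append((fields[0], fields[1]))
    if not edges:
        raise NetworkFormatError(f"{path}: no edges found")
    return DirectedNetwork.from_edges(edges)


def write_edge_list(net: DirectedNetwork, path) -> None:
    """Write a network as a two-column TSV edge list (isolates as comments)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# source\ttarget\n")
        for u, v in sorted(net.graph.edges):
            fh.write(f"{u}\t{v}\n")
        for node in sorted(n for n in net.graph.nodes if net.graph.degree(n) == 0):
            fh.write(f"# isolated\t{node}\n")


def _entry_label(entry, expand: bool) -> list[str]:
    """Node label(s) for a KGML entry: the first listed name, or all names
    when ``expand`` is set."""
    names = (entry.get("name") or "").split()
    graphics = entry.find("graphics")
    if graphics is not None and graphics.get("name"):
        display = [s.strip() for s in graphics.get("name").split(",") if s.strip()]
        if display:
            names = display
    if not names:
        names = [f"entry_{entry.get('id')}"]
    return names if expand else [names[0]]


def read_kgml(path, expand_entries: bool = False) -> DirectedNetwork:
    """Parse a KEGG KGML pathway file into a directed network.

    Each ``entry`` becomes one node named by its first listed gene name
    (or one node per name with ``expand_entries``); each ``relation``
    becomes a directed edge entry1 → entry2.  ``group`` entries are
    expanded to their components.  Relation subtypes are ignored; only
    the topology is read.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise NetworkFormatError(f"{path}: not well-formed KGML ({exc})") from exc
    root = tree.getroot()

    labels: dict[str, list[str]] = {}
    groups: dict[str, list[str]] = {}
    for entry in root.findall("entry"):
        eid = entry.get("id")
        if entry.get("type") == "group":
            groups[eid] = [c.get("id") for c in entry.findall("component")]
        else:
            labels[eid] = _entry_label(entry, expand_entries)

    def resolve(eid: str) -> list[str]:
        if eid in groups:
            out: list[str] = []
            for comp in groups[eid]:
                out.extend(resolve(comp))
            return out
        return labels.get(eid, [])

    edges = []
    for rel in root.findall("relation"):
        for src in resolve(rel.get("entry1")):
            for dst in resolve(rel.get("entry2")):
                edges.append((src, dst))
    if not edges:
        logger.warning("%s: KGML file contains no relations", path)
    net = DirectedNetwork.from_edges(
        edges, nodes=[n for names in labels.values() for n in names]
    )
    return net


def read_gene_set(path) -> GeneSet:
    """Parse a plain-text gene list: one symbol per line, ``#`` comments."""
    path = Path(path)
    labels = set()
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            labels.add(line)
    if not labels:
        raise EmptyGeneSetError(f"{path}: no gene symbols found")
    return GeneSet(labels=frozenset(labels))
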