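"""Subgraph census: enumerate and classify all connected k-node induced
subgraphs of a directed network, keeping node identities.

Enumeration uses the ESU scheme (recursive extension over the
undirected support), which visits every connected k-node subset exactly
once without scanning all C(n, k) subsets.  Each subset's induced
submatrix is classified by its canonical pattern id; the stored node
order is the relabeling that realizes the canonical representative, so
genetic elements can be mapped back onto pattern positions.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np

from .network_io import DirectedNetwork
from .patterns import PatternCatalog, PatternId, encode_bits, enumerate_patterns

__all__ = [
    "SubgraphOccurrence",
    "SubgraphCensus",
    "connected_subsets",
    "census",
    "node_coverage",
    "frequency_distribution",
]


class EmptyCensusError(ValueError):
    """Statistic undefined on an empty census or network."""


@dataclass(frozen=True)
class SubgraphOccurrence:
    """One placement of a pattern: node labels ordered to realize the
    canonical representative matrix."""

    pattern: PatternId
    nodes: tuple


@dataclass
class SubgraphCensus:
    """All connected k-node induced subgraphs of one network, by pattern."""

    k: int
    counts: dict[PatternId, int] = field(default_factory=dict)
    occurrences: dict[PatternId, list[SubgraphOccurrence]] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def covered_nodes(self) -> set:
        return {
            n for occs in self.occurrences.values() for o in occs for n in o.nodes
        }


def connected_subsets(net: DirectedNetwork, k: int) -> Iterator[tuple]:
    """Yield each weakly connected k-node subset exactly once (ESU).

    Nodes are handled in a fixed arbitrary order; each subset grows only
    through exclusive neighbors with a higher order index, which
    guarantees uniqueness.
    """
    if k < 1:
        raise ValueError("subset size must be >= 1")
    g = net.graph
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    undirected = {v: set(g.predecessors(v)) | set(g.successors(v)) for v in nodes}

    def extend(subgraph: list, extension: set, neighborhood: set, root_idx: int):
        if len(subgraph) == k:
            yield tuple(subgraph)
            return
        ext = set(extension)
        while ext:
            w = ext.pop()
            # exclusive neighbors of w: not adjacent to any current node
            excl = {
                u
                for u in undirected[w]
                if index[u] > root_idx and u not in neighborhood and u != w
            }
            yield from extend(
                subgraph + [w], ext | excl, neighborhood | {w} | undirected[w], root_idx
            )

    for v in nodes:
        vi = index[v]
        initial = {u for u in undirected[v] if index[u] > vi}
        yield from extend([v], initial, {v} | undirected[v], vi)


def _induced_matrix(net: DirectedNetwork, subset: tuple) -> np.ndarray:
    g = net.graph
    k = len(subset)
    a = np.zeros((k, k), dtype=np.int64)
    for i, u in enumerate(subset):
        for j, v in enumerate(subset):
            if i != j and g.has_edge(u, v):
                a[i, j] = 1
    return a


def _classify(a: np.ndarray, subset: tuple) -> SubgraphOccurrence:
    """Canonical id of an induced matrix plus the realizing node order.

    Among node orderings achieving the minimal encoding, the
    lexicographically smallest label tuple is stored.
    """
    k = a.shape[0]
    best_code = None
    best_nodes = None
    for perm in itertools.permutations(range(k)):
        # position p of the representative is filled by subset node
        # inv[p]; build that ordering and encode it
        ordered = np.empty(k, dtype=np.int64)
        for i, p in enumerate(perm):
            ordered[p] = i
        code = encode_bits(a[np.ix_(ordered, ordered)])
        nodes = tuple(subset[i] for i in ordered)
        if best_code is None or code < best_code or (
            code == best_code and nodes < best_nodes
        ):
            best_code, best_nodes = code, nodes
    return SubgraphOccurrence(pattern=PatternId(k=k, id=best_code), nodes=best_nodes)


def census(net: DirectedNetwork, k: int, with_nodes: bool = True) -> SubgraphCensus:
    """Classify every connected k-node induced subgraph of a network."""
    result = SubgraphCensus(k=k)
    for subset in connected_subsets(net, k):
        a = _induced_matrix(net, subset)
        occ = _classify(a, subset)
        result.counts[occ.pattern] = result.counts.get(occ.pattern, 0) + 1
        if with_nodes:
            result.occurrences.setdefault(occ.pattern, []).append(occ)
    return result


def node_coverage(
    census3: SubgraphCensus, census4: SubgraphCensus, net: DirectedNetwork
) -> dict[str, float]:
    """Fraction of network nodes embedded in ≥1 occurrence, per size and
    jointly (nodes present at both the 3- and 4-node level)."""
    n = net.n_nodes
    if n == 0:
        raise EmptyCensusError("coverage undefined for an empty network")
    c3 = census3.covered_nodes()
    c4 = census4.covered_nodes()
    return {
        "k3": len(c3) / n,
        "k4": len(c4) / n,
        "both": len(c3 & c4) / n,
    }


def frequency_distribution(
    c: SubgraphCensus, catalog: PatternCatalog | None = None
) -> dict[PatternId, float]:
    """Occurrence counts normalized to one over the full pattern catalog
    (absent patterns get probability 0)."""
    if c.total == 0:
        raise EmptyCensusError("frequency distribution undefined for empty census")
    catalog = catalog or enumerate_patterns(c.k)
    return {pid: c.counts.get(pid, 0) / c.total for pid in catalog}
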