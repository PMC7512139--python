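"""Synthetic directed networks with controllable density and reciprocity.

Real inputs to the pipeline are regulatory networks of up to a few
hundred genes; the generator emulates them as dyad-level random
digraphs.  For every unordered node pair one of four outcomes is drawn
— no edge, i→j, j→i, or a mutual dyad — with probabilities chosen so
that the expected edge density is ``p_edge`` and the expected
correlation reciprocity approaches ``target_r``: writing p = p_edge,
the mutual-dyad probability is m = r·p(1−p) + p², which makes the
population value of the Garlaschelli–Loffredo r equal to the target.
Per-arc independent sampling corresponds to m = p² (r = 0); dyad-level
sampling is required to reach any other target.

Planted-pattern networks provide exact census ground truth: requested
pattern instances are laid down on disjoint node sets, so each instance
contributes exactly one occurrence of its pattern and nothing else.
Optional background dyads are extra two-node components; being smaller
than any censused subgraph size (k ≥ 3) they cannot create or join
occurrences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .census import SubgraphOccurrence
from .network_io import DirectedNetwork
from .patterns import PatternId, decode_id

__all__ = ["SynthConfig", "random_digraph", "planted_pattern_network"]


class InfeasibleConfigError(ValueError):
    """No dyad distribution realizes the requested (p_edge, target_r)."""


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; ``seed`` fixes the full output."""

    n: int = 50
    p_edge: float = 0.1
    target_r: float | None = None
    seed: int = 0
    planted: tuple[tuple[PatternId, int], ...] = ()
    background_pairs: int = 0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 nodes")
        if not 0 <= self.p_edge <= 1:
            raise ValueError("p_edge must be in [0, 1]")
        if self.target_r is not None and not -1 <= self.target_r <= 1:
            raise ValueError("target_r must be in [-1, 1]")


def _dyad_probabilities(p: float, r: float | None) -> tuple[float, float, float]:
    """(P(no edge), P(single arc), P(mutual)) per unordered pair."""
    if r is None:
        m = p * p  # independent arcs
    else:
        m = r * p * (1 - p) + p * p
    single = 2 * (p - m)  # both orientations together
    none = 1 - single - m
    if m < -1e-12 or single < -1e-12 or none < -1e-12 or m > min(1.0, p) + 1e-12:
        raise InfeasibleConfigError(
            f"no dyad distribution with p_edge={p}, target_r={r}"
        )
    return max(none, 0.0), max(single, 0.0), max(m, 0.0)


def random_digraph(cfg: SynthConfig) -> DirectedNetwork:
    """Dyad-level Erdős–Rényi-style digraph with tunable reciprocity."""
    none, single, mutual = _dyad_probabilities(cfg.p_edge, cfg.target_r)
    rng = np.random.default_rng(cfg.seed)
    labels = [f"g{i:04d}" for i in range(cfg.n)]
    edges = []
    for i in range(cfg.n):
        for j in range(i + 1, cfg.n):
            u = rng.random()
            if u < mutual:
                edges.append((labels[i], labels[j]))
                edges.append((labels[j], labels[i]))
            elif u < mutual + single:
                if rng.random() < 0.5:
                    edges.append((labels[i], labels[j]))
                else:
                    edges.append((labels[j], labels[i]))
    return DirectedNetwork.from_edges(edges, nodes=labels)


def planted_pattern_network(
    cfg: SynthConfig,
) -> tuple[DirectedNetwork, list[SubgraphOccurrence]]:
    """Disjoint union of requested pattern instances with ground truth.

    Returns the network and the exact list of occurrences it contains
    at each planted size (one per planted instance).  Background dyads,
    if requested, are added as separate two-node components.
    """
    if not cfg.planted:
        raise ValueError("planted list must be non-empty")
    edges = []
    truth: list[SubgraphOccurrence] = []
    counter = 0
    for pid, count in cfg.planted:
        rep = decode_id(pid.id, pid.k)
        for _ in range(count):
            labels = [f"p{counter:04d}_{t}" for t in range(pid.k)]
            counter += 1
            for i in range(pid.k):
                for j in range(pid.k):
                    if rep[i, j]:
                        edges.append((labels[i], labels[j]))
            truth.append(SubgraphOccurrence(pattern=pid, nodes=tuple(labels)))
    for b in range(cfg.background_pairs):
        edges.append((f"bg{b}_0", f"bg{b}_1"))
    return DirectedNetwork.from_edges(edges), truth
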