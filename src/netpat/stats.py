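"""Entropy of subgraph frequency distributions, rank statistics, and
driver-gene odds-ratio enrichment.

The Shannon entropy H = −Σ p log₂ p of a pattern frequency
distribution measures how evenly a network uses the available
patterns; it is normalized by log₂ of the catalog size (13 for 3-node,
199 for 4-node patterns) so H_R ∈ [0, 1].  Enrichment of a gene set in
the *subgraph module* — the nodes embedded in at least one 3- or
4-node occurrence — is quantified by the odds ratio of the 2×2 table

                    module   non-module
    drivers            a         b
    non-drivers        c         d

OR = (a·d)/(b·c), with a pseudo-count applied to every cell when any
cell is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .census import SubgraphCensus
from .network_io import DirectedNetwork, GeneSet
from .patterns import CATALOG_SIZES

__all__ = [
    "shannon_entropy",
    "normalized_entropy",
    "min_rank",
    "spearman_rank_correlation",
    "ContingencyTable",
    "contingency_table",
    "odds_ratio",
]


class UndefinedStatisticError(ValueError):
    """The requested statistic is undefined on this input."""


def shannon_entropy(dist: Mapping) -> float:
    """H = −Σ p log₂ p in bits, with 0·log 0 = 0."""
    probs = np.asarray(list(dist.values()), dtype=float)
    if probs.size == 0 or probs.min() < 0 or not math.isclose(
        probs.sum(), 1.0, abs_tol=1e-9
    ):
        raise UndefinedStatisticError("input is not a probability distribution")
    nz = probs[probs > 0]
    return float(-(nz * np.log2(nz)).sum())


def normalized_entropy(dist: Mapping, k: int) -> float:
    """Entropy divided by log₂(catalog size) for k ∈ {3, 4}; in [0, 1]."""
    if k not in (3, 4):
        raise UndefinedStatisticError(f"normalized entropy defined for k=3,4, got {k}")
    return shannon_entropy(dist) / math.log2(CATALOG_SIZES[k])


def min_rank(values: Sequence[float], ascending: bool = True) -> list[int]:
    """Competition ("minimum") ranks: rank(v) = 1 + #strictly better."""
    if len(values) == 0:
        raise UndefinedStatisticError("cannot rank an empty list")
    vals = list(values)
    if ascending:
        return [1 + sum(1 for w in vals if w < v) for v in vals]
    return [1 + sum(1 for w in vals if w > v) for v in vals]


def spearman_rank_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation of two rank vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise UndefinedStatisticError("need two equal-length vectors of length >= 3")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for zero variance")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass(frozen=True)
class ContingencyTable:
    """Driver/non-driver × subgraph-module/non-module gene counts."""

    a: int  # drivers inside the subgraph module
    b: int  # drivers outside
    c: int  # non-drivers inside
    d: int  # non-drivers outside

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def contingency_table(
    net: DirectedNetwork,
    census3: SubgraphCensus,
    census4: SubgraphCensus,
    drivers: GeneSet,
) -> ContingencyTable:
    """Cross-classify network genes by driver status and membership in
    the subgraph module (nodes in any 3- or 4-node occurrence)."""
    nodes = set(net.nodes)
    if not nodes:
        raise UndefinedStatisticError("empty network")
    module = (census3.covered_nodes() | census4.covered_nodes()) & nodes
    a = sum(1 for n in module if n in drivers)
    c = len(module) - a
    outside = nodes - module
    b = sum(1 for n in outside if n in drivers)
    d = len(outside) - b
    return ContingencyTable(a=a, b=b, c=c, d=d)


def odds_ratio(t: ContingencyTable, pseudo: float = 1.0) -> float:
    """OR = (a·d)/(b·c); ``pseudo`` is added to every cell iff any cell
    is zero (otherwise the ratio is undefined or degenerate)."""
    if pseudo < 0:
        raise ValueError("pseudo-count must be >= 0")
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        a, b, c, d = a + pseudo, b + pseudo, c + pseudo, d + pseudo
    if b * c == 0:
        raise UndefinedStatisticError("odds ratio undefined: zero denominator")
    return (a * d) / (b * c)
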