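"""Functional-subgraph containment between patterns and irreducibility.

A *functional subgraph* of a pattern is obtained by choosing a node
subset and any subset of the induced edges such that the result spans
the chosen nodes and is weakly connected (the structural/functional
motif distinction of Sporns & Kötter).  A pattern with no functional
subgraph of its own size is *irreducible*: removing any single edge
disconnects it, which is equivalent to having exactly k−1 edges (a tree
support).
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np
import pandas as pd

from .patterns import (
    PatternCatalog,
    PatternId,
    canonical_id,
    decode_id,
    encode_bits,
    is_weakly_connected,
)


@lru_cache(maxsize=None)
def _canonical_of_code(code: int, k: int) -> PatternId:
    return canonical_id(decode_id(code, k))

__all__ = [
    "functional_subgraphs",
    "irreducible_patterns",
    "containment_table",
]


def functional_subgraphs(p: PatternId, k_sub: int) -> set[PatternId]:
    """All pattern ids realized by spanning connected edge-subsets of a
    node subset of ``p``; ``p`` itself is excluded at its own size."""
    if k_sub > p.k or k_sub < 2:
        raise ValueError(f"k_sub must be in [2, {p.k}]")
    a = decode_id(p.id, p.k)
    found: set[PatternId] = set()
    for subset in itertools.combinations(range(p.k), k_sub):
        sub = a[np.ix_(subset, subset)]
        edges = list(zip(*np.nonzero(sub)))
        for r in range(1, len(edges) + 1):
            for chosen in itertools.combinations(edges, r):
                m = np.zeros((k_sub, k_sub), dtype=np.int64)
                for i, j in chosen:
                    m[i, j] = 1
                if is_weakly_connected(m):
                    found.add(_canonical_of_code(encode_bits(m), k_sub))
    if k_sub == p.k:
        found.discard(p)
    return found


def irreducible_patterns(catalog: PatternCatalog) -> set[PatternId]:
    """Patterns with no same-size functional subgraph."""
    return {p for p in catalog if not functional_subgraphs(p, p.k)}


def containment_table(
    catalog_k: PatternCatalog, catalog_sub: PatternCatalog
) -> pd.DataFrame:
    """Binary container × contained matrix of functional-subgraph
    presence (rows: size-k patterns, columns: size-k′ patterns)."""
    if catalog_sub.k > catalog_k.k:
        raise ValueError("contained catalog must not be larger than container")
    rows = {}
    cols = catalog_sub.ids
    for p in catalog_k:
        present = {q.id for q in functional_subgraphs(p, catalog_sub.k)}
        rows[p.id] = [1 if c in present else 0 for c in cols]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
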