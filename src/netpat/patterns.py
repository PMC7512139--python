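"""Canonical catalog of small directed graph patterns.

A *pattern* is an isomorphism class of weakly connected, self-loop-free,
binary directed graphs on k nodes (mutual arcs allowed, multi-arcs not).
Each labeled digraph is encoded as a decimal by reading its adjacency
matrix row-major, most-significant bit first (bit of entry (1,1) is the
MSB); the canonical id of a pattern is the minimum encoding over all k!
node relabelings.  Under this convention id 38 is the feed-forward loop,
id 6 the single-input module, id 98 the 3-cycle and id 238 the complete
3-node digraph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

__all__ = [
    "PatternId",
    "PatternCatalog",
    "CATALOG_SIZES",
    "encode_bits",
    "decode_id",
    "canonical_id",
    "is_weakly_connected",
    "enumerate_patterns",
]

#: number of weakly connected k-node patterns, k = 2..5
CATALOG_SIZES = {2: 2, 3: 13, 4: 199, 5: 9364}

MIN_K, MAX_K = 2, 5


class InvalidMatrixError(ValueError):
    """Adjacency matrix violates the pattern-space invariants."""


class NotConnectedError(ValueError):
    """Operation requires a weakly connected digraph."""


class UnsupportedSizeError(ValueError):
    """Node count outside the supported catalog range."""


@dataclass(frozen=True, order=True)
class PatternId:
    """Name of one isomorphism class: node count plus canonical decimal id."""

    k: int
    id: int

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PatternId(k={self.k}, id={self.id})"


@dataclass
class PatternCatalog:
    """All weakly connected k-node patterns, one minimal representative each."""

    k: int
    patterns: list[PatternId] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.patterns)

    def __iter__(self) -> Iterator[PatternId]:
        return iter(self.patterns)

    @property
    def ids(self) -> list[int]:
        return [p.id for p in self.patterns]

    def representative(self, pid: PatternId | int) -> np.ndarray:
        i = pid.id if isinstance(pid, PatternId) else pid
        return decode_id(i, self.k)


def _as_matrix(m) -> np.ndarray:
    a = np.asarray(m, dtype=np.int64)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise InvalidMatrixError(f"adjacency matrix must be square, got {a.shape}")
    if not np.isin(a, (0, 1)).all():
        raise InvalidMatrixError("adjacency entries must be 0 or 1")
    if np.trace(a) != 0:
        raise InvalidMatrixError("self-loops (nonzero diagonal) are not allowed")
    return a


def encode_bits(m) -> int:
    """Row-major decimal encoding of a zero-diagonal adjacency matrix.

    Entry (i, j) (1-based) contributes ``2**(k*k - (k*(i-1) + j))``; the
    (1,1) entry is the most significant bit.
    """
    a = _as_matrix(m)
    k = a.shape[0]
    code = 0
    for bit in a.ravel():
        code = (code << 1) | int(bit)
    assert code < (1 << (k * k))
    return code


def decode_id(code: int, k: int) -> np.ndarray:
    """Inverse of :func:`encode_bits`: decimal id -> k×k adjacency matrix."""
    if not 0 <= code < (1 << (k * k)):
        raise InvalidMatrixError(f"id {code} out of range for k={k}")
    bits = [(code >> (k * k - 1 - t)) & 1 for t in range(k * k)]
    a = np.array(bits, dtype=np.int64).reshape(k, k)
    if np.trace(a) != 0:
        raise InvalidMatrixError(f"id {code} has a diagonal bit set (self-loop)")
    return a


def is_weakly_connected(m) -> bool:
    """True iff the undirected support of the digraph is connected."""
    a = _as_matrix(m)
    k = a.shape[0]
    if k == 0:
        return False
    sym = a | a.T
    seen = np.zeros(k, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        u = stack.pop()
        for v in np.flatnonzero(sym[u]):
            if not seen[v]:
                seen[v] = True
                stack.append(int(v))
    return bool(seen.all())


def canonical_id(m) -> PatternId:
    """Minimum encoding over all node relabelings of a connected pattern."""
    a = _as_matrix(m)
    if not is_weakly_connected(a):
        raise NotConnectedError("pattern must be weakly connected")
    k = a.shape[0]
    best = min(
        encode_bits(a[np.ix_(perm, perm)])
        for perm in itertools.permutations(range(k))
    )
    return PatternId(k=k, id=best)


def _offdiag_bit_positions(k: int) -> list[int]:
    """MSB-first bit positions (exponents) of the off-diagonal entries."""
    return [
        k * k - 1 - (k * i + j)
        for i in range(k)
        for j in range(k)
        if i != j
    ]


def _permutation_bit_tables(k: int) -> list[list[tuple[int, int]]]:
    """For each node permutation, (source-exponent, target-exponent) pairs.

    Relabeling by ``perm`` moves entry (i, j) to (perm[i], perm[j]); the
    tables let the whole orbit of a code be computed with shifts and masks.
    """
    tables = []
    for perm in itertools.permutations(range(k)):
        pairs = []
        for i in range(k):
            for j in range(k):
                if i == j:
                    continue
                src = k * k - 1 - (k * i + j)
                dst = k * k - 1 - (k * perm[i] + perm[j])
                pairs.append((src, dst))
        tables.append(pairs)
    return tables


def _connected_codes_mask(k: int, codes: np.ndarray) -> np.ndarray:
    """Vectorized weak-connectivity test over an array of encodings.

    Runs k-1 rounds of neighborhood expansion on node bitmasks derived
    from the symmetrized adjacency bits.
    """
    n = codes.shape[0]
    # adj[v] = bitmask over nodes adjacent (either direction) to v
    adj = np.zeros((k, n), dtype=np.uint32)
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            bit = ((codes >> np.uint32(k * k - 1 - (k * i + j))) & 1).astype(np.uint32)
            adj[i] |= bit << np.uint32(j)
            adj[j] |= bit << np.uint32(i)
    reach = np.full(n, 1, dtype=np.uint32)  # start from node 0
    for _ in range(k - 1):
        grown = reach.copy()
        for v in range(k):
            has_v = ((reach >> np.uint32(v)) & 1).astype(bool)
            grown[has_v] |= adj[v][has_v]
        reach = grown
    full = np.uint32((1 << k) - 1)
    return reach == full


def enumerate_patterns(k: int) -> PatternCatalog:
    """Exhaustively enumerate all weakly connected k-node patterns.

    Scans every assignment of the k(k-1) off-diagonal bits, canonicalizes
    each labeled digraph with per-permutation bit tables (vectorized over
    the whole code space), keeps weakly connected classes and returns one
    minimal representative per class, sorted by id.
    """
    if not MIN_K <= k <= MAX_K:
        raise UnsupportedSizeError(f"catalog supports k in [{MIN_K}, {MAX_K}], got {k}")

    positions = _offdiag_bit_positions(k)
    nbits = len(positions)
    n = 1 << nbits

    # expand compact off-diagonal indices into full k*k-bit encodings
    compact = np.arange(n, dtype=np.uint32)
    codes = np.zeros(n, dtype=np.uint32)
    for t, pos in enumerate(positions):
        codes |= ((compact >> np.uint32(nbits - 1 - t)) & 1) << np.uint32(pos)

    canon = codes.copy()
    for pairs in _permutation_bit_tables(k):
        permuted = np.zeros(n, dtype=np.uint32)
        for src, dst in pairs:
            permuted |= ((codes >> np.uint32(src)) & 1) << np.uint32(dst)
        np.minimum(canon, permuted, out=canon)

    is_rep = canon == codes
    connected = _connected_codes_mask(k, codes[is_rep])
    rep_codes = np.sort(codes[is_rep][connected])
    patterns = [PatternId(k=k, id=int(c)) for c in rep_codes]
    return PatternCatalog(k=k, patterns=patterns)
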