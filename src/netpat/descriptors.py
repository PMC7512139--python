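"""Non-spectral pattern descriptors: reciprocity, cyclomatic and
algorithmic complexity, and the combined per-pattern descriptor table.

Reciprocity comes in two flavors.  The traditional reciprocity R is the
fraction of arcs that belong to mutual dyads, R = L↔/L.  The
correlation reciprocity r (Garlaschelli–Loffredo) is the Pearson-style
correlation between mirror off-diagonal adjacency entries,

    r = Σ_{i≠j} (a_ij − ā)(a_ji − ā) / Σ_{i≠j} (a_ij − ā)²,
    ā = Σ_{i≠j} a_ij / (N(N−1)),

so r > 0 signals a bidirectional tendency and r < 0 a purely in- or
out-oriented structure.  Cyclomatic complexity is CC = e − N + 2P with P
the number of exit nodes (out-degree zero), the control-flow-graph
metric applied to a regulatory pattern.  Kolmogorov complexity is
estimated by a pluggable backend; the default is a context-tree-
weighting universal code over the adjacency bit string.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from functools import lru_cache
from typing import Mapping, Protocol, Sequence

import numpy as np

from .patterns import PatternCatalog, PatternId, _as_matrix
from .spectral import EnergyVector, energy_vector, spectrum_of

__all__ = [
    "reciprocity_traditional",
    "reciprocity_r",
    "cyclomatic_complexity",
    "kolmogorov_complexity",
    "ComplexityBackend",
    "CTWBackend",
    "DescriptorTable",
    "build_descriptor_table",
]


class UndefinedReciprocityError(ValueError):
    """Reciprocity is undefined for an edgeless graph."""


def reciprocity_traditional(m) -> float:
    """Fraction of arcs in mutual dyads: R = L↔/L."""
    a = _as_matrix(m)
    e = int(a.sum())
    if e == 0:
        raise UndefinedReciprocityError("reciprocity undefined for e = 0")
    mutual = int((a & a.T).sum())  # ordered arcs with a reversed partner
    return mutual / e


def reciprocity_r(m) -> float:
    """Correlation reciprocity over off-diagonal entry pairs.

    Degenerate case: on the complete digraph every off-diagonal entry
    equals ā, the defining ratio is 0/0 and r is taken to be 1 (the edge
    set is exactly symmetric).
    """
    a = _as_matrix(m)
    n = a.shape[0]
    e = int(a.sum())
    if e == 0:
        raise UndefinedReciprocityError("reciprocity undefined for e = 0")
    off = ~np.eye(n, dtype=bool)
    abar = a[off].mean()
    dev = a[off] - abar
    denom = (dev**2).sum()
    if denom == 0:
        return 1.0
    num = ((a - abar) * (a.T - abar))[off].sum()
    return float(num / denom)


def cyclomatic_complexity(m) -> int:
    """CC = e − N + 2P, P = number of out-degree-zero (exit) nodes."""
    a = _as_matrix(m)
    e = int(a.sum())
    n = a.shape[0]
    sinks = int((a.sum(axis=1) == 0).sum())
    return e - n + 2 * sinks


# ---------------------------------------------------------------------------
# algorithmic complexity


class ComplexityBackend(Protocol):
    """Interface for bit-string algorithmic-complexity estimators."""

    name: str
    version: str

    def complexity(self, bits: Sequence[int]) -> float:
        """Estimated complexity of a binary string, in bits."""
        ...


class UnsupportedStringError(ValueError):
    """Bit string outside the backend's supported length range."""


@lru_cache(maxsize=None)
def _kt_probability(c0: int, c1: int) -> Fraction:
    """Krichevsky–Trofimov estimator for a (c0, c1) count pair."""
    p = Fraction(1)
    a = b = 0
    for _ in range(c0):
        p *= Fraction(2 * a + 1, 2 * (a + b + 1))
        a += 1
    for _ in range(c1):
        p *= Fraction(2 * b + 1, 2 * (a + b + 1))
        b += 1
    return p


@dataclass(frozen=True)
class CTWBackend:
    """Context-tree-weighting universal code as a complexity estimator.

    The complexity of a bit string is the ideal code length −log₂ P(s)
    under the CTW mixture over all binary tree sources up to ``depth``,
    with Krichevsky–Trofimov leaf estimators and a zero-padded past.
    Exact rational arithmetic makes the estimate fully deterministic.
    """

    depth: int = 6
    max_length: int = 4096
    name: str = "ctw-kt"
    version: str = "1.0"

    def complexity(self, bits: Sequence[int]) -> float:
        bits = [int(b) for b in bits]
        if not bits or len(bits) > self.max_length:
            raise UnsupportedStringError(
                f"string length {len(bits)} outside (0, {self.max_length}]"
            )
        if any(b not in (0, 1) for b in bits):
            raise ValueError("input must be a binary string")
        counts: dict[tuple[int, ...], list[int]] = {}
        padded = [0] * self.depth + bits
        for t, b in enumerate(bits):
            ctx = tuple(padded[t : t + self.depth])
            for d in range(self.depth + 1):
                key = ctx[len(ctx) - d :]
                counts.setdefault(key, [0, 0])[b] += 1

        def weighted(suffix: tuple[int, ...]) -> Fraction:
            c0, c1 = counts.get(suffix, (0, 0))
            pe = _kt_probability(c0, c1)
            if len(suffix) == self.depth or (c0 + c1) == 0:
                return pe
            half = Fraction(1, 2)
            return half * pe + half * weighted((0,) + suffix) * weighted((1,) + suffix)

        return -math.log2(weighted(()))


DEFAULT_BACKEND = CTWBackend()


def matrix_bit_string(m) -> list[int]:
    """Serialize an adjacency matrix as its row-major bits followed by
    its column-major bits.

    The doubled scan exposes both row and column regularities to a 1-D
    code, which removes the complexity collisions a single row-major
    scan leaves between structurally different patterns.
    """
    a = _as_matrix(m)
    return [int(b) for b in a.ravel()] + [int(b) for b in a.T.ravel()]


def kolmogorov_complexity(m, backend: ComplexityBackend | None = None) -> float:
    """Algorithmic-complexity estimate of a pattern, in bits."""
    backend = backend or DEFAULT_BACKEND
    return backend.complexity(matrix_bit_string(m))


# ---------------------------------------------------------------------------
# combined descriptor table


@dataclass
class DescriptorTable:
    """Per-pattern descriptors for one catalog: nine energies, R, r, CC, KC."""

    catalog: PatternCatalog
    energy: Mapping[PatternId, EnergyVector]
    R: Mapping[PatternId, float]
    r: Mapping[PatternId, float]
    cc: Mapping[PatternId, int]
    kc: Mapping[PatternId, float]
    kc_backend: str = "ctw-kt 1.0"
    _spectra: dict = field(default_factory=dict, repr=False)

    def spectrum(self, pid: PatternId, kind: str) -> np.ndarray:
        key = (pid, kind)
        if key not in self._spectra:
            self._spectra[key] = spectrum_of(self.catalog.representative(pid), kind)
        return self._spectra[key]

    @property
    def pattern_ids(self) -> list[PatternId]:
        return list(self.catalog)


def build_descriptor_table(
    catalog: PatternCatalog, backend: ComplexityBackend | None = None
) -> DescriptorTable:
    backend = backend or DEFAULT_BACKEND
    energy, R, r, cc, kc = {}, {}, {}, {}, {}
    for pid in catalog:
        a = catalog.representative(pid)
        energy[pid] = energy_vector(a)
        R[pid] = reciprocity_traditional(a)
        r[pid] = reciprocity_r(a)
        cc[pid] = cyclomatic_complexity(a)
        kc[pid] = backend.complexity(matrix_bit_string(a))
    return DescriptorTable(
        catalog=catalog,
        energy=energy,
        R=R,
        r=r,
        cc=cc,
        kc=kc,
        kc_backend=f"{backend.name} {backend.version}",
    )
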