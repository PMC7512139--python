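"""Spectral descriptors of directed patterns: nine graph energies.

For a digraph with adjacency matrix A, total-degree diagonal matrix D
(in-degree plus out-degree), Laplacian L = D - A and signless Laplacian
Q = D + A, the descriptors are:

* graph energy          E  = Σ|α_i|,  α over eigenvalues of A
* Laplacian energy      LE = Σ|β_i| - 2e/n,  β over eigenvalues of L
* signless Lap. energy  QE = Σ|γ_i| - 2e/n,  γ over eigenvalues of Q
* generalized energies  for M, N in {A, L, Q}: Σ_i sqrt(|λ_i(M Nᵗ)|),
  which for M = N is the sum of the singular values of M.

Eigenvalue moduli are used throughout, so complex spectra (asymmetric
patterns such as the 3-cycle) are handled uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .patterns import PatternCatalog, PatternId, _as_matrix

__all__ = [
    "EnergyVector",
    "ENERGY_NAMES",
    "degree_matrix",
    "graph_energy",
    "laplacian_energy",
    "signless_laplacian_energy",
    "generalized_energy",
    "spectrum_of",
    "energy_vector",
    "energy_table",
    "energy_bounds",
]

ENERGY_NAMES = ("E", "LE", "QE", "AAt", "LLt", "QQt", "ALt", "AQt", "LQt")

#: matrix-product spectra accepted by :func:`spectrum_of`
SPECTRUM_KINDS = ("A", "L", "Q", "AAt", "LLt", "QQt", "ALt", "AQt", "LQt")


@dataclass(frozen=True)
class EnergyVector:
    """The nine energies of one pattern (dimensionless, all ≥ 0)."""

    E: float
    LE: float
    QE: float
    AAt: float
    LLt: float
    QQt: float
    ALt: float
    AQt: float
    LQt: float

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, n) for n in ENERGY_NAMES)


def degree_matrix(m) -> np.ndarray:
    """Diagonal matrix of total degrees (in-degree + out-degree)."""
    a = _as_matrix(m)
    return np.diag(a.sum(axis=0) + a.sum(axis=1))


def _base_matrix(a: np.ndarray, which: str) -> np.ndarray:
    d = degree_matrix(a)
    if which == "A":
        return a.astype(float)
    if which == "L":
        return (d - a).astype(float)
    if which == "Q":
        return (d + a).astype(float)
    raise ValueError(f"unknown base matrix {which!r}; expected A, L or Q")


def _order_spectrum(values: np.ndarray) -> np.ndarray:
    """Descending real part, ties broken by descending imaginary part."""
    idx = np.lexsort((-values.imag, -values.real))
    return values[idx]


def spectrum_of(m, which: str = "A") -> np.ndarray:
    """Canonically ordered eigenvalues of A, L, Q or a product M·Nᵗ."""
    a = _as_matrix(m)
    if which in ("A", "L", "Q"):
        mat = _base_matrix(a, which)
    elif which in SPECTRUM_KINDS:
        left = _base_matrix(a, which[0])
        right = _base_matrix(a, which[1])
        mat = left @ right.T
    else:
        raise ValueError(f"unknown spectrum kind {which!r}")
    return _order_spectrum(np.linalg.eigvals(mat))


def graph_energy(m) -> float:
    """Sum of the moduli of the adjacency eigenvalues."""
    a = _as_matrix(m)
    return float(np.abs(np.linalg.eigvals(a.astype(float))).sum())


def _shifted_energy(a: np.ndarray, which: str) -> float:
    e = int(a.sum())
    n = a.shape[0]
    vals = np.linalg.eigvals(_base_matrix(a, which))
    return float(np.abs(vals).sum() - 2.0 * e / n)


def laplacian_energy(m) -> float:
    """Σ|eigenvalues of L| − 2e/n with L = D − A."""
    return _shifted_energy(_as_matrix(m), "L")


def signless_laplacian_energy(m) -> float:
    """Σ|eigenvalues of Q| − 2e/n with Q = D + A."""
    return _shifted_energy(_as_matrix(m), "Q")


def generalized_energy(m, left: str = "A", right: str = "A") -> float:
    """Σ sqrt(|λ_i|) over eigenvalues of M·Nᵗ, M/N drawn from {A, L, Q}.

    For left == right this is the Schatten 1-norm (sum of singular
    values) of M; the asymmetric pairs extend that definition.
    """
    a = _as_matrix(m)
    if left not in ("A", "L", "Q") or right not in ("A", "L", "Q"):
        raise ValueError(f"unsupported pair ({left!r}, {right!r})")
    prod = _base_matrix(a, left) @ _base_matrix(a, right).T
    vals = np.linalg.eigvals(prod)
    return float(np.sqrt(np.abs(vals)).sum())


def energy_vector(m) -> EnergyVector:
    """All nine energies of one pattern."""
    a = _as_matrix(m)
    return EnergyVector(
        E=graph_energy(a),
        LE=laplacian_energy(a),
        QE=signless_laplacian_energy(a),
        AAt=generalized_energy(a, "A", "A"),
        LLt=generalized_energy(a, "L", "L"),
        QQt=generalized_energy(a, "Q", "Q"),
        ALt=generalized_energy(a, "A", "L"),
        AQt=generalized_energy(a, "A", "Q"),
        LQt=generalized_energy(a, "L", "Q"),
    )


def energy_table(catalog: PatternCatalog) -> dict[PatternId, EnergyVector]:
    """Nine-energy table over a whole catalog, keyed by pattern id."""
    return {p: energy_vector(catalog.representative(p)) for p in catalog}


def energy_bounds(
    table: Mapping[PatternId, EnergyVector], which: str
) -> tuple[float, float, float | None]:
    """(min, max, max/min) of one energy over a table; ratio None if min=0."""
    if not table:
        raise ValueError("energy table is empty")
    values = [ev[which] for ev in table.values()]
    lo, hi = min(values), max(values)
    ratio = None if lo == 0 else hi / lo
    return lo, hi, ratio
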