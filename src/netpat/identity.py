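"""Minimal unique-identifier search for patterns.

Many descriptors are degenerate: distinct patterns can share a graph
energy (equienergetic pairs) or even a full spectrum.  This module
partitions a catalog by equality of a chosen descriptor combination,
counts how many patterns become distinguishable, and greedily grows a
minimal identifying key.

Descriptor components are named: one of the nine energies ("E", "LE",
"QE", "AAt", "LLt", "QQt", "ALt", "AQt", "LQt"), "r" (correlation
reciprocity), "CC" (cyclomatic complexity), or "spectrum:<kind>" (the
canonically ordered eigenvalues of the named matrix or matrix product).

Case presets follow the unique-identifier analysis: Case A uses the
energy alone, Case B adds r and CC, Case C further adds the spectrum of
the same matrix product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .descriptors import DescriptorTable
from .patterns import PatternId
from .spectral import ENERGY_NAMES

__all__ = [
    "DescriptorKey",
    "descriptor_classes",
    "distinguishability_count",
    "greedy_minimal_set",
    "case_key",
]


@dataclass
class DescriptorKey:
    """An ordered list of descriptor components plus a float tolerance."""

    components: list[str] = field(default_factory=list)
    tolerance: float = 1e-6

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


def _component_value(table: DescriptorTable, pid: PatternId, comp: str):
    if comp in ENERGY_NAMES:
        return table.energy[pid][comp]
    if comp == "r":
        return table.r[pid]
    if comp == "CC":
        return float(table.cc[pid])
    if comp == "R":
        return table.R[pid]
    if comp == "KC":
        return table.kc[pid]
    if comp.startswith("spectrum:"):
        return table.spectrum(pid, comp.split(":", 1)[1])
    raise ValueError(f"unknown descriptor component {comp!r}")


def _values_equal(x, y, tol: float) -> bool:
    if isinstance(x, np.ndarray) or isinstance(y, np.ndarray):
        x, y = np.asarray(x), np.asarray(y)
        return x.shape == y.shape and bool(np.all(np.abs(x - y) <= tol))
    return abs(x - y) <= tol


def descriptor_classes(
    table: DescriptorTable, key: DescriptorKey
) -> list[list[PatternId]]:
    """Partition the catalog into classes equal on every key component.

    Floats compare within the key tolerance; spectra compare
    element-wise after canonical ordering.  Classes are returned sorted
    by their smallest member id.
    """
    if not key.components:
        raise ValueError("descriptor key must have at least one component")
    pids = table.pattern_ids
    values = {
        pid: [_component_value(table, pid, c) for c in key.components] for pid in pids
    }
    classes: list[list[PatternId]] = []
    for pid in pids:
        for cls in classes:
            rep = cls[0]
            if all(
                _values_equal(a, b, key.tolerance)
                for a, b in zip(values[pid], values[rep])
            ):
                cls.append(pid)
                break
        else:
            classes.append([pid])
    return sorted(classes, key=lambda c: c[0].id)


def distinguishability_count(
    table: DescriptorTable, key: DescriptorKey, mode: str = "classes"
) -> int:
    """Number of equivalence classes, or of patterns alone in their class."""
    classes = descriptor_classes(table, key)
    if mode == "classes":
        return len(classes)
    if mode == "singletons":
        return sum(1 for c in classes if len(c) == 1)
    raise ValueError(f"mode must be 'classes' or 'singletons', got {mode!r}")


def greedy_minimal_set(
    table: DescriptorTable,
    candidates: list[str],
    tolerance: float = 1e-6,
) -> DescriptorKey:
    """Greedily accumulate components that maximize the class count.

    At each step the candidate giving the largest increase is added
    (ties broken by candidate order); the search stops when no candidate
    increases the class count or all patterns are singletons.
    """
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    chosen: list[str] = []
    best_count = 0
    remaining = list(candidates)
    n = len(table.pattern_ids)
    while remaining and best_count < n:
        scores = [
            distinguishability_count(
                table, DescriptorKey(chosen + [c], tolerance), "classes"
            )
            for c in remaining
        ]
        top = max(scores)
        if top <= best_count:
            break
        pick = remaining.pop(scores.index(top))
        chosen.append(pick)
        best_count = top
    return DescriptorKey(chosen, tolerance)


def case_key(energy: str, case: str, tolerance: float = 1e-6) -> DescriptorKey:
    """Preset keys: A = {energy}, B = {energy, r, CC},
    C = {energy, r, CC, spectrum of the energy's matrix}."""
    if energy not in ENERGY_NAMES:
        raise ValueError(f"unknown energy {energy!r}")
    if case == "A":
        comps = [energy]
    elif case == "B":
        comps = [energy, "r", "CC"]
    elif case == "C":
        spectrum_kind = energy if energy not in ("E", "LE", "QE") else {
            "E": "A",
            "LE": "L",
            "QE": "Q",
        }[energy]
        comps = [energy, "r", "CC", f"spectrum:{spectrum_kind}"]
    else:
        raise ValueError(f"case must be A, B or C, got {case!r}")
    return DescriptorKey(comps, tolerance)
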