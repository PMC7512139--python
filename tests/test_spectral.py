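"""Nine graph energies against the published 3-node reference table."""

import itertools

import numpy as np
import pytest

from netpat.patterns import decode_id
from netpat.spectral import (
    ENERGY_NAMES,
    degree_matrix,
    energy_bounds,
    energy_table,
    energy_vector,
    generalized_energy,
    graph_energy,
    laplacian_energy,
    signless_laplacian_energy,
    spectrum_of,
)

from _printed_tables import ENERGY_TABLE_3, ONE_ULP, SPOT


class TestDegreeMatrix:
    def test_total_degree_convention(self):
        # complete 3-node digraph: every node has in 2 + out 2
        assert np.array_equal(
            degree_matrix(decode_id(238, 3)), np.diag([4, 4, 4])
        )
        # two-output SIM: leaves have degree 1, hub 2
        assert np.array_equal(degree_matrix(decode_id(6, 3)), np.diag([1, 1, 2]))

    def test_empty_pattern(self):
        assert np.array_equal(degree_matrix(np.zeros((3, 3), int)), np.zeros((3, 3)))


class TestPrintedEnergyTable:
    @pytest.mark.parametrize("pid", sorted(ENERGY_TABLE_3))
    def test_all_nine_energies_within_one_printed_ulp(self, pid):
        got = energy_vector(decode_id(pid, 3)).as_tuple()
        for name, expected, value in zip(ENERGY_NAMES, ENERGY_TABLE_3[pid], got):
            assert value == pytest.approx(expected, abs=ONE_ULP), (pid, name)

    @pytest.mark.parametrize(
        "pid,func,expected",
        [
            (238, graph_energy, 4.00),
            (78, graph_energy, 2.83),  # = 2*sqrt(2)
            (6, graph_energy, 0.00),  # nilpotent adjacency
            (238, laplacian_energy, 8.00),
            (6, laplacian_energy, 2.67),
            (110, laplacian_energy, 6.67),
            (98, signless_laplacian_energy, 4.46),
            (14, signless_laplacian_energy, 4.00),
        ],
    )
    def test_spot_values_at_printed_precision(self, pid, func, expected):
        assert func(decode_id(pid, 3)) == pytest.approx(expected, abs=SPOT)

    @pytest.mark.parametrize(
        "pid,left,right,expected",
        [
            (238, "L", "Q", 11.21),  # = sqrt(12) + 2*sqrt(15)
            (6, "A", "L", 1.41),  # = sqrt(2)
            (12, "A", "A", 2.00),
            (238, "A", "Q", 6.93),
            (238, "A", "L", 6.47),
        ],
    )
    def test_generalized_energy_spots(self, pid, left, right, expected):
        got = generalized_energy(decode_id(pid, 3), left, right)
        assert got == pytest.approx(expected, abs=SPOT)

    def test_unsupported_pair_rejected(self):
        with pytest.raises(ValueError):
            generalized_energy(decode_id(6, 3), "A", "X")


class TestSpectra:
    def test_complete_digraph_spectrum(self):
        sp = spectrum_of(decode_id(238, 3), "A")
        assert np.allclose(sp, [2, -1, -1])

    def test_three_cycle_roots_of_unity(self):
        sp = spectrum_of(decode_id(98, 3), "A")
        assert np.allclose(np.abs(sp), 1.0)
        assert sp[0] == pytest.approx(1.0)

    def test_nilpotent_spectrum(self):
        assert np.allclose(spectrum_of(decode_id(6, 3), "A"), 0.0)

    def test_adjacency_spectrum_sums_to_zero(self, catalog3):
        for p in catalog3:
            total = spectrum_of(catalog3.representative(p), "A").sum()
            assert abs(total) < 1e-9


class TestStructure:
    def test_energy_invariant_under_relabeling(self):
        a = decode_id(110, 3)
        base = energy_vector(a).as_tuple()
        for perm in itertools.permutations(range(3)):
            relabeled = a[np.ix_(perm, perm)]
            assert np.allclose(energy_vector(relabeled).as_tuple(), base, atol=1e-9)

    @pytest.mark.parametrize("pair", [(6, 36), (14, 74)])
    def test_equienergetic_pairs_agree_on_all_nine(self, pair):
        va = energy_vector(decode_id(pair[0], 3)).as_tuple()
        vb = energy_vector(decode_id(pair[1], 3)).as_tuple()
        assert np.allclose(va, vb, atol=1e-9)

    def test_symmetric_pattern_AAt_equals_E(self):
        # id 78 has a symmetric adjacency matrix
        a = decode_id(78, 3)
        assert generalized_energy(a, "A", "A") == pytest.approx(
            graph_energy(a), abs=1e-9
        )

    def test_adjacency_energy_zero_multiplicity_is_four(self, catalog3):
        zeros = [
            p
            for p in catalog3
            if graph_energy(catalog3.representative(p)) < 1e-9
        ]
        assert {p.id for p in zeros} == {6, 12, 36, 38}

    def test_QE_has_three_values_of_multiplicity_three(self, catalog3):
        values = [
            round(signless_laplacian_energy(catalog3.representative(p)), 6)
            for p in catalog3
        ]
        counts = {v: values.count(v) for v in values}
        tripled = sorted(v for v, c in counts.items() if c == 3)
        assert tripled == pytest.approx([8 / 3, 4.0, 16 / 3], abs=1e-6)


class TestEnergyBounds:
    def test_laplacian_bounds_for_three_node_catalog(self, catalog3):
        table = energy_table(catalog3)
        lo, hi, ratio = energy_bounds(table, "LE")
        assert lo == pytest.approx(8 / 3, abs=1e-9)
        assert hi == pytest.approx(8.0, abs=1e-9)
        assert ratio == pytest.approx(3.0, abs=1e-9)

    def test_zero_minimum_gives_undefined_ratio(self, catalog3):
        table = energy_table(catalog3)
        lo, hi, ratio = energy_bounds(table, "E")
        assert lo == 0.0 and ratio is None

    def test_single_pattern_ratio_one(self, catalog3):
        pid = catalog3.patterns[-1]
        table = {pid: energy_vector(catalog3.representative(pid))}
        assert energy_bounds(table, "LE")[2] == pytest.approx(1.0)
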