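"""Subgraph census: ESU enumeration, classification, coverage."""

import itertools
import random
from collections import Counter

import pytest

from netpat.census import (
    EmptyCensusError,
    _induced_matrix,
    census,
    connected_subsets,
    frequency_distribution,
    node_coverage,
)
from netpat.network_io import DirectedNetwork
from netpat.patterns import PatternId, canonical_id, encode_bits, is_weakly_connected


def brute_force_census(net, k):
    counts = Counter()
    for sub in itertools.combinations(net.nodes, k):
        a = _induced_matrix(net, sub)
        if is_weakly_connected(a):
            counts[canonical_id(a)] += 1
    return dict(counts)


def random_network(rng, n, p):
    edges = [
        (f"n{i}", f"n{j}")
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < p
    ]
    return DirectedNetwork.from_edges(edges, nodes=[f"n{i}" for i in range(n)])


class TestConnectedSubsets:
    def test_path_single_triple(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "c")])
        assert [frozenset(s) for s in connected_subsets(net, 3)] == [
            frozenset({"a", "b", "c"})
        ]

    def test_star_all_hub_triples(self):
        net = DirectedNetwork.from_edges([("x", "a"), ("x", "b"), ("x", "c")])
        subs = {frozenset(s) for s in connected_subsets(net, 3)}
        assert subs == {
            frozenset({"x", "a", "b"}),
            frozenset({"x", "a", "c"}),
            frozenset({"x", "b", "c"}),
        }

    def test_disjoint_edges_no_triples(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("c", "d")])
        assert list(connected_subsets(net, 3)) == []

    def test_k_larger_than_network_is_empty(self):
        net = DirectedNetwork.from_edges([("a", "b")])
        assert list(connected_subsets(net, 3)) == []


class TestCensus:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([("a", "b"), ("b", "c")], {12: 1}),  # cascade
            ([("x", "y"), ("x", "z"), ("y", "z")], {38: 1}),  # FFL
            ([("x", "a"), ("x", "b"), ("x", "c")], {6: 3}),  # SIM triples
        ],
    )
    def test_small_fixtures(self, edges, expected):
        c = census(DirectedNetwork.from_edges(edges), 3)
        assert {p.id: n for p, n in c.counts.items()} == expected

    def test_occurrence_order_realizes_representative(self):
        net = DirectedNetwork.from_edges([("x", "y"), ("x", "z"), ("y", "z")])
        occ = census(net, 3).occurrences[PatternId(3, 38)][0]
        assert encode_bits(_induced_matrix(net, occ.nodes)) == 38

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_networks(self, seed):
        rng = random.Random(seed)
        net = random_network(rng, rng.randint(5, 12), rng.uniform(0.1, 0.35))
        for k in (3, 4):
            got = census(net, k, with_nodes=False).counts
            assert got == brute_force_census(net, k)

    def test_invariant_under_label_permutation(self):
        rng = random.Random(11)
        net = random_network(rng, 10, 0.25)
        relabel = {n: f"z{hash(n) % 97}_{n}" for n in net.nodes}
        permuted = DirectedNetwork.from_edges(
            [(relabel[u], relabel[v]) for u, v in net.edges],
            nodes=[relabel[n] for n in net.nodes],
        )
        a = census(net, 3, with_nodes=False).counts
        b = census(permuted, 3, with_nodes=False).counts
        assert a == b

    def test_every_subset_classified_once(self):
        rng = random.Random(3)
        net = random_network(rng, 9, 0.3)
        c = census(net, 3)
        assert c.total == len(list(connected_subsets(net, 3)))


class TestCoverage:
    def test_full_coverage_on_cascade(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "c")])
        cov = node_coverage(census(net, 3), census(net, 4), net)
        assert cov["k3"] == 1.0
        assert cov["k4"] == 0.0

    def test_partial_coverage_with_isolated_pair(self):
        net = DirectedNetwork.from_edges([("a", "b"), ("b", "c"), ("d", "e")])
        cov = node_coverage(census(net, 3), census(net, 4), net)
        assert cov["k3"] == pytest.approx(3 / 5)

    def test_empty_network_rejected(self):
        net = DirectedNetwork.from_edges([], nodes=[])
        with pytest.raises(EmptyCensusError):
            node_coverage(census(net, 3), census(net, 4), net)


class TestFrequencyDistribution:
    def test_point_mass_and_normalization(self, catalog3):
        net = DirectedNetwork.from_edges([("x", "a"), ("x", "b"), ("x", "c")])
        dist = frequency_distribution(census(net, 3), catalog3)
        assert dist[PatternId(3, 6)] == 1.0
        assert len(dist) == 13
        assert sum(dist.values()) == pytest.approx(1.0)

    def test_even_split(self, catalog3):
        net = DirectedNetwork.from_edges(
            [("a", "b"), ("b", "c"), ("x", "y"), ("x", "z")]
        )
        dist = frequency_distribution(census(net, 3), catalog3)
        assert dist[PatternId(3, 12)] == pytest.approx(0.5)
        assert dist[PatternId(3, 6)] == pytest.approx(0.5)

    def test_empty_census_rejected(self):
        net = DirectedNetwork.from_edges([("a", "b")])
        with pytest.raises(EmptyCensusError):
            frequency_distribution(census(net, 3))
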