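"""Interaction enrichment between annotation classes, and gene-list Fisher tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import chianet as c

from helpers import network_from_graph, random_graph
from oracles import binom_upper_tail, hypergeom_upper_tail


class TestObservedPairFrequency:
    def test_empty_annotation(self):
        net = network_from_graph(3, [(0, 1)])
        assert c.observed_pair_frequency(net, set(), {0, 1}) == 0

    def test_bruteforce_example(self):
        # edges A1-B1, A1-C1, B1-B2 with ids A1=0, B1=1, C1=2, B2=3
        net = network_from_graph(4, [(0, 1), (0, 2), (1, 3)])
        assert c.observed_pair_frequency(net, {0, 1}, {3}) == 1

    def test_self_pair_on_triangle(self):
        net = network_from_graph(3, [(0, 1), (0, 2), (1, 2)])
        assert c.observed_pair_frequency(net, {0, 1, 2}, {0, 1, 2}) == 3

    def test_each_edge_counted_once(self, rng):
        n = 20
        net = network_from_graph(n, random_graph(rng, n, 0.3))
        a = set(rng.choice(n, 8, replace=False).tolist())
        b = set(rng.choice(n, 8, replace=False).tolist())
        expect = sum(
            1
            for e in net.edges
            if (e.node_a in a and e.node_b in b) or (e.node_a in b and e.node_b in a)
        )
        assert c.observed_pair_frequency(net, a, b) == expect


class TestExpectedPairProbability:
    def test_single_pair_of_four(self):
        assert c.expected_pair_probability(4, 1, 1, 0) == pytest.approx(1 / 6)

    def test_empty_set(self):
        assert c.expected_pair_probability(10, 0, 4, 0) == 0.0

    def test_identical_sets(self):
        assert c.expected_pair_probability(5, 3, 3, 3) == pytest.approx(3 / 10)

    def test_too_few_nodes_rejected(self):
        with pytest.raises(ValueError):
            c.expected_pair_probability(1, 1, 1)

    def test_matches_enumeration_with_overlap(self, rng):
        n = 8
        for _ in range(30):
            a = set(rng.choice(n, int(rng.integers(0, n + 1)), replace=False).tolist())
            b = set(rng.choice(n, int(rng.integers(0, n + 1)), replace=False).tolist())
            count = sum(
                1
                for u in range(n)
                for v in range(u + 1, n)
                if (u in a and v in b) or (u in b and v in a)
            )
            got = c.expected_pair_probability(n, len(a), len(b), len(a & b))
            assert got == pytest.approx(count / math.comb(n, 2))

    def test_pair_type_probabilities_partition(self):
        # disjoint labels A, B, C covering all of N=9: the six pair types
        # (AA, AB, AC, BB, BC, CC) partition all unordered pairs
        sizes = {"A": 2, "B": 3, "C": 4}
        total = 0.0
        names = list(sizes)
        for i, x in enumerate(names):
            for y in names[i:]:
                if x == y:
                    total += c.expected_pair_probability(9, sizes[x], sizes[x], sizes[x])
                else:
                    total += c.expected_pair_probability(9, sizes[x], sizes[y], 0)
        assert total == pytest.approx(1.0)


class TestBinomialPvalue:
    def test_exact_values(self):
        assert c.binomial_pvalue(3, 5, 0.5) == pytest.approx(0.5)
        assert c.binomial_pvalue(5, 5, 0.5) == pytest.approx(0.03125)

    def test_zero_observed_is_one(self):
        assert c.binomial_pvalue(0, 100, 0.37) == 1.0

    @given(st.integers(0, 20), st.integers(0, 20), st.floats(0, 1))
    def test_matches_direct_summation_and_monotone(self, k, n, p):
        if k > n:
            k = n
        got = c.binomial_pvalue(k, n, p)
        assert got == pytest.approx(binom_upper_tail(k, n, p), abs=1e-12)
        if k > 0:
            assert got <= c.binomial_pvalue(k - 1, n, p) + 1e-12


class TestPermutationNull:
    def test_seed_reproducibility(self, rng):
        net = network_from_graph(20, random_graph(rng, 20, 0.2))
        a, b = set(range(5)), set(range(5, 10))
        r1 = c.permutation_null(net, a, b, n_perms=50, seed=7)
        r2 = c.permutation_null(net, a, b, n_perms=50, seed=7)
        assert np.array_equal(r1.perm_null, r2.perm_null)
        assert r1.p_permutation == r2.p_permutation

    def test_planted_complete_bipartite_hits_floor(self):
        # every A-B pair wired, nothing else: observed is maximal
        a, b = set(range(5)), set(range(5, 10))
        edges = [(i, j) for i in a for j in b]
        net = network_from_graph(30, edges)
        res = c.permutation_null(net, a, b, n_perms=200, seed=3)
        assert res.observed == 25
        assert res.p_permutation == pytest.approx(1 / 201)

    def test_p_floor_invariant(self, rng):
        net = network_from_graph(15, random_graph(rng, 15, 0.3))
        res = c.permutation_null(net, {0, 1}, {2, 3}, n_perms=19, seed=0)
        assert res.p_permutation >= 1 / 20

    def test_labels_never_rewire_edges(self, rng):
        net = network_from_graph(15, random_graph(rng, 15, 0.3))
        before = list(net.edges)
        c.permutation_null(net, {0, 1, 2}, {3, 4}, n_perms=20, seed=1)
        assert net.edges == before

    def test_result_carries_both_nulls(self, rng):
        net = network_from_graph(20, random_graph(rng, 20, 0.25))
        a, b = set(range(6)), set(range(6, 12))
        res = c.permutation_null(net, a, b, n_perms=99, seed=5)
        assert res.p_theoretical == pytest.approx(
            c.expected_pair_probability(20, 6, 6, 0)
        )
        assert res.p_binomial == pytest.approx(
            c.binomial_pvalue(res.observed, net.n_edges, res.p_theoretical)
        )

    def test_permutation_tracks_binomial_when_model_holds(self, rng):
        # edges drawn as independent uniform pairs: the theoretical model
        # is exact, so permutation and binomial p-values agree closely
        n = 60
        pairs = [(u, v) for u in range(n) for v in range(u + 1, n)]
        idx = rng.choice(len(pairs), 300, replace=False)
        net = network_from_graph(n, [pairs[i] for i in idx])
        a = set(range(15))
        b = set(range(15, 30))
        res = c.permutation_null(net, a, b, n_perms=2000, seed=11)
        assert res.p_permutation == pytest.approx(res.p_binomial, abs=0.05)


class TestFisherEnrichment:
    def test_single_extreme_table(self):
        universe = {f"g{i}" for i in range(20)}
        targets = {f"g{i}" for i in range(5)}
        res = c.fisher_enrichment(targets, targets, universe)
        assert res.p_value == pytest.approx(1 / math.comb(20, 5))
        assert math.isinf(res.odds_ratio)

    def test_zero_overlap_small_counts(self):
        universe = {f"g{i}" for i in range(10)}
        res = c.fisher_enrichment({"g0"}, {"g9"}, universe)
        assert res.p_value >= 0.5

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            c.fisher_enrichment(set(), set(), set())

    def test_sets_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            c.fisher_enrichment({"x"}, set(), {"y"})

    def test_matches_hypergeometric_oracle_all_small_tables(self):
        for N in range(2, 13):
            universe = {f"g{i}" for i in range(N)}
            for K in range(N + 1):
                reference = {f"g{i}" for i in range(K)}
                for n in range(N + 1):
                    for k in range(max(0, n + K - N), min(n, K) + 1):
                        targets = {f"g{i}" for i in range(k)} | {
                            f"g{i}" for i in range(K, K + n - k)
                        }
                        res = c.fisher_enrichment(targets, reference, universe)
                        assert res.p_value == pytest.approx(
                            hypergeom_upper_tail(N, K, n, k), abs=1e-10
                        )


def test_pairwise_enrichment_table(rng):
    net = network_from_graph(30, random_graph(rng, 30, 0.15))
    anns = [
        c.AnnotationSet(name=f"S{i}", kind="interval",
                        node_hits={int(v): [net.nodes[int(v)].interval]
                                   for v in rng.choice(30, 8, replace=False)})
        for i in range(3)
    ]
    df = c.pairwise_enrichment(net, anns, n_perms=50, seed=2)
    assert len(df) == 6  # 3 self pairs + 3 cross pairs
    assert {"p_binomial_fdr", "p_permutation_fdr"} <= set(df.columns)
    assert ((df["p_permutation"] > 0) & (df["p_permutation"] <= 1)).all()
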