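"""Network construction: anchor merging, peak nodes, edges, components."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import chianet as c
from chianet.core import GenomicInterval, Interaction
from chianet.network_build import build_edges, map_to_nodes

from helpers import random_graph, random_intervals, network_from_graph
from oracles import components_by_unionfind, merge_by_unionfind


def iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestMergeAnchors:
    def test_empty(self):
        assert c.merge_anchors([]) == []

    def test_overlapping_chain(self):
        nodes = c.merge_anchors([iv("chr1", 100, 200), iv("chr1", 150, 300), iv("chr1", 400, 500)])
        assert [n.interval for n in nodes] == [iv("chr1", 100, 300), iv("chr1", 400, 500)]
        assert [n.id for n in nodes] == [0, 1]

    def test_no_cross_chromosome_merge(self):
        nodes = c.merge_anchors([iv("chr1", 100, 200), iv("chr2", 100, 200)])
        assert len(nodes) == 2

    def test_bookended_do_not_merge_by_default(self):
        assert len(c.merge_anchors([iv("chr1", 100, 200), iv("chr1", 200, 300)])) == 2
        assert len(c.merge_anchors([iv("chr1", 100, 200), iv("chr1", 200, 300)], merge_bookended=True)) == 1

    def test_matches_unionfind_oracle(self, rng):
        anchors = random_intervals(rng, 500)
        nodes = c.merge_anchors(anchors)
        got = sorted((n.interval.chrom, n.interval.start, n.interval.end) for n in nodes)
        assert got == merge_by_unionfind(anchors)

    def test_every_anchor_contained_in_exactly_one_node(self, rng):
        anchors = random_intervals(rng, 200)
        nodes = c.merge_anchors(anchors)
        for a in anchors:
            containing = [
                n for n in nodes
                if n.interval.chrom == a.chrom
                and n.interval.start <= a.start
                and a.end <= n.interval.end
            ]
            assert len(containing) == 1

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 80)).map(
                lambda t: GenomicInterval("chr1", t[0], t[0] + t[1])
            ),
            max_size=40,
        )
    )
    def test_idempotent(self, anchors):
        once = [n.interval for n in c.merge_anchors(anchors)]
        twice = [n.interval for n in c.merge_anchors(once)]
        assert once == twice


class TestPeakNodes:
    def test_peak_refines_anchor(self):
        nodes, mapping = c.define_nodes_from_peaks(
            [iv("chr1", 100, 200)], [iv("chr1", 150, 450)]
        )
        assert [n.interval for n in nodes] == [iv("chr1", 150, 450)]
        assert mapping[iv("chr1", 100, 200)] == [0]
        assert nodes[0].source == "peak"

    def test_anchor_without_peak_maps_to_nothing(self):
        nodes, mapping = c.define_nodes_from_peaks(
            [iv("chr1", 100, 200)], [iv("chr1", 300, 400)]
        )
        assert nodes == [] and mapping[iv("chr1", 100, 200)] == []

    def test_anchor_spanning_two_peaks_maps_to_both(self):
        nodes, mapping = c.define_nodes_from_peaks(
            [iv("chr1", 100, 400)], [iv("chr1", 50, 150), iv("chr1", 300, 500)]
        )
        assert mapping[iv("chr1", 100, 400)] == [0, 1]

    def test_peak_without_anchor_dropped(self):
        nodes, _ = c.define_nodes_from_peaks(
            [iv("chr1", 100, 200)], [iv("chr1", 150, 250), iv("chr1", 900, 950)]
        )
        assert [n.interval for n in nodes] == [iv("chr1", 150, 250)]

    def test_empty_peaks_warns(self):
        with pytest.warns(UserWarning, match="empty peak set"):
            nodes, mapping = c.define_nodes_from_peaks([iv("chr1", 0, 10)], [])
        assert nodes == []

    def test_mapping_matches_bruteforce_overlap(self, rng):
        anchors = random_intervals(rng, 100)
        peaks = random_intervals(rng, 40)
        nodes, mapping = c.define_nodes_from_peaks(anchors, peaks)
        for a in set(anchors):
            expect = sorted(n.id for n in nodes if n.interval.overlaps(a))
            assert mapping[a] == expect


class TestBuildEdges:
    def test_aggregation_sums_counts(self):
        a, b = iv("chr1", 0, 100), iv("chr1", 500, 600)
        interactions = [Interaction(a, b, pet_count=p) for p in (2, 3, 4)]
        nodes = c.merge_anchors([a, b])
        edges, counts = build_edges(interactions, nodes, map_to_nodes([a, b], nodes))
        (edge,) = edges
        assert (edge.interaction_count, edge.pet_count) == (3, 9)
        assert counts == {"used": 3, "self_loop": 0, "unmapped": 0}

    def test_self_loop_counted_not_stored(self):
        a, b = iv("chr1", 0, 100), iv("chr1", 50, 150)  # merge into one node
        nodes = c.merge_anchors([a, b])
        edges, counts = build_edges(
            [Interaction(a, b, pet_count=1)], nodes, map_to_nodes([a, b], nodes)
        )
        assert edges == [] and counts["self_loop"] == 1

    def test_unmapped_anchor_counted(self):
        a, b = iv("chr1", 0, 100), iv("chr1", 500, 600)
        nodes, mapping = c.define_nodes_from_peaks([a, b], [iv("chr1", 0, 50)])
        edges, counts = build_edges([Interaction(a, b)], nodes, mapping)
        assert edges == [] and counts["unmapped"] == 1

    def test_fanout_to_all_overlapping_node_pairs(self):
        a, b = iv("chr1", 100, 400), iv("chr1", 900, 1000)
        peaks = [iv("chr1", 50, 150), iv("chr1", 300, 500), iv("chr1", 850, 950)]
        nodes, mapping = c.define_nodes_from_peaks([a, b], peaks)
        edges, counts = build_edges([Interaction(a, b, pet_count=5)], nodes, mapping)
        assert {(e.node_a, e.node_b) for e in edges} == {(0, 2), (1, 2)}
        assert all(e.pet_count == 5 for e in edges)
        assert counts["used"] == 1


class TestConnectedComponents:
    def test_no_edges_all_singletons(self):
        net = network_from_graph(5, [])
        assert c.connected_components(net) == [0, 1, 2, 3, 4]

    def test_path_is_single_component(self):
        net = network_from_graph(4, [(0, 1), (1, 2), (2, 3)])
        assert c.connected_components(net) == [0, 0, 0, 0]

    def test_labels_match_unionfind_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 31))
            edges = random_graph(rng, n, 0.05)
            net = network_from_graph(n, edges)
            assert c.connected_components(net) == components_by_unionfind(n, edges)


class TestBuildNetwork:
    @staticmethod
    def _clique_interactions(node_starts, chrom="chr1"):
        ivs = [iv(chrom, s, s + 100) for s in node_starts]
        return [
            Interaction(ivs[i], ivs[j])
            for i in range(len(ivs))
            for j in range(i + 1, len(ivs))
        ]

    def test_two_planted_cliques_two_components(self):
        interactions = self._clique_interactions([0, 1000, 2000, 3000]) + \
            self._clique_interactions([50_000, 51_000, 52_000, 53_000])
        net = c.build_network(interactions)
        assert net.n_components == 2
        assert net.n_nodes == 8 and net.n_edges == 12

    def test_min_pet_filters_everything(self):
        interactions = self._clique_interactions([0, 1000])
        with pytest.warns(UserWarning, match="filtered"):
            net = c.build_network(interactions, min_pet=5)
        assert net.n_nodes == 0 and net.build_stats.pet_filtered == 1

    def test_approaches_agree_when_peaks_equal_anchors(self):
        fx = c.generate(c.FixtureSpec(seed=21))
        anchors = [a for it in fx.interactions for a in (it.anchor1, it.anchor2)]
        net1 = c.build_network(fx.interactions)
        net2 = c.build_network(fx.interactions, peaks=anchors)
        edges1 = {(e.node_a, e.node_b, e.interaction_count, e.pet_count) for e in net1.edges}
        edges2 = {(e.node_a, e.node_b, e.interaction_count, e.pet_count) for e in net2.edges}
        assert edges1 == edges2
        assert [n.component for n in net1.nodes] == [n.component for n in net2.nodes]

    @pytest.mark.parametrize("use_peaks", [False, True])
    def test_structural_invariants_on_fixture(self, use_peaks):
        fx = c.generate(c.FixtureSpec(seed=22, n_components=8))
        net = c.build_network(fx.interactions, peaks=fx.peaks if use_peaks else None)
        # conservation of input interactions across the stats buckets
        assert net.build_stats.conserved
        # no two node intervals on one chromosome overlap (sweep)
        by_chrom = {}
        for n in net.nodes:
            by_chrom.setdefault(n.interval.chrom, []).append(n.interval)
        for ivs in by_chrom.values():
            ivs.sort(key=lambda x: x.start)
            for prev, nxt in zip(ivs, ivs[1:]):
                assert prev.end <= nxt.start
        # handshake identity
        assert int(net.degrees().sum()) == 2 * net.n_edges
        # every edge within one component
        comp = [n.component for n in net.nodes]
        assert all(comp[e.node_a] == comp[e.node_b] for e in net.edges)

    def test_conservation_with_filtering_and_unmapped(self):
        fx = c.generate(c.FixtureSpec(seed=23))
        # drop some peak loci so a few anchors become unmapped
        peaks = fx.peaks[: len(fx.peaks) // 2]
        net = c.build_network(fx.interactions, peaks=peaks, min_pet=2)
        s = net.build_stats
        assert s.input == len(fx.interactions)
        assert s.pet_filtered > 0 and s.unmapped > 0
        assert s.conserved
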