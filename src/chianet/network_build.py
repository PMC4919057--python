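"""Network construction from paired-anchor interaction data.

Two construction approaches:

1. interaction data alone — nodes are maximal unions of overlapping
   interaction anchors (:func:`merge_anchors`);
2. interactions plus an open-chromatin peak set (DNase-seq / ATAC-seq) —
   the merged peaks define the nodes and anchors that touch no peak are
   filtered out as likely false positives
   (:func:`define_nodes_from_peaks`).

Edges connect node pairs whose intervals are overlapped by the two
anchors of an interaction; the number of interactions collapsed onto a
node pair and their summed PET counts are kept as edge weights.
Connected components are labelled by breadth-first search.
"""

from __future__ import annotations

import warnings
from collections import defaultdict, deque
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .core import (
    BuildStats,
    Edge,
    GenomicInterval,
    Interaction,
    Network,
    Node,
)

__all__ = [
    "merge_anchors",
    "define_nodes_from_peaks",
    "map_to_nodes",
    "build_edges",
    "connected_components",
    "build_network",
]


def _merge_intervals(
    intervals: Iterable[GenomicInterval], merge_bookended: bool = False
) -> list[GenomicInterval]:
    """Union of overlapping intervals, sorted by (chrom, start).

    Strict half-open semantics by default: intervals sharing only a
    boundary base ([100,200) and [200,300)) stay separate unless
    ``merge_bookended`` is set.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged:
            last = merged[-1]
            touching = iv.start < last.end or (merge_bookended and iv.start == last.end)
            if iv.chrom == last.chrom and touching:
                if iv.end > last.end:
                    merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
                continue
        merged.append(iv)
    return merged


def merge_anchors(
    anchors: Iterable[GenomicInterval], merge_bookended: bool = False
) -> list[Node]:
    """Define nodes by merging overlapping interaction anchors.

    Returns the minimal set of maximal intervals such that every input
    anchor is contained in exactly one node and any two overlapping
    anchors share a node; nodes are numbered densely in (chrom, start)
    order.
    """
    return [
        Node(id=i, interval=iv, source="merged_anchors")
        for i, iv in enumerate(_merge_intervals(anchors, merge_bookended))
    ]


def _node_trees(nodes: Sequence[Node]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for n in nodes:
        trees[n.interval.chrom][n.interval.start : n.interval.end] = n.id
    return trees


def map_to_nodes(
    anchors: Iterable[GenomicInterval], nodes: Sequence[Node]
) -> dict[GenomicInterval, list[int]]:
    """Map each distinct anchor interval to the node ids it overlaps.

    An anchor overlapping no node maps to an empty list; an anchor
    spanning several nodes maps to all of them (sorted by id).
    """
    trees = _node_trees(nodes)
    mapping: dict[GenomicInterval, list[int]] = {}
    for a in anchors:
        if a in mapping:
            continue
        tree = trees.get(a.chrom)
        hits = sorted(h.data for h in tree.overlap(a.start, a.end)) if tree else []
        mapping[a] = hits
    return mapping


def define_nodes_from_peaks(
    anchors: Iterable[GenomicInterval],
    peaks: Iterable[GenomicInterval],
    merge_bookended: bool = False,
) -> tuple[list[Node], dict[GenomicInterval, list[int]]]:
    """Define nodes from an open-chromatin peak set (approach 2).

    Peaks are merged into pairwise non-overlapping intervals; each merged
    peak that overlaps at least one anchor becomes a node.  Returns the
    node list and the anchor -> node-ids mapping; anchors overlapping no
    peak map to nothing (their interactions will be filtered).
    """
    anchors = list(anchors)
    merged = _merge_intervals(peaks, merge_bookended)
    if not merged:
        warnings.warn(
            "empty peak set: no nodes defined, all interactions will be filtered",
            stacklevel=2,
        )
        return [], {a: [] for a in anchors}
    candidates = [Node(id=i, interval=iv, source="peak") for i, iv in enumerate(merged)]
    prelim = map_to_nodes(anchors, candidates)
    hit_ids = sorted({nid for ids in prelim.values() for nid in ids})
    renumber = {old: new for new, old in enumerate(hit_ids)}
    nodes = [
        Node(id=renumber[n.id], interval=n.interval, source="peak")
        for n in candidates
        if n.id in renumber
    ]
    mapping = {a: [renumber[i] for i in ids] for a, ids in prelim.items()}
    return nodes, mapping


def build_edges(
    interactions: Iterable[Interaction],
    nodes: Sequence[Node],
    mapping: dict[GenomicInterval, list[int]],
) -> tuple[list[Edge], dict[str, int]]:
    """Aggregate interactions into simple weighted edges.

    Each interaction contributes to every distinct node pair in
    (nodes of anchor1) x (nodes of anchor2): +1 interaction_count and
    +pet_count per pair.  Interactions with an unmapped anchor or with
    both anchors in a single node produce no edge and are tallied in the
    returned counts dict (keys: used, self_loop, unmapped) — the caller
    folds these into :class:`~chianet.core.BuildStats`.
    """
    agg: dict[tuple[int, int], list[int]] = {}
    counts = {"used": 0, "self_loop": 0, "unmapped": 0}
    chroms = [n.interval.chrom for n in nodes]
    for it in interactions:
        ids1 = mapping.get(it.anchor1, [])
        ids2 = mapping.get(it.anchor2, [])
        if not ids1 or not ids2:
            counts["unmapped"] += 1
            continue
        pairs = {
            (min(a, b), max(a, b)) for a in ids1 for b in ids2 if a != b
        }
        if not pairs:
            counts["self_loop"] += 1
            continue
        counts["used"] += 1
        for key in pairs:
            if key in agg:
                agg[key][0] += 1
                agg[key][1] += it.pet_count
            else:
                agg[key] = [1, it.pet_count]
    edges = [
        Edge(
            node_a=a,
            node_b=b,
            interaction_count=ic,
            pet_count=pc,
            trans=chroms[a] != chroms[b],
        )
        for (a, b), (ic, pc) in sorted(agg.items())
    ]
    return edges, counts


def connected_components(network: Network) -> list[int]:
    """Breadth-first-search component label per node.

    Labels are 0..C-1, assigned in ascending order of each component's
    smallest node id; isolated nodes form singleton components.
    """
    n = network.n_nodes
    adj: list[list[int]] = [[] for _ in range(n)]
    for e in network.edges:
        adj[e.node_a].append(e.node_b)
        adj[e.node_b].append(e.node_a)
    labels = [-1] * n
    next_label = 0
    for start in range(n):
        if labels[start] != -1:
            continue
        labels[start] = next_label
        queue = deque([start])
        while queue:
            u = queue.popleft()
            for v in adj[u]:
                if labels[v] == -1:
                    labels[v] = next_label
                    queue.append(v)
        next_label += 1
    return labels


def build_network(
    interactions: Iterable[Interaction],
    peaks: Optional[Iterable[GenomicInterval]] = None,
    min_pet: int = 1,
    merge_bookended: bool = False,
) -> Network:
    """Build a chromatin interaction network end to end.

    Applies the ``min_pet`` support filter, defines nodes from merged
    anchors (``peaks is None``) or from the peak set, aggregates edges
    and labels connected components.  ``build_stats`` accounts for every
    input interaction: input = used + pet_filtered + self_loop + unmapped.
    """
    interactions = list(interactions)
    stats = BuildStats(input=len(interactions))
    kept = [it for it in interactions if it.pet_count >= min_pet]
    stats.pet_filtered = len(interactions) - len(kept)
    anchors = [a for it in kept for a in (it.anchor1, it.anchor2)]
    if peaks is None:
        nodes = merge_anchors(anchors, merge_bookended)
        mapping = map_to_nodes(anchors, nodes)
    else:
        nodes, mapping = define_nodes_from_peaks(anchors, peaks, merge_bookended)
    edges, counts = build_edges(kept, nodes, mapping)
    stats.used = counts["used"]
    stats.self_loop = counts["self_loop"]
    stats.unmapped = counts["unmapped"]
    network = Network(nodes=nodes, edges=edges, build_stats=stats)
    if stats.input and not edges and not nodes:
        warnings.warn("all interactions were filtered; network is empty", stacklevel=2)
    labels = connected_components(network)
    for node, label in zip(network.nodes, labels):
        node.component = label
    return network
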