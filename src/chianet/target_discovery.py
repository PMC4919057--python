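"""Shortest-path discovery of gene targets of annotated loci.

Given a set of source nodes (e.g. nodes harboring non-coding variants)
and a set of target nodes (e.g. nodes overlapping gene promoters), this
module enumerates all shortest paths between them, classifies target
genes as *direct* (same node as the source, or one edge away) or
*indirect* (2-4 edges away by default), and provides the nearest-TSS
assignment as the linear-genome baseline to compare against.

Distances are hop counts on the simple unweighted graph, consistent
with :mod:`chianet.network_metrics`.
"""

from __future__ import annotations

import warnings
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .annotation import AnnotationSet
from .core import GeneModel, Network, Variant

__all__ = [
    "TargetPath",
    "TargetClassification",
    "shortest_paths_between",
    "classify_targets",
    "nearest_tss",
]

DEFAULT_MAX_DIST = 4
DEFAULT_MAX_PATHS_PER_PAIR = 1000


@dataclass
class TargetPath:
    """All tied shortest paths from one source node to one target node."""

    source_node: int
    target_node: int
    hop_distance: int
    paths: list[list[int]]
    source_features: list = field(default_factory=list)
    target_features: list = field(default_factory=list)


@dataclass
class TargetClassification:
    """Gene targets split by minimum hop distance from any source."""

    direct: set[str]
    indirect: set[str]
    max_indirect: int
    gene_distances: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert not (self.direct & self.indirect)


def _bfs_parents(
    adj: list[list[int]], start: int, max_dist: int
) -> tuple[dict[int, int], dict[int, list[int]]]:
    """BFS from ``start`` up to depth ``max_dist``.

    Returns (distance, shortest-path predecessors) maps over reached
    nodes; every predecessor list realizes some tied shortest path.
    """
    dist = {start: 0}
    parents: dict[int, list[int]] = {start: []}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        if dist[u] == max_dist:
            continue
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                parents[v] = [u]
                queue.append(v)
            elif dist[v] == dist[u] + 1:
                parents[v].append(u)
    return dist, parents


def _enumerate_paths(
    parents: dict[int, list[int]], target: int, cap: int
) -> tuple[list[list[int]], bool]:
    """All shortest paths to ``target`` via the predecessor DAG, capped."""
    paths: list[list[int]] = []
    stack = [(target, [target])]
    truncated = False
    while stack:
        node, suffix = stack.pop()
        preds = parents[node]
        if not preds:
            paths.append(list(reversed(suffix)))
            if len(paths) >= cap:
                truncated = bool(stack)
                break
            continue
        for p in sorted(preds, reverse=True):
            stack.append((p, suffix + [p]))
    paths.sort()
    return paths, truncated


def shortest_paths_between(
    network: Network,
    sources: Iterable[int],
    targets: Iterable[int],
    max_dist: int = DEFAULT_MAX_DIST,
    source_annotation: Optional[AnnotationSet] = None,
    target_annotation: Optional[AnnotationSet] = None,
    max_paths_per_pair: int = DEFAULT_MAX_PATHS_PER_PAIR,
) -> list[TargetPath]:
    """Enumerate all shortest paths from source nodes to target nodes.

    For every (source, target) pair within ``max_dist`` hops, one
    :class:`TargetPath` holds *all* tied shortest paths (capped at
    ``max_paths_per_pair`` with a warning).  A node that is both source
    and target yields a zero-hop path.  Pairs in different components
    are omitted.  Feature records from the optional annotation sets are
    attached to each path.
    """
    if max_dist < 0:
        raise ValueError(f"max_dist must be >= 0, got {max_dist}")
    sources = sorted(set(sources))
    targets = sorted(set(targets))
    for v in (*sources, *targets):
        if not 0 <= v < network.n_nodes:
            raise ValueError(f"node id {v} not in network")
    adj: list[list[int]] = [[] for _ in network.node_ids()]
    for e in network.edges:
        adj[e.node_a].append(e.node_b)
        adj[e.node_b].append(e.node_a)
    target_set = set(targets)
    out: list[TargetPath] = []
    for s in sources:
        dist, parents = _bfs_parents(adj, s, max_dist)
        for t in sorted(target_set & dist.keys()):
            paths, truncated = _enumerate_paths(parents, t, max_paths_per_pair)
            if truncated:
                warnings.warn(
                    f"path enumeration for pair ({s}, {t}) capped at "
                    f"{max_paths_per_pair} tied shortest paths",
                    stacklevel=2,
                )
            out.append(
                TargetPath(
                    source_node=s,
                    target_node=t,
                    hop_distance=dist[t],
                    paths=paths,
                    source_features=(
                        list(source_annotation.node_hits.get(s, []))
                        if source_annotation
                        else []
                    ),
                    target_features=(
                        list(target_annotation.node_hits.get(t, []))
                        if target_annotation
                        else []
                    ),
                )
            )
    return out


def classify_targets(
    paths: Sequence[TargetPath],
    gene_annotation: AnnotationSet,
    direct_max: int = 1,
    indirect_range: tuple[int, int] = (2, 4),
) -> TargetClassification:
    """Split target genes into direct and indirect targets.

    Each gene's distance is the minimum hop distance over all its
    promoter-bearing nodes and all sources.  Genes at distance
    <= ``direct_max`` are direct (this includes distance 0, the gene
    sharing the source's node); genes within ``indirect_range`` are
    indirect; genes farther than the indirect upper bound are excluded.
    """
    lo, hi = indirect_range
    if lo > hi:
        raise ValueError(f"invalid indirect_range {indirect_range}")
    if direct_max >= lo:
        raise ValueError(
            f"direct_max ({direct_max}) overlaps indirect_range {indirect_range}"
        )
    gene_dist: dict[str, int] = {}
    for tp in paths:
        for gene in gene_annotation.genes_for_node(tp.target_node):
            prev = gene_dist.get(gene)
            if prev is None or tp.hop_distance < prev:
                gene_dist[gene] = tp.hop_distance
    direct = {g for g, d in gene_dist.items() if d <= direct_max}
    indirect = {g for g, d in gene_dist.items() if lo <= d <= hi} - direct
    kept = {g: d for g, d in gene_dist.items() if d <= hi}
    return TargetClassification(
        direct=direct, indirect=indirect, max_indirect=hi, gene_distances=kept
    )


def nearest_tss(
    variants: Iterable[Variant], genes: Sequence[GeneModel]
) -> dict[Variant, list[GeneModel]]:
    """Assign each variant to the gene(s) with the nearest TSS.

    The linear-genome baseline: distance is |pos - TSS| on the same
    chromosome; all tied genes are reported.  A variant on a chromosome
    with no genes maps to an empty list.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    sorted_tss: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
    for chrom, models in by_chrom.items():
        models = sorted(models, key=lambda g: (g.tss, g.name))
        sorted_tss[chrom] = (np.array([g.tss for g in models]), models)
    out: dict[Variant, list[GeneModel]] = {}
    for v in variants:
        entry = sorted_tss.get(v.chrom)
        if entry is None:
            out[v] = []
            continue
        tss_arr, models = entry
        dists = np.abs(tss_arr - v.pos)
        best = dists.min()
        out[v] = [m for m, d in zip(models, dists) if d == best]
    return out
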