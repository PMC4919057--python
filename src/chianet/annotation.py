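"""Annotating network nodes with genomic features.

Feature sets — intervals, point variants, genes (via their promoters or
their whole bodies), promoter windows, plain gene lists — are mapped
onto the nodes they overlap.  The promoter of a gene is the window
``[TSS - flank, TSS + flank + 1)`` (default flank 2 kb), clamped at
coordinate 0; this keeps the TSS base itself in the window on both
strands and is the convention used throughout target discovery.

Overlap is strict half-open sharing of >= 1 bp; a variant is a 1-bp
interval ``[pos, pos+1)``, so a variant sitting exactly on a node's
``end`` coordinate does not hit it.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .core import (
    GeneModel,
    GenomicInterval,
    Network,
    Promoter,
    Variant,
    feature_gene,
)

__all__ = [
    "AnnotationSet",
    "PromoterSet",
    "find_overlaps",
    "promoters_from_genes",
    "annotate_nodes",
    "gene_list_annotation",
    "superimpose_gene_network",
]

DEFAULT_PROMOTER_FLANK = 2000


@dataclass
class PromoterSet:
    """Promoter windows, one per gene model, tagged with gene names."""

    promoters: list[Promoter]
    flank_bp: int


@dataclass
class AnnotationSet:
    """A named mapping from network nodes to the features hitting them.

    ``node_hits`` holds only nodes with at least one hit; a feature may
    hit several nodes (e.g. a promoter straddling two open-chromatin
    sites).
    """

    name: str
    kind: str  # interval | variant | gene | promoter | gene_list
    node_hits: dict[int, list] = field(default_factory=dict)

    def nodes(self) -> set[int]:
        return set(self.node_hits)

    def genes(self) -> set[str]:
        """All gene symbols carried by the hit records."""
        return {
            g
            for records in self.node_hits.values()
            for r in records
            if (g := feature_gene(r)) is not None
        }

    def genes_for_node(self, node_id: int) -> set[str]:
        return {
            g
            for r in self.node_hits.get(node_id, [])
            if (g := feature_gene(r)) is not None
        }

    def gene_to_nodes(self) -> dict[str, set[int]]:
        out: dict[str, set[int]] = defaultdict(set)
        for node_id, records in self.node_hits.items():
            for r in records:
                g = feature_gene(r)
                if g is not None:
                    out[g].add(node_id)
        return dict(out)

    def n_hits(self) -> int:
        return sum(len(v) for v in self.node_hits.values())


def find_overlaps(
    query: Sequence[GenomicInterval], subject: Sequence[GenomicInterval]
) -> list[tuple[int, int]]:
    """All (query index, subject index) pairs sharing >= 1 bp.

    Deterministic query-major order.  Bookended intervals do not count
    (half-open convention).
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for j, iv in enumerate(subject):
        trees[iv.chrom][iv.start : iv.end] = j
    out: list[tuple[int, int]] = []
    for i, iv in enumerate(query):
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        out.extend((i, j) for j in sorted(h.data for h in tree.overlap(iv.start, iv.end)))
    return out


def promoters_from_genes(
    genes: Iterable[GeneModel], flank_bp: int = DEFAULT_PROMOTER_FLANK
) -> PromoterSet:
    """Promoter windows ``[TSS - flank, TSS + flank + 1)`` per gene.

    Clamped to start >= 0; duplicates by (gene, interval) removed.
    """
    if flank_bp < 0:
        raise ValueError(f"flank_bp must be >= 0, got {flank_bp}")
    promoters: list[Promoter] = []
    seen: set[tuple] = set()
    for g in genes:
        tss = g.tss
        iv = GenomicInterval(g.chrom, max(0, tss - flank_bp), tss + flank_bp + 1)
        key = (g.name, iv)
        if key not in seen:
            seen.add(key)
            promoters.append(Promoter(interval=iv, gene=g.name))
    return PromoterSet(promoters=promoters, flank_bp=flank_bp)


def _feature_intervals(
    features: Iterable, kind: Optional[str], flank_bp: int
) -> tuple[list, list[GenomicInterval], str]:
    """Normalize a feature collection to (records, their intervals, kind)."""
    if isinstance(features, PromoterSet):
        records = list(features.promoters)
        return records, [p.interval for p in records], "promoter"
    records = list(features)
    if not records:
        return [], [], kind or "interval"
    first = records[0]
    if isinstance(first, Variant):
        return records, [v.interval for v in records], kind or "variant"
    if isinstance(first, Promoter):
        return records, [p.interval for p in records], kind or "promoter"
    if isinstance(first, GeneModel):
        if kind == "interval":  # whole gene body
            ivs = [GenomicInterval(g.chrom, g.tx_start, g.tx_end) for g in records]
            return records, ivs, "interval"
        pset = promoters_from_genes(records, flank_bp)
        return (
            list(pset.promoters),
            [p.interval for p in pset.promoters],
            kind or "gene",
        )
    if isinstance(first, GenomicInterval):
        return records, list(records), kind or "interval"
    raise TypeError(f"unsupported feature type {type(first).__name__}")


def annotate_nodes(
    network: Network,
    features: Iterable,
    name: str,
    kind: Optional[str] = None,
    flank_bp: int = DEFAULT_PROMOTER_FLANK,
    overwrite: bool = False,
) -> AnnotationSet:
    """Map a feature set onto the nodes it overlaps and register it.

    Gene models annotate through their promoter windows by default
    (pass ``kind="interval"`` for whole-body overlap); variants are
    treated as 1-bp intervals.  The result is stored on
    ``network.annotations[name]``; re-using a name raises unless
    ``overwrite`` is set.
    """
    if name in network.annotations and not overwrite:
        raise ValueError(
            f"annotation {name!r} already exists (pass overwrite=True to replace)"
        )
    records, intervals, resolved_kind = _feature_intervals(features, kind, flank_bp)
    node_ivs = [n.interval for n in network.nodes]
    node_hits: dict[int, list] = defaultdict(list)
    for fi, ni in find_overlaps(intervals, node_ivs):
        node_hits[ni].append(records[fi])
    ann = AnnotationSet(name=name, kind=resolved_kind, node_hits=dict(node_hits))
    network.annotations[name] = ann
    return ann


def gene_list_annotation(
    gene_annotation: AnnotationSet, gene_names: Iterable[str], name: str
) -> AnnotationSet:
    """Restrict a gene/promoter annotation to a plain gene list.

    Produces a ``gene_list`` annotation containing only hit records
    whose gene symbol is in the list — how curated lists (e.g. known
    oncogenes) are placed onto a network already annotated with all
    promoters.
    """
    wanted = set(gene_names)
    node_hits = {
        node_id: kept
        for node_id, records in gene_annotation.node_hits.items()
        if (kept := [r for r in records if feature_gene(r) in wanted])
    }
    return AnnotationSet(name=name, kind="gene_list", node_hits=node_hits)


def superimpose_gene_network(
    network: Network,
    gene_pairs: Iterable[tuple[str, str]],
    gene_annotation: AnnotationSet,
) -> tuple[list[tuple[int, int, tuple[str, str]]], int]:
    """Project a gene-level interaction list (e.g. protein-protein pairs)
    onto the chromatin network's nodes.

    For each pair (g1, g2), every unordered node pair (a, b), a != b,
    with g1 on a and g2 on b (or vice versa) is reported once.  Pairs
    with a gene absent from the annotation are skipped; the count of
    skipped pairs is returned alongside the hits.
    """
    gene_nodes = gene_annotation.gene_to_nodes()
    hits: list[tuple[int, int, tuple[str, str]]] = []
    skipped = 0
    for g1, g2 in gene_pairs:
        n1 = gene_nodes.get(g1)
        n2 = gene_nodes.get(g2)
        if not n1 or not n2:
            skipped += 1
            continue
        pairs = {
            (min(a, b), max(a, b)) for a in n1 for b in n2 if a != b
        }
        hits.extend((a, b, (g1, g2)) for a, b in sorted(pairs))
    return hits, skipped
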