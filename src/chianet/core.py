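"""Core domain types for chromatin interaction networks.

All genomic coordinates are 0-based half-open ``[start, end)`` (BED
convention), on every type and at every module boundary.  Readers in
:mod:`chianet.genomic_io` normalize to this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx
import numpy as np

__all__ = [
    "GenomicInterval",
    "Interaction",
    "Variant",
    "GeneModel",
    "Promoter",
    "Node",
    "Edge",
    "BuildStats",
    "Network",
    "feature_label",
    "feature_gene",
]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic span ``chrom:[start, end)``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two spans share >= 1 bp (half-open: bookended
        intervals like [100,200) and [200,300) do NOT overlap)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class Interaction:
    """One paired-anchor chromatin interaction.

    ``pet_count`` is the number of paired-end tags supporting the
    interaction.  Anchors are stored canonically ordered by
    ``(chrom, start, end)``; the constructor reorders if needed.
    """

    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int = 1
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.pet_count < 1:
            raise ValueError(f"pet_count must be >= 1, got {self.pet_count}")
        a, b = self.anchor1, self.anchor2
        if (b.chrom, b.start, b.end) < (a.chrom, a.start, a.end):
            object.__setattr__(self, "anchor1", b)
            object.__setattr__(self, "anchor2", a)

    @property
    def trans(self) -> bool:
        """True for inter-chromosomal interactions."""
        return self.anchor1.chrom != self.anchor2.chrom


@dataclass(frozen=True)
class Variant:
    """A point variant; ``pos`` is the 0-based base position."""

    chrom: str
    pos: int
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"pos must be >= 0, got {self.pos}")

    @property
    def interval(self) -> GenomicInterval:
        """The variant as a 1-bp half-open interval ``[pos, pos+1)``."""
        return GenomicInterval(self.chrom, self.pos, self.pos + 1)


@dataclass(frozen=True)
class GeneModel:
    """A transcript span with strand; TSS is strand dependent."""

    name: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.tx_end <= self.tx_start:
            raise ValueError(
                f"tx_end must exceed tx_start for {self.name}: "
                f"[{self.tx_start}, {self.tx_end})"
            )

    @property
    def tss(self) -> int:
        """Transcription start site: tx_start on '+', tx_end-1 on '-'."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1


@dataclass(frozen=True)
class Promoter:
    """A promoter window tagged with the gene it belongs to."""

    interval: GenomicInterval
    gene: str


def feature_label(feature: object) -> str:
    """Short human-readable label for any annotation feature record."""
    if isinstance(feature, Variant):
        return feature.id or f"{feature.chrom}:{feature.pos}"
    if isinstance(feature, GeneModel):
        return feature.name
    if isinstance(feature, Promoter):
        return feature.gene
    if isinstance(feature, GenomicInterval):
        return str(feature)
    return str(feature)


def feature_gene(feature: object) -> Optional[str]:
    """Gene symbol carried by a feature record, if any."""
    if isinstance(feature, GeneModel):
        return feature.name
    if isinstance(feature, Promoter):
        return feature.gene
    return None


@dataclass
class Node:
    """A network vertex: a merged-anchor or open-chromatin interval."""

    id: int
    interval: GenomicInterval
    source: str = "merged_anchors"  # or "peak"
    component: Optional[int] = None


@dataclass(frozen=True)
class Edge:
    """An aggregated connection between two nodes.

    ``interaction_count`` is the number of input interactions collapsed
    onto this node pair; ``pet_count`` their summed paired-end tags.
    Stored with ``node_a < node_b``; self-loops are never stored.
    """

    node_a: int
    node_b: int
    interaction_count: int = 1
    pet_count: int = 1
    trans: bool = False

    def __post_init__(self) -> None:
        if self.node_a >= self.node_b:
            raise ValueError(
                f"edges require node_a < node_b, got ({self.node_a}, {self.node_b})"
            )
        if self.interaction_count < 1 or self.pet_count < 1:
            raise ValueError("interaction_count and pet_count must be >= 1")


@dataclass
class BuildStats:
    """Bookkeeping of where every input interaction went during a build.

    Invariant: ``input == used + pet_filtered + self_loop + unmapped``.
    """

    input: int = 0
    pet_filtered: int = 0
    self_loop: int = 0
    unmapped: int = 0
    used: int = 0

    @property
    def conserved(self) -> bool:
        return self.input == (
            self.used + self.pet_filtered + self.self_loop + self.unmapped
        )

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "pet_filtered": self.pet_filtered,
            "self_loop": self.self_loop,
            "unmapped": self.unmapped,
            "used": self.used,
        }


@dataclass
class Network:
    """A chromatin interaction network: interval nodes, weighted edges."""

    nodes: list[Node] = field(default_factory=list)
    edges: list[Edge] = field(default_factory=list)
    build_stats: BuildStats = field(default_factory=BuildStats)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [n.id for n in self.nodes]
        if ids != list(range(len(ids))):
            raise ValueError("node ids must be dense 0..N-1 in list order")
        for e in self.edges:
            if e.node_b >= len(self.nodes):
                raise ValueError(f"edge endpoint {e.node_b} is not a node id")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_components(self) -> int:
        labels = {n.component for n in self.nodes}
        labels.discard(None)
        return len(labels)

    def node_ids(self) -> range:
        return range(len(self.nodes))

    def edge_array(self) -> np.ndarray:
        """Edges as an (E, 2) int array of node ids; empty -> (0, 2)."""
        if not self.edges:
            return np.empty((0, 2), dtype=np.int64)
        return np.array([(e.node_a, e.node_b) for e in self.edges], dtype=np.int64)

    def to_networkx(self) -> nx.Graph:
        """The network as a simple undirected networkx graph.

        Node and edge attributes mirror the GML export.  The graph is
        rebuilt on every call; callers doing repeated traversals should
        hold on to the result.
        """
        g = nx.Graph()
        for n in self.nodes:
            g.add_node(
                n.id,
                chrom=n.interval.chrom,
                start=n.interval.start,
                end=n.interval.end,
                source=n.source,
                component=-1 if n.component is None else n.component,
            )
        for e in self.edges:
            g.add_edge(
                e.node_a,
                e.node_b,
                interaction_count=e.interaction_count,
                pet_count=e.pet_count,
                trans=int(e.trans),
            )
        return g

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=np.int64)
        for e in self.edges:
            deg[e.node_a] += 1
            deg[e.node_b] += 1
        return deg
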