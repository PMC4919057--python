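"""Synthetic interaction datasets with known ground truth.

The generator lays out toy chromosomes with non-overlapping 1 kb node
loci on a 6 kb pitch, so that a +/-2 kb promoter window around a locus
midpoint can never straddle two loci.  It emits every input format the
toolkit reads — paired interactions (BEDPE), open-chromatin peaks
(BED), variant tables, gene tables, gene lists and gene-pair lists —
together with the planted truth: the number of connected components and
a set of variant -> gene paths at exact hop distances.

Random components are spanning trees plus density-controlled extra
edges; planted paths live in dedicated path-graph components, one per
planted (variant, gene, hop) triple, so their shortest-path distances
are exact by construction.  PET counts are geometric, mimicking the
heavy-tailed tag support of real paired-end interaction calls.

Everything is driven by one seed; identical seeds give byte-identical
files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import GeneModel, GenomicInterval, Interaction, Variant

__all__ = ["FixtureSpec", "FixtureData", "generate", "generate_fixture"]

NODE_WIDTH = 1000
PITCH = 6000  # node start-to-start distance; leaves a 5 kb gap
_CHROMS = ("chr1", "chr2", "chr3")


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``planted_paths`` entries are (variant id, gene name, hop distance);
    each becomes its own path-graph component whose first node holds the
    variant and whose node at the given hop distance holds the gene's
    TSS.
    """

    n_components: int = 4
    nodes_per_component: tuple[int, int] = (3, 6)
    edge_density: float = 0.3
    pet_geom_p: float = 0.4
    anchor_width_bp: tuple[int, int] = (200, 800)
    n_variants: int = 10
    n_genes: int = 15
    n_peaks: int = 5  # decoy peaks overlapping no anchor
    planted_paths: tuple[tuple[str, str, int], ...] = (
        ("NCV_D1", "GENE_D1", 1),
        ("NCV_D3", "GENE_D3", 3),
    )
    promoter_flank_bp: int = 2000
    self_loop_rate: float = 0.15
    duplicate_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.nodes_per_component
        if self.n_components < 0 or lo < 2 or hi < lo:
            raise ValueError("nodes_per_component must satisfy 2 <= lo <= hi")
        if not 0 < self.edge_density <= 1:
            raise ValueError("edge_density must be in (0, 1]")
        for vid, gene, hop in self.planted_paths:
            if hop < 0:
                raise ValueError(f"planted hop for {vid} must be >= 0")
            if hop + 1 > hi:
                raise ValueError(
                    f"planted path {vid}->{gene} needs {hop + 1} nodes but "
                    f"components allow at most {hi}"
                )


@dataclass
class FixtureData:
    """In-memory fixture: all inputs plus the planted ground truth."""

    interactions: list[Interaction]
    peaks: list[GenomicInterval]
    variants: list[Variant]
    genes: list[GeneModel]
    gene_list: list[str]
    gene_pairs: list[tuple[str, str]]
    truth: dict
    spec: FixtureSpec


def _sample_anchor(
    rng: np.random.Generator, node: GenomicInterval, width_range: tuple[int, int]
) -> GenomicInterval:
    """A random sub-interval of ``node`` containing the locus midpoint.

    Anchors of one locus therefore pairwise overlap, so approach-1
    anchor merging recovers exactly one node per locus.
    """
    mid = node.start + NODE_WIDTH // 2
    w_lo, w_hi = width_range
    w = int(rng.integers(max(2, w_lo), min(w_hi, NODE_WIDTH - 1) + 1))
    l_min = max(1, w - (node.end - 1 - mid))
    l_max = min(w - 1, mid - node.start)
    left = int(rng.integers(l_min, l_max + 1))
    return GenomicInterval(node.chrom, mid - left, mid - left + w)


def _component_edges(rng: np.random.Generator, n: int, density: float) -> list[tuple[int, int]]:
    """Random connected simple graph: spanning tree + extra edges."""
    edges = {(int(rng.integers(0, k)), k) for k in range(1, n)}
    for a in range(n):
        for b in range(a + 1, n):
            if (a, b) not in edges and rng.random() < density:
                edges.add((a, b))
    return sorted(edges)


def generate(spec: FixtureSpec) -> FixtureData:
    """Generate one synthetic dataset in memory."""
    rng = np.random.default_rng(spec.seed)
    offsets = {c: 10000 for c in _CHROMS}

    components: list[dict] = []  # {'nodes': [iv], 'edges': [(i,j)], 'planted': ...}
    for vid, gene, hop in spec.planted_paths:
        n = hop + 1
        components.append(
            {"n": n, "edges": [(i, i + 1) for i in range(n - 1)], "planted": (vid, gene, hop)}
        )
    for _ in range(spec.n_components):
        n = int(rng.integers(spec.nodes_per_component[0], spec.nodes_per_component[1] + 1))
        components.append({"n": n, "edges": _component_edges(rng, n, spec.edge_density), "planted": None})

    gaps: list[tuple[str, int]] = []  # (chrom, gap-center position)
    for ci, comp in enumerate(components):
        chrom = _CHROMS[ci % len(_CHROMS)]
        start = offsets[chrom]
        comp["nodes"] = [
            GenomicInterval(chrom, start + j * PITCH, start + j * PITCH + NODE_WIDTH)
            for j in range(comp["n"])
        ]
        gaps.extend(
            (chrom, start + j * PITCH + NODE_WIDTH + 2500) for j in range(comp["n"])
        )
        offsets[chrom] = start + comp["n"] * PITCH + PITCH

    interactions: list[Interaction] = []
    for comp in components:
        nodes = comp["nodes"]
        for a, b in comp["edges"]:
            n_rep = 1 + int(rng.random() < spec.duplicate_rate)
            for _ in range(n_rep):
                interactions.append(
                    Interaction(
                        _sample_anchor(rng, nodes[a], spec.anchor_width_bp),
                        _sample_anchor(rng, nodes[b], spec.anchor_width_bp),
                        pet_count=int(rng.geometric(spec.pet_geom_p)),
                    )
                )
        # occasional intra-node interaction: exercises self-loop accounting
        # and materializes single-node planted components
        if len(nodes) == 1 or rng.random() < spec.self_loop_rate:
            node = nodes[int(rng.integers(0, len(nodes)))]
            interactions.append(
                Interaction(
                    _sample_anchor(rng, node, spec.anchor_width_bp),
                    _sample_anchor(rng, node, spec.anchor_width_bp),
                    pet_count=int(rng.geometric(spec.pet_geom_p)),
                )
            )

    variants: list[Variant] = []
    genes: list[GeneModel] = []
    planted_truth = []
    for comp in components:
        if comp["planted"] is None:
            continue
        vid, gene_name, hop = comp["planted"]
        src = comp["nodes"][0]
        variants.append(Variant(src.chrom, src.start + NODE_WIDTH // 2, vid))
        tgt = comp["nodes"][hop]
        tss = tgt.start + NODE_WIDTH // 2
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            model = GeneModel(gene_name, tgt.chrom, "+", tss, tss + 1500)
        else:
            model = GeneModel(gene_name, tgt.chrom, "-", tss - 1499, tss + 1)
        genes.append(model)
        planted_truth.append({"variant": vid, "gene": gene_name, "hop": hop})

    # background variants and genes live at gap centers: they overlap no
    # node locus, so planted counts stay exact
    for i in range(spec.n_variants):
        chrom, center = gaps[int(rng.integers(0, len(gaps)))]
        variants.append(Variant(chrom, center + int(rng.integers(-400, 401)), f"BGV{i}"))
    for i in range(spec.n_genes):
        chrom, center = gaps[i % len(gaps)]
        tss = center + (37 * (i // len(gaps))) % 400
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            genes.append(GeneModel(f"BGGENE{i}", chrom, "+", tss, tss + 1200))
        else:
            genes.append(GeneModel(f"BGGENE{i}", chrom, "-", tss - 1199, tss + 1))

    peaks = [iv for comp in components for iv in comp["nodes"]]
    for i in range(spec.n_peaks):
        chrom, center = gaps[(7 * i + 3) % len(gaps)]
        peaks.append(GenomicInterval(chrom, center - 1200, center - 700))
    peaks.sort(key=lambda iv: (iv.chrom, iv.start))

    planted_names = [g for _, g, _ in spec.planted_paths]
    gene_list = planted_names[::2] + [f"BGGENE{i}" for i in range(0, spec.n_genes, 3)]
    gene_pairs = [
        (planted_names[i], planted_names[(i + 1) % len(planted_names)])
        for i in range(len(planted_names) - 1)
    ]

    truth = {
        "n_components": len(components),
        "n_nodes": sum(c["n"] for c in components),
        "n_edges": sum(len(c["edges"]) for c in components),
        "planted": planted_truth,
    }
    return FixtureData(
        interactions=interactions,
        peaks=peaks,
        variants=variants,
        genes=genes,
        gene_list=gene_list,
        gene_pairs=gene_pairs,
        truth=truth,
        spec=spec,
    )


def generate_fixture(spec: FixtureSpec, outdir: str | Path) -> dict[str, Path]:
    """Generate a dataset and write it as flat files under ``outdir``.

    Files: interactions.bedpe (anchor order randomized to exercise
    reader canonicalization), peaks.bed, variants.tsv, genes.tsv,
    gene_list.txt, gene_pairs.tsv, truth.json.  Byte-identical for a
    fixed seed.
    """
    data = generate(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / fname for name, fname in [
        ("interactions", "interactions.bedpe"),
        ("peaks", "peaks.bed"),
        ("variants", "variants.tsv"),
        ("genes", "genes.tsv"),
        ("gene_list", "gene_list.txt"),
        ("gene_pairs", "gene_pairs.tsv"),
        ("truth", "truth.json"),
    ]}

    swap_rng = np.random.default_rng(spec.seed + 1)
    with open(paths["interactions"], "w") as fh:
        for it in data.interactions:
            a, b = it.anchor1, it.anchor2
            if swap_rng.random() < 0.5:
                a, b = b, a
            fh.write(
                f"{a.chrom}\t{a.start}\t{a.end}\t{b.chrom}\t{b.start}\t{b.end}\t{it.pet_count}\n"
            )
    with open(paths["peaks"], "w") as fh:
        fh.write("track name=synthetic_open_chromatin\n")
        for iv in data.peaks:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(paths["variants"], "w") as fh:
        for v in data.variants:
            fh.write(f"{v.chrom}\t{v.pos}\t{v.id}\n")
    with open(paths["genes"], "w") as fh:
        fh.write("\t".join(["name", "chrom", "strand", "txStart", "txEnd"]) + "\n")
        for g in data.genes:
            fh.write(f"{g.name}\t{g.chrom}\t{g.strand}\t{g.tx_start}\t{g.tx_end}\n")
    with open(paths["gene_list"], "w") as fh:
        fh.writelines(name + "\n" for name in data.gene_list)
    with open(paths["gene_pairs"], "w") as fh:
        fh.writelines(f"{a}\t{b}\n" for a, b in data.gene_pairs)
    with open(paths["truth"], "w") as fh:
        json.dump(data.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
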