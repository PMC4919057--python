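"""Readers and writers for the flat-file formats the toolkit consumes.

Supported inputs: BEDPE-dialect paired interactions, BED3+ peaks, variant
tables (chrom, pos[, id]), refGene-style gene tables, plain gene lists and
two-column gene-pair lists.  Outputs: GML networks, CSV target tables.

Every reader normalizes coordinates to 0-based half-open intervals.
Chromosome names are compared as exact strings; ``normalize_chrom`` can
strip or add a "chr" prefix when mixed conventions must be reconciled.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import networkx as nx

from .core import (
    BuildStats,
    Edge,
    GeneModel,
    GenomicInterval,
    Interaction,
    Network,
    Node,
    Variant,
    feature_gene,
    feature_label,
)

__all__ = [
    "read_interactions",
    "write_interactions",
    "read_bed",
    "write_bed",
    "read_variants",
    "read_gene_table",
    "read_gene_list",
    "read_gene_pairs",
    "write_gml",
    "read_gml",
    "write_target_table",
    "normalize_chrom",
]

_HEADER_PREFIXES = ("track", "browser", "#")


def normalize_chrom(chrom: str, style: str = "chr") -> str:
    """Force a chromosome name into the ``chr``-prefixed or bare style."""
    if style == "chr":
        return chrom if chrom.startswith("chr") else "chr" + chrom
    if style == "bare":
        return chrom[3:] if chrom.startswith("chr") else chrom
    raise ValueError(f"unknown chromosome style {style!r}")


def _is_header(line: str) -> bool:
    return line.startswith(_HEADER_PREFIXES)


def read_interactions(
    path: str | Path, dialect: str = "bedpe"
) -> list[Interaction]:
    """Read paired-anchor interactions from a BEDPE-dialect file.

    Both dialects (``bedpe`` and ``chiapet_tool``) are tab-separated
    ``chrom1 start1 end1 chrom2 start2 end2 pet_count [score]``; the
    ``chiapet_tool`` dialect is accepted as the same 7-column superset.
    A missing 7th column defaults pet_count to 1 with a warning.  Anchors
    are stored canonically ordered.  Malformed lines raise ``ValueError``
    naming the line number.
    """
    if dialect not in ("bedpe", "chiapet_tool"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[Interaction] = []
    warned_pet = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header(line):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 6 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                a1 = GenomicInterval(fields[0], int(fields[1]), int(fields[2]))
                a2 = GenomicInterval(fields[3], int(fields[4]), int(fields[5]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if len(fields) >= 7 and fields[6] != "":
                try:
                    pet = int(fields[6])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: PET count {fields[6]!r} is not an integer"
                    ) from exc
            else:
                if not warned_pet:
                    warnings.warn(
                        f"{path}: no PET-count column; defaulting pet_count=1",
                        stacklevel=2,
                    )
                    warned_pet = True
                pet = 1
            if pet < 1:
                raise ValueError(f"{path}:{lineno}: pet_count must be >= 1, got {pet}")
            score = None
            if len(fields) >= 8 and fields[7] != "":
                try:
                    score = float(fields[7])
                except ValueError:
                    score = None
            out.append(Interaction(a1, a2, pet_count=pet, score=score))
    return out


def write_interactions(interactions: Iterable[Interaction], path: str | Path) -> None:
    """Write interactions as 7/8-column BEDPE (anchors in canonical order)."""
    with open(path, "w") as fh:
        for it in interactions:
            cols = [
                it.anchor1.chrom,
                str(it.anchor1.start),
                str(it.anchor1.end),
                it.anchor2.chrom,
                str(it.anchor2.start),
                str(it.anchor2.end),
                str(it.pet_count),
            ]
            if it.score is not None:
                cols.append(repr(it.score))
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3+ intervals; track/browser/# header lines are skipped."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header(line):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 3 columns, got {len(fields)}"
                )
            try:
                out.append(GenomicInterval(fields[0], int(fields[1]), int(fields[2])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def read_variants(path: str | Path) -> list[Variant]:
    """Read a variant table: tab-separated ``chrom pos [id]``, 0-based."""
    out: list[Variant] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or _is_header(line):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 2 columns, got {len(fields)}"
                )
            vid = fields[2] if len(fields) >= 3 and fields[2] else None
            try:
                out.append(Variant(fields[0], int(fields[1]), vid))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return out


_GENE_COLUMNS = ("name", "chrom", "strand", "txStart", "txEnd")


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read a refGene-style gene table.

    The file is tab-separated with columns ``name chrom strand txStart
    txEnd``, either in that order (headerless) or identified by a header
    line.  Duplicate ``(name, chrom, tx_start)`` rows are dropped.
    """
    models: list[GeneModel] = []
    seen: set[tuple] = set()
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        return models
    idx = dict(zip(_GENE_COLUMNS, range(5)))
    body = lines
    first = lines[0].lstrip("#").split("\t")
    if set(_GENE_COLUMNS) <= set(first):
        idx = {c: first.index(c) for c in _GENE_COLUMNS}
        body = lines[1:]
    for lineno, line in enumerate(body, start=2 if body is not lines else 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 5:
            raise ValueError(
                f"{path}:{lineno}: expected >= 5 columns, got {len(fields)}"
            )
        strand = fields[idx["strand"]]
        if strand not in ("+", "-"):
            raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
        try:
            model = GeneModel(
                name=fields[idx["name"]],
                chrom=fields[idx["chrom"]],
                strand=strand,
                tx_start=int(fields[idx["txStart"]]),
                tx_end=int(fields[idx["txEnd"]]),
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        key = (model.name, model.chrom, model.tx_start)
        if key not in seen:
            seen.add(key)
            models.append(model)
    return models


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain one-gene-per-line list (order kept, duplicates dropped)."""
    out: list[str] = []
    seen: set[str] = set()
    with open(path) as fh:
        for raw in fh:
            name = raw.strip()
            if not name or name.startswith("#"):
                continue
            if name not in seen:
                seen.add(name)
                out.append(name)
    return out


def read_gene_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a two-column gene-pair list (e.g. protein-protein pairs)."""
    pairs: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated gene names"
                )
            pairs.append((fields[0], fields[1]))
    return pairs


def write_gml(network: Network, path: str | Path) -> None:
    """Export a network as Graph Modelling Language.

    Node attributes: chrom, start, end, source, component, annotations (a
    semicolon-joined ``set:feature`` string).  Edge attributes:
    interaction_count, pet_count, trans (0/1).  Build statistics are
    stored as graph attributes so :func:`read_gml` can restore them.
    """
    g = network.to_networkx()
    for name, ann in network.annotations.items():
        for node_id, records in ann.node_hits.items():
            tags = [f"{name}:{feature_label(r)}" for r in records]
            prev = g.nodes[node_id].get("annotations", "")
            joined = ";".join(filter(None, [prev, *tags]))
            g.nodes[node_id]["annotations"] = joined
    for node_id in g.nodes:
        g.nodes[node_id].setdefault("annotations", "")
    for key, value in network.build_stats.to_dict().items():
        g.graph[f"stats_{key}"] = value
    nx.write_gml(g, str(path))


def read_gml(path: str | Path) -> Network:
    """Read a network previously written by :func:`write_gml`.

    Third-party GML graphs load too provided each node carries chrom,
    start and end attributes.  Annotation strings are not re-expanded
    into AnnotationSets.
    """
    g = nx.read_gml(str(path), label="id")
    nodes = []
    for node_id in sorted(g.nodes):
        data = g.nodes[node_id]
        comp = data.get("component", -1)
        nodes.append(
            Node(
                id=int(node_id),
                interval=GenomicInterval(
                    data["chrom"], int(data["start"]), int(data["end"])
                ),
                source=data.get("source", "merged_anchors"),
                component=None if comp == -1 else int(comp),
            )
        )
    edges = []
    for u, v, data in g.edges(data=True):
        a, b = sorted((int(u), int(v)))
        edges.append(
            Edge(
                node_a=a,
                node_b=b,
                interaction_count=int(data.get("interaction_count", 1)),
                pet_count=int(data.get("pet_count", 1)),
                trans=bool(data.get("trans", 0)),
            )
        )
    edges.sort(key=lambda e: (e.node_a, e.node_b))
    stats = BuildStats(
        **{k: int(g.graph.get(f"stats_{k}", 0)) for k in
           ("input", "pet_filtered", "self_loop", "unmapped", "used")}
    )
    return Network(nodes=nodes, edges=edges, build_stats=stats)


_TARGET_COLUMNS = [
    "source_node",
    "source_annotation",
    "target_node",
    "target_gene",
    "hop_distance",
    "path",
    "classification",
]


def write_target_table(
    paths: Sequence,
    path: str | Path,
    direct_max: int = 1,
    indirect_range: tuple[int, int] = (2, 4),
) -> None:
    """Write discovered target paths as CSV.

    One row per (target path, target gene); genes come from the target
    node's feature records.  Tied shortest paths are joined with ``|``
    inside the path column; node ids within a path with ``->``.  Rows are
    sorted by (source_node, hop_distance, target_node, target_gene).
    """
    rows = []
    for tp in paths:
        src_label = ",".join(
            sorted(feature_label(f) for f in tp.source_features)
        )
        genes = sorted(
            {g for f in tp.target_features if (g := feature_gene(f)) is not None}
        ) or [""]
        path_str = "|".join("->".join(map(str, p)) for p in tp.paths)
        if tp.hop_distance <= direct_max:
            cls = "direct"
        elif indirect_range[0] <= tp.hop_distance <= indirect_range[1]:
            cls = "indirect"
        else:
            cls = "beyond"
        for gene in genes:
            rows.append(
                (
                    tp.source_node,
                    src_label,
                    tp.target_node,
                    gene,
                    tp.hop_distance,
                    path_str,
                    cls,
                )
            )
    rows.sort(key=lambda r: (r[0], r[4], r[2], r[3]))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TARGET_COLUMNS)
        writer.writerows(rows)
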