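"""Enrichment of interactions between annotation classes.

Tests whether edges connecting two sets of annotated nodes (say, nodes
harboring variants and nodes overlapping enhancers) occur more often
than chance.  Two nulls are offered:

* a **theoretical** null in which each edge is an independent uniform
  draw of an unordered node pair, giving a closed-form per-edge
  probability and a one-tailed binomial p-value;
* a **permutation** null that shuffles the annotation labels over nodes
  — never rewiring edges — preserving the two set sizes and their
  overlap, with the add-one empirical p-value
  (1 + #{permuted >= observed}) / (n_perms + 1), which can never be 0.

Gene-list enrichment of discovered targets uses the one-tailed
(hypergeometric) Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import AnnotationSet
from .core import Network

__all__ = [
    "EnrichmentResult",
    "FisherResult",
    "observed_pair_frequency",
    "expected_pair_probability",
    "binomial_pvalue",
    "permutation_null",
    "pairwise_enrichment",
    "fisher_enrichment",
]

NodeSet = Union[AnnotationSet, Iterable[int]]


def _as_node_set(ann: NodeSet) -> set[int]:
    return ann.nodes() if isinstance(ann, AnnotationSet) else set(ann)


@dataclass
class EnrichmentResult:
    """Observed vs expected interaction frequency for an annotation pair."""

    annotation_a: str
    annotation_b: str
    observed: int
    n_edges: int
    p_theoretical: float
    p_binomial: float
    perm_null: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    p_permutation: float = float("nan")
    n_perms: int = 0
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "annotation_a": self.annotation_a,
            "annotation_b": self.annotation_b,
            "observed": self.observed,
            "n_edges": self.n_edges,
            "p_theoretical": self.p_theoretical,
            "p_binomial": self.p_binomial,
            "p_permutation": self.p_permutation,
            "n_perms": self.n_perms,
            "seed": self.seed,
        }


@dataclass
class FisherResult:
    """One-tailed Fisher's exact test of target/reference gene overlap."""

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    p_value: float


def observed_pair_frequency(network: Network, ann_a: NodeSet, ann_b: NodeSet) -> int:
    """Count edges with one endpoint in A and the other in B.

    Each edge counts at most once; for A = B this is the number of edges
    with both endpoints in A.
    """
    a = _as_node_set(ann_a)
    b = _as_node_set(ann_b)
    count = 0
    for e in network.edges:
        u, v = e.node_a, e.node_b
        if (u in a and v in b) or (u in b and v in a):
            count += 1
    return count


def expected_pair_probability(
    n_nodes: int, n_a: int, n_b: int, overlap_ab: Optional[int] = None
) -> float:
    """Probability that a uniform random unordered node pair is an A-B pair.

    Exact enumeration: qualifying pairs / C(N, 2), where the number of
    unordered pairs {u, v} with u in A, v in B (or vice versa) is
    ``n_a*n_b - o - C(o, 2)`` with o = |A ∩ B|.  For identical sets
    (o = n_a = n_b) this reduces to C(n_a, 2) / C(N, 2); for disjoint
    sets to n_a*n_b / C(N, 2).
    """
    if n_nodes < 2:
        raise ValueError(f"need >= 2 nodes, got {n_nodes}")
    if not (0 <= n_a <= n_nodes and 0 <= n_b <= n_nodes):
        raise ValueError("annotation sizes exceed node count")
    if overlap_ab is None:
        overlap_ab = n_a if n_a == n_b else 0
    if overlap_ab > min(n_a, n_b):
        raise ValueError("overlap larger than a set")
    qualifying = n_a * n_b - overlap_ab - comb(overlap_ab, 2)
    return qualifying / comb(n_nodes, 2)


def binomial_pvalue(observed: int, n_edges: int, p: float) -> float:
    """Upper-tail binomial probability P(X >= observed), X ~ Bin(n, p)."""
    if not 0 <= observed <= n_edges:
        raise ValueError(f"observed must be in [0, {n_edges}], got {observed}")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n_edges, p))


def permutation_null(
    network: Network,
    ann_a: NodeSet,
    ann_b: NodeSet,
    n_perms: int = 1000,
    seed: int = 0,
    name_a: str = "A",
    name_b: str = "B",
) -> EnrichmentResult:
    """Full enrichment test for one annotation pair.

    Each permutation pushes both label sets through one uniform random
    permutation of the node ids (preserving |A|, |B| and |A ∩ B|) and
    recounts A-B edges; edges are never rewired.  The empirical p-value
    uses the add-one estimator, so it is bounded below by
    1/(n_perms + 1).  The theoretical (binomial) p-value is computed
    alongside.
    """
    if n_perms < 1:
        raise ValueError(f"n_perms must be >= 1, got {n_perms}")
    if isinstance(ann_a, AnnotationSet):
        name_a = ann_a.name
    if isinstance(ann_b, AnnotationSet):
        name_b = ann_b.name
    a = _as_node_set(ann_a)
    b = _as_node_set(ann_b)
    n = network.n_nodes
    observed = observed_pair_frequency(network, a, b)
    p_theo = expected_pair_probability(n, len(a), len(b), len(a & b)) if n >= 2 else 0.0
    p_binom = binomial_pvalue(observed, network.n_edges, p_theo)

    edge_arr = network.edge_array()
    u, v = edge_arr[:, 0], edge_arr[:, 1]
    a_mask = np.zeros(n, dtype=bool)
    b_mask = np.zeros(n, dtype=bool)
    a_mask[list(a)] = True
    b_mask[list(b)] = True
    rng = np.random.default_rng(seed)
    null = np.empty(n_perms, dtype=np.int64)
    for i in range(n_perms):
        perm = rng.permutation(n)
        pa = a_mask[perm]
        pb = b_mask[perm]
        null[i] = int(np.count_nonzero((pa[u] & pb[v]) | (pb[u] & pa[v])))
    p_perm = (1 + int(np.count_nonzero(null >= observed))) / (n_perms + 1)
    return EnrichmentResult(
        annotation_a=name_a,
        annotation_b=name_b,
        observed=observed,
        n_edges=network.n_edges,
        p_theoretical=p_theo,
        p_binomial=p_binom,
        perm_null=null,
        p_permutation=p_perm,
        n_perms=n_perms,
        seed=seed,
    )


def pairwise_enrichment(
    network: Network,
    annotations: Sequence[AnnotationSet],
    n_perms: int = 1000,
    seed: int = 0,
    include_self_pairs: bool = True,
) -> pd.DataFrame:
    """Enrichment tests for every annotation pair, with BH-FDR columns.

    The Benjamini-Hochberg correction across the tested pairs is an
    extension beyond the single-pair tests; both raw and adjusted
    p-values are reported.
    """
    from statsmodels.stats.multitest import multipletests

    results = []
    pairs = []
    for i, ann_i in enumerate(annotations):
        for j in range(i if include_self_pairs else i + 1, len(annotations)):
            pairs.append((ann_i, annotations[j]))
    for k, (ann_i, ann_j) in enumerate(pairs):
        res = permutation_null(
            network, ann_i, ann_j, n_perms=n_perms, seed=seed + k
        )
        results.append(res.to_dict())
    df = pd.DataFrame(results)
    if not df.empty:
        for col in ("p_binomial", "p_permutation"):
            df[f"{col}_fdr"] = multipletests(df[col], method="fdr_bh")[1]
    return df


def fisher_enrichment(
    target_genes: Iterable[str],
    reference_list: Iterable[str],
    universe: Iterable[str],
) -> FisherResult:
    """One-tailed Fisher's exact test for reference-gene enrichment.

    Tests whether discovered target genes over-represent a curated
    reference list against a gene universe (default in callers: all
    genes annotated onto the network).  The 2x2 table is
    [[targets ∩ list, targets \\ list], [list \\ targets, neither]].
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    targets = set(target_genes)
    reference = set(reference_list)
    if not targets <= universe or not reference <= universe:
        raise ValueError("target and reference gene sets must be within the universe")
    k = len(targets & reference)
    table = (
        (k, len(targets) - k),
        (len(reference) - k, len(universe) - len(targets) - len(reference) + k),
    )
    odds, p = stats.fisher_exact(table, alternative="greater")
    return FisherResult(table=table, odds_ratio=float(odds), p_value=float(p))
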