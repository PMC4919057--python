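"""Shared construction helpers for the test suite."""

import numpy as np

from chianet.core import Edge, GenomicInterval, Network, Node


def network_from_graph(n, edges, component_labels=False):
    """A Network over n abstract nodes with the given simple edge list.

    Node intervals are dummy non-overlapping 500 bp spans on chr1.
    """
    nodes = [
        Node(i, GenomicInterval("chr1", 10_000 + i * 1000, 10_000 + i * 1000 + 500))
        for i in range(n)
    ]
    uniq = sorted({(min(a, b), max(a, b)) for a, b in edges})
    net = Network(nodes=nodes, edges=[Edge(a, b) for a, b in uniq])
    if component_labels:
        from chianet.network_build import connected_components

        for node, label in zip(net.nodes, connected_components(net)):
            node.component = label
    return net


def random_graph(rng, n, p):
    """Erdős–Rényi G(n, p) edge list."""
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(iu.size) < p
    return list(zip(iu[mask].tolist(), ju[mask].tolist()))


def random_intervals(rng, n, chroms=("chr1", "chr2"), span=5000, max_width=300):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(0, span))
        width = int(rng.integers(1, max_width))
        out.append(GenomicInterval(chrom, start, start + width))
    return out
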