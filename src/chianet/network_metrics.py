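"""Node centrality measures on the interaction network.

The graph is treated as simple and unweighted: distances are hop
counts, and PET counts never enter the shortest-path computations (the
biology of "one edge away" / "2-4 edges away" is hop-based).

Conventions:

* degree — number of incident edges (not PET-weighted);
* betweenness — shortest-path betweenness, each unordered pair (s, t)
  counted once, fractional (Brandes) credit split among tied shortest
  paths; unnormalized by default, optionally normalized within each
  component by (k-1)(k-2)/2;
* closeness — component-scoped: (k-1) / sum of distances to the other
  k-1 nodes of the component; isolated nodes score 0;
* harmonic — network-scoped mean reciprocal distance,
  (1/(N-1)) * sum 1/d(v, u) with 1/inf = 0, which stays meaningful on
  disconnected graphs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from .core import Network

__all__ = [
    "degree",
    "betweenness",
    "closeness",
    "harmonic_centrality",
    "centrality_report",
]


def degree(network: Network) -> dict[int, int]:
    """Number of incident edges per node."""
    return {i: int(d) for i, d in enumerate(network.degrees())}


def betweenness(network: Network, normalized: bool = False) -> dict[int, float]:
    """Shortest-path betweenness per node.

    Unnormalized: the (fractionally credited) number of shortest paths
    through the node, each unordered pair counted once.  With
    ``normalized=True`` each value is divided by (k-1)(k-2)/2 where k is
    the node's component size (0 where k < 3).
    """
    g = network.to_networkx()
    raw = nx.betweenness_centrality(g, normalized=False)
    if not normalized:
        return {v: float(b) for v, b in raw.items()}
    comp_size: dict[int, int] = {}
    for comp in nx.connected_components(g):
        for v in comp:
            comp_size[v] = len(comp)
    out = {}
    for v, b in raw.items():
        k = comp_size.get(v, 1)
        denom = (k - 1) * (k - 2) / 2
        out[v] = float(b) / denom if denom > 0 else 0.0
    return out


def closeness(network: Network) -> dict[int, float]:
    """Component-scoped closeness centrality per node.

    (k-1) / sum of hop distances within the node's component of size k;
    0 for isolated nodes.
    """
    g = network.to_networkx()
    return {v: float(c) for v, c in nx.closeness_centrality(g, wf_improved=False).items()}


def harmonic_centrality(network: Network) -> dict[int, float]:
    """Network-scoped harmonic centrality per node.

    (1/(N-1)) * sum over u != v of 1/d(v, u), unreachable nodes
    contributing 0.  Defined as 0 for a single-node network.
    """
    n = network.n_nodes
    if n <= 1:
        return {v: 0.0 for v in network.node_ids()}
    g = network.to_networkx()
    raw = nx.harmonic_centrality(g)
    return {v: float(h) / (n - 1) for v, h in raw.items()}


def centrality_report(network: Network, normalized_betweenness: bool = False) -> pd.DataFrame:
    """All four centralities plus node metadata, one row per node."""
    deg = degree(network)
    btw = betweenness(network, normalized=normalized_betweenness)
    clo = closeness(network)
    har = harmonic_centrality(network)
    rows = []
    for node in network.nodes:
        rows.append(
            {
                "node": node.id,
                "chrom": node.interval.chrom,
                "start": node.interval.start,
                "end": node.interval.end,
                "component": node.component,
                "degree": deg[node.id],
                "betweenness": btw[node.id],
                "closeness": clo[node.id],
                "harmonic": har[node.id],
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "node",
            "chrom",
            "start",
            "end",
            "component",
            "degree",
            "betweenness",
            "closeness",
            "harmonic",
        ],
    )
    assert np.isfinite(df[["betweenness", "closeness", "harmonic"]].to_numpy()).all()
    return df
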