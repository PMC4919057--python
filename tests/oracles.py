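"""Independent brute-force oracles used to check the implementation.

Everything here is deliberately naive — O(n^2) scans, exhaustive path
enumeration, direct hypergeometric summation — and shares no code with
the package paths it validates.
"""

from collections import deque
from math import comb


class UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra

    def groups(self):
        out = {}
        for i in range(len(self.parent)):
            out.setdefault(self.find(i), []).append(i)
        return sorted(out.values(), key=min)


def merge_by_unionfind(intervals):
    """Merged intervals via union-find over all pairwise overlaps."""
    n = len(intervals)
    uf = UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = intervals[i], intervals[j]
            if a.chrom == b.chrom and a.start < b.end and b.start < a.end:
                uf.union(i, j)
    spans = []
    for group in uf.groups():
        ivs = [intervals[k] for k in group]
        spans.append(
            (ivs[0].chrom, min(iv.start for iv in ivs), max(iv.end for iv in ivs))
        )
    return sorted(spans)


def components_by_unionfind(n, edges):
    """Component label per node, labels ordered by smallest member id."""
    uf = UnionFind(n)
    for a, b in edges:
        uf.union(a, b)
    labels = [0] * n
    for lab, group in enumerate(uf.groups()):
        for v in group:
            labels[v] = lab
    return labels


def brute_overlaps(query, subject):
    return sorted(
        (i, j)
        for i, q in enumerate(query)
        for j, s in enumerate(subject)
        if q.chrom == s.chrom and q.start < s.end and s.start < q.end
    )


def bfs_distances(adj, start):
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def all_shortest_paths(adj, s, t):
    """Every shortest s->t path by exhaustive BFS-bounded DFS."""
    dist = bfs_distances(adj, s)
    if t not in dist:
        return []
    target_len = dist[t]
    paths = []

    def walk(node, path):
        if len(path) - 1 > target_len:
            return
        if node == t and len(path) - 1 == target_len:
            paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    walk(s, [s])
    return sorted(paths)


def brute_centralities(n, edges):
    """degree / betweenness / closeness / harmonic by exhaustive
    enumeration of all shortest paths between all pairs."""
    adj = {v: [] for v in range(n)}
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    deg = {v: len(adj[v]) for v in range(n)}
    dists = {v: bfs_distances(adj, v) for v in range(n)}

    btw = {v: 0.0 for v in range(n)}
    for s in range(n):
        for t in range(s + 1, n):
            paths = all_shortest_paths(adj, s, t)
            if not paths:
                continue
            for path in paths:
                for mid in path[1:-1]:
                    btw[mid] += 1.0 / len(paths)

    clo = {}
    har = {}
    for v in range(n):
        reach = {u: d for u, d in dists[v].items() if u != v}
        clo[v] = len(reach) / sum(reach.values()) if reach else 0.0
        har[v] = (
            sum(1.0 / d for d in reach.values()) / (n - 1) if n > 1 else 0.0
        )
    return deg, btw, clo, har


def hypergeom_upper_tail(N, K, n, k):
    """P(X >= k), X ~ Hypergeom(N, K, n), by direct summation."""
    total = comb(N, n)
    return sum(
        comb(K, j) * comb(N - K, n - j)
        for j in range(k, min(n, K) + 1)
        if n - j <= N - K
    ) / total


def binom_upper_tail(k, n, p):
    """P(X >= k), X ~ Binomial(n, p), by direct summation."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))
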