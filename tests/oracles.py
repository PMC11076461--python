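"""Independent brute-force oracles for tree metrics and spanning trees.

Deliberately naive: paths are enumerated pair by pair with BFS, the MST
optimum is found by scoring every spanning tree from its Prüfer sequence,
and assortativity is a direct Pearson computation on the doubled edge list.
These never call the package's own implementations.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def prufer_to_edges(seq: tuple[int, ...]) -> list[tuple[int, int]]:
    """Decode a Prüfer sequence over nodes 0..n-1 (n = len(seq) + 2)."""
    import heapq

    n = len(seq) + 2
    degree = [1] * n
    for v in seq:
        degree[v] += 1
    edges = []
    heap = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(heap)
    for v in seq:
        u = heapq.heappop(heap)
        edges.append((min(u, v), max(u, v)))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(heap, v)
    u = heapq.heappop(heap)
    v = heapq.heappop(heap)
    edges.append((min(u, v), max(u, v)))
    return edges


def all_trees(n: int):
    """Yield the edge lists of all n^(n-2) labeled trees on n nodes."""
    if n == 2:
        yield [(0, 1)]
        return
    for seq in itertools.product(range(n), repeat=n - 2):
        yield prufer_to_edges(seq)


def _adjacency(n: int, edges) -> list[list[int]]:
    adj = [[] for _ in range(n)]
    for a, b in edges:
        adj[a].append(b)
        adj[b].append(a)
    return adj


def bfs_path(adj, s: int, t: int) -> list[int]:
    """The unique path between s and t in a tree, via BFS back-pointers."""
    prev = {s: None}
    q = deque([s])
    while q:
        u = q.popleft()
        if u == t:
            break
        for v in adj[u]:
            if v not in prev:
                prev[v] = u
                q.append(v)
    path = [t]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return path[::-1]


def brute_betweenness(n: int, edges) -> list[float]:
    """Fraction of node pairs whose connecting path transits each node."""
    adj = _adjacency(n, edges)
    counts = [0] * n
    for s, t in itertools.combinations(range(n), 2):
        for v in bfs_path(adj, s, t)[1:-1]:
            counts[v] += 1
    denom = (n - 1) * (n - 2) / 2
    return [c / denom if denom > 0 else 0.0 for c in counts]


def brute_diameter_normalized(n: int, edges) -> float:
    adj = _adjacency(n, edges)
    longest = max(
        len(bfs_path(adj, s, t)) - 1 for s, t in itertools.combinations(range(n), 2)
    )
    return longest / (n - 1)


def brute_leaf_fraction(n: int, edges) -> float:
    deg = [0] * n
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return sum(1 for d in deg if d == 1) / n


def brute_assortativity(n: int, edges) -> float | None:
    """Pearson correlation of endpoint degrees over the doubled edge list."""
    deg = [0] * n
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    xs, ys = [], []
    for a, b in edges:
        xs += [deg[a], deg[b]]
        ys += [deg[b], deg[a]]
    mx = sum(xs) / len(xs)
    my = sum(ys) / len(ys)
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    if sxx == 0 or syy == 0:
        return None
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    return sxy / math.sqrt(sxx * syy)


def exhaustive_max_spanning_tree_weight(weights) -> float:
    """Maximum total weight over every spanning tree (Prüfer enumeration)."""
    n = len(weights)
    return max(
        sum(weights[a][b] for a, b in edges) for edges in all_trees(n)
    )
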