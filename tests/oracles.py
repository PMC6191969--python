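"""Independent reference implementations used only for cross-checking.

These deliberately share no code with the package kernels: plain queue BFS,
binary-heap Dijkstra, and a textbook |V|-1-sweep Bellman-Ford over
adjacency lists built straight from the edge table.  SCC ground truth comes
from networkx (Tarjan-style).
"""

from __future__ import annotations

import heapq
import math
from collections import deque

import networkx as nx

from frontiernet.graph_core import CSRGraph


def adjacency(g: CSRGraph) -> list[list[tuple[int, float]]]:
    return [list(g.arcs(u)) for u in range(g.num_vertices)]


def queue_bfs(g: CSRGraph, source: int) -> list[float]:
    """Plain FIFO-queue BFS; unreachable = inf."""
    adj = adjacency(g)
    depth = [math.inf] * g.num_vertices
    depth[source] = 0
    q = deque([source])
    while q:
        u = q.popleft()
        for v, _ in adj[u]:
            if depth[v] == math.inf:
                depth[v] = depth[u] + 1
                q.append(v)
    return depth


def dijkstra(g: CSRGraph, source: int) -> list[float]:
    """Binary-heap Dijkstra (non-negative weights); unreachable = inf."""
    adj = adjacency(g)
    dist = [math.inf] * g.num_vertices
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, u = heapq.heappop(heap)
        if d > dist[u]:
            continue
        for v, w in adj[u]:
            nd = d + w
            if nd < dist[v]:
                dist[v] = nd
                heapq.heappush(heap, (nd, v))
    return dist


def bellman_ford(g: CSRGraph, source: int) -> list[float]:
    """Textbook |V|-1 full-sweep Bellman-Ford; raises on a reachable
    negative cycle."""
    arcs = [
        (u, v, w) for u in range(g.num_vertices) for v, w in g.arcs(u)
    ]
    dist = [math.inf] * g.num_vertices
    dist[source] = 0.0
    for _ in range(max(0, g.num_vertices - 1)):
        changed = False
        for u, v, w in arcs:
            if dist[u] + w < dist[v]:
                dist[v] = dist[u] + w
                changed = True
        if not changed:
            break
    for u, v, w in arcs:
        if dist[u] + w < dist[v] - 1e-12:
            raise ValueError("negative cycle")
    return dist


def to_nx(g: CSRGraph) -> nx.DiGraph:
    """Arc set as a simple networkx digraph (parallel arcs collapse; that
    is irrelevant for reachability/SCC questions)."""
    G = nx.DiGraph()
    G.add_nodes_from(range(g.num_vertices))
    for u in range(g.num_vertices):
        for v, _ in g.arcs(u):
            G.add_edge(u, v)
    return G


def scc_partition(g: CSRGraph) -> set[frozenset[int]]:
    """True SCC partition (networkx Tarjan-family oracle)."""
    return {frozenset(c) for c in nx.strongly_connected_components(to_nx(g))}


def labels_to_partition(labels) -> set[frozenset[int]]:
    comps: dict[int, set[int]] = {}
    for v, c in enumerate(labels):
        comps.setdefault(int(c), set()).add(v)
    return {frozenset(s) for s in comps.values()}
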