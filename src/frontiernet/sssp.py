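"""Frontier-based Bellman-Ford single-source shortest paths.

Per pass, the arcs leaving every frontier vertex are relaxed:
``dist[v] <- min(dist[v], dist[u] + w)``.  The next frontier contains all
and only the vertices whose tentative distance improved during the pass —
these are the vertices whose outgoing arcs must be re-examined.  The loop
ends when a pass improves nothing, i.e. the frontier empties.

Negative arc weights are accepted (Bellman-Ford semantics).  A negative
cycle reachable from the source makes improvement never stop; the frontier
being non-empty after ``|V|`` full passes proves one exists, and the solver
raises rather than return an ill-defined "shortest" path.

Relaxation sweeps the frontier in ascending vertex order and reads the
distance array live (Gauss-Seidel style); convergence is to the same fixed
point as a frozen-snapshot sweep, in no more passes.  The recorded
predecessor for a vertex with several equal-cost parents is whichever wrote
last in this canonical order — implementation-defined but deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .graph_core import CSRGraph

__all__ = ["UNREACHED", "NO_PRED", "SsspResult", "relax_frontier", "sssp"]

#: Distance sentinel for vertices with no path from the source.
UNREACHED: float = np.inf

#: Predecessor sentinel for the source itself and for unreached vertices.
NO_PRED: int = -1


@dataclass(frozen=True)
class SsspResult:
    """Shortest-path matrices: one row per source.

    ``distances[i][v]`` is the minimum total arc weight over paths
    ``sources[i] -> v`` (``inf`` if unreachable).  ``predecessors`` (when
    requested) holds the parent of ``v`` on one optimal path, ``NO_PRED``
    at the source and at unreached vertices.
    """

    distances: np.ndarray
    predecessors: np.ndarray | None
    sources: np.ndarray


def relax_frontier(
    g: CSRGraph,
    f1: np.ndarray,
    dist: np.ndarray,
    pred: np.ndarray,
) -> np.ndarray:
    """Relax all arcs leaving the frontier; return the improved vertices.

    ``dist`` and ``pred`` are updated in place.  The returned frontier is
    duplicate-free and ascending.
    """
    f1 = np.sort(np.asarray(f1, dtype=np.int64))
    changed = np.zeros(g.num_vertices, dtype=bool)
    offsets, targets, weights = g.offsets, g.targets, g.weights
    for u in f1:
        du = dist[u]
        for k in range(offsets[u], offsets[u + 1]):
            v = targets[k]
            nd = du + weights[k]
            if nd < dist[v]:
                dist[v] = nd
                pred[v] = u
                changed[v] = True
    return np.nonzero(changed)[0].astype(np.int64)


def sssp(
    g: CSRGraph,
    sources: Sequence[int],
    want_predecessors: bool = True,
    on_pass: Callable[[int, int, np.ndarray], None] | None = None,
) -> SsspResult:
    """Bellman-Ford shortest paths from each source.

    Parameters
    ----------
    g
        Graph in CSR form; weights may be negative.
    sources
        Vertex ids; duplicates allowed.
    want_predecessors
        When False, only the distance matrix is kept (``predecessors`` is
        None in the result).
    on_pass
        Optional hook called as ``on_pass(source_row, pass_index, frontier)``
        with the frontier produced by that relaxation pass.

    Raises
    ------
    ValueError
        ``"negative cycle reachable from source"`` when the frontier is
        still non-empty after ``|V|`` full passes.
    """
    src = np.asarray(list(sources), dtype=np.int64)
    if src.size and (src.min() < 0 or src.max() >= g.num_vertices):
        bad = src[(src < 0) | (src >= g.num_vertices)][0]
        raise ValueError(
            f"invalid vertex id: {int(bad)} not in [0, {g.num_vertices})"
        )
    n = g.num_vertices
    distances = np.full((src.size, n), UNREACHED, dtype=np.float64)
    predecessors = np.full((src.size, n), NO_PRED, dtype=np.int64)
    for i, s in enumerate(src):
        dist = distances[i]
        pred = predecessors[i]
        dist[s] = 0.0
        f1 = np.asarray([s], dtype=np.int64)
        passes = 0
        while f1.size:
            if passes >= n:
                raise ValueError("negative cycle reachable from source")
            f1 = relax_frontier(g, f1, dist, pred)
            passes += 1
            if on_pass is not None:
                on_pass(i, passes, f1)
        pred[s] = NO_PRED  # a negative-weight arc back into s must not linger
    return SsspResult(
        distances, predecessors if want_predecessors else None, src
    )


def reconstruct_path(
    result: SsspResult, row: int, target: int
) -> list[int] | None:
    """Walk predecessor links back from ``target``; None if unreached.

    Returns the vertex sequence source .. target.
    """
    if result.predecessors is None:
        raise ValueError("result was computed without predecessors")
    if not np.isfinite(result.distances[row, target]):
        return None
    path = [int(target)]
    v = int(target)
    src = int(result.sources[row])
    n = result.distances.shape[1]
    while v != src:
        v = int(result.predecessors[row, v])
        if v == NO_PRED or len(path) > n:
            raise RuntimeError("broken predecessor chain")
        path.append(v)
    path.reverse()
    return path
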