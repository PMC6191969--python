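"""Level-synchronous frontier-based breadth-first search.

The traversal keeps two frontiers: ``f1`` holds the vertices visited at the
current level, ``f2`` collects their not-yet-visited neighbours.  After each
propagation step ``f2`` is deduplicated (several frontier vertices may reach
the same neighbour in one step) and swapped into ``f1``.  Depth is hop count;
weights are ignored.  The multi-source entry point returns an ``s x |V|``
depth matrix, one row per requested source.

Unreachable vertices carry the :data:`UNREACHED` sentinel (the maximal int64,
serialised as ``"inf"`` by the I/O layer).  Frontiers are emitted in
ascending vertex order, which makes every run deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .graph_core import CSRGraph

__all__ = ["UNREACHED", "DepthMatrix", "bfs_step", "bfs_multi"]

#: Depth sentinel for vertices with no path from the source.
UNREACHED: int = np.iinfo(np.int64).max


@dataclass(frozen=True)
class DepthMatrix:
    """BFS result: ``depths[i][v]`` = hop distance from ``sources[i]`` to ``v``.

    Entries for unreachable vertices equal :data:`UNREACHED`.
    """

    depths: np.ndarray
    sources: np.ndarray

    def as_float(self) -> np.ndarray:
        """Depths as float64 with ``inf`` in place of the sentinel."""
        out = self.depths.astype(np.float64)
        out[self.depths == UNREACHED] = np.inf
        return out


def _gather_neighbors(g: CSRGraph, frontier: np.ndarray) -> np.ndarray:
    """Concatenated targets of all arcs leaving the frontier vertices."""
    starts = g.offsets[frontier]
    counts = g.offsets[frontier + 1] - starts
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    # flat arc indices: per-frontier-vertex ranges laid end to end
    base = np.repeat(starts, counts)
    within = np.arange(total, dtype=np.int64) - np.repeat(
        np.cumsum(counts) - counts, counts
    )
    return g.targets[base + within]


def bfs_step(
    g: CSRGraph,
    f1: np.ndarray,
    visited: np.ndarray,
    depths: np.ndarray,
    level: int,
) -> np.ndarray:
    """One frontier propagation step.

    Every member of ``f1`` must already be visited with depth ``level``.
    All unvisited neighbours of ``f1`` are assigned depth ``level + 1``,
    marked visited, and returned as the next frontier ``f2`` — deduplicated
    and in ascending vertex order.  ``visited`` and ``depths`` are updated
    in place.
    """
    f1 = np.asarray(f1, dtype=np.int64)
    nbrs = _gather_neighbors(g, f1)
    fresh = nbrs[~visited[nbrs]]
    f2 = np.unique(fresh)  # duplicate filtering + canonical order
    visited[f2] = True
    depths[f2] = level + 1
    return f2


def bfs_multi(
    g: CSRGraph,
    sources: Sequence[int],
    on_level: Callable[[int, int, np.ndarray], None] | None = None,
) -> DepthMatrix:
    """Multi-source BFS: one independent level-synchronous sweep per source.

    Parameters
    ----------
    g
        Graph in CSR form.
    sources
        Vertex ids; duplicates allowed (rows are independent).
    on_level
        Optional instrumentation hook called as
        ``on_level(source_row, level, frontier)`` with the frontier *at* that
        level (so level 0 reports ``[source]``).

    Returns
    -------
    DepthMatrix
        ``depths[i][v]`` = minimum number of arcs from ``sources[i]`` to
        ``v``; :data:`UNREACHED` where no path exists.
    """
    src = np.asarray(list(sources), dtype=np.int64)
    if src.size and (src.min() < 0 or src.max() >= g.num_vertices):
        bad = src[(src < 0) | (src >= g.num_vertices)][0]
        raise ValueError(
            f"invalid vertex id: {int(bad)} not in [0, {g.num_vertices})"
        )
    depths = np.full((src.size, g.num_vertices), UNREACHED, dtype=np.int64)
    for i, s in enumerate(src):
        visited = np.zeros(g.num_vertices, dtype=bool)
        visited[s] = True
        depths[i, s] = 0
        f1 = np.asarray([s], dtype=np.int64)
        level = 0
        while f1.size:
            if on_level is not None:
                on_level(i, level, f1)
            f1 = bfs_step(g, f1, visited, depths[i], level)
            level += 1
    return DepthMatrix(depths, src)
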