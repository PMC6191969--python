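"""Edge-table (COO) and compressed-sparse-row graph core.

Graphs enter the toolkit as an edge table: a flat list of
``(source, target, weight)`` records over 0-based contiguous integer
vertex ids (string labels are resolved to indices by :mod:`frontiernet.cli_io`).
Every traversal kernel runs on the CSR form produced by :func:`build_csr`,
which concatenates per-vertex adjacency into ``targets``/``weights`` arrays
indexed by an ``offsets`` array of length ``num_vertices + 1``.

Conventions
-----------
* Parallel edges are kept, never collapsed; collapsing would silently
  change shortest-path semantics.
* Self-loops are kept.
* Undirected graphs are stored as symmetric directed CSR: each input
  record ``(u, v, w)`` with ``u != v`` contributes the two arcs
  ``(u, v, w)`` and ``(v, u, w)``; self-loops are stored once.
* Canonical adjacency order: within each vertex slice, targets ascending,
  ties between parallel edges broken by weight ascending.  This makes
  graph equality well defined and traversal output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "EdgeTable",
    "CSRGraph",
    "validate_edges",
    "build_csr",
    "transpose",
    "induced_subgraph",
]


@dataclass(frozen=True)
class EdgeTable:
    """COO-style edge list: parallel arrays of sources, targets, weights.

    ``num_vertices`` fixes the vertex universe; isolated vertices (ids never
    appearing in a record) are legitimate members of the graph.
    """

    sources: np.ndarray
    targets: np.ndarray
    weights: np.ndarray
    num_vertices: int

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[int, int, float]],
        num_vertices: int | None = None,
    ) -> "EdgeTable":
        """Build an edge table from ``(source, target, weight)`` triples.

        When ``num_vertices`` is omitted it is inferred as ``max id + 1``
        (0 for an empty record list).
        """
        recs = list(records)
        if recs:
            src = np.asarray([r[0] for r in recs], dtype=np.int64)
            tgt = np.asarray([r[1] for r in recs], dtype=np.int64)
            w = np.asarray(
                [r[2] if len(r) > 2 else 1.0 for r in recs], dtype=np.float64
            )
        else:
            src = np.empty(0, dtype=np.int64)
            tgt = np.empty(0, dtype=np.int64)
            w = np.empty(0, dtype=np.float64)
        if num_vertices is None:
            num_vertices = int(max(src.max(), tgt.max())) + 1 if recs else 0
        return cls(src, tgt, w, int(num_vertices))

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sources", np.asarray(self.sources, dtype=np.int64)
        )
        object.__setattr__(
            self, "targets", np.asarray(self.targets, dtype=np.int64)
        )
        object.__setattr__(
            self, "weights", np.asarray(self.weights, dtype=np.float64)
        )

    def __len__(self) -> int:
        return self.sources.size

    @property
    def records(self) -> Iterator[tuple[int, int, float]]:
        """Iterate records as plain Python tuples."""
        for s, t, w in zip(self.sources, self.targets, self.weights):
            yield int(s), int(t), float(w)


def validate_edges(edges: EdgeTable) -> EdgeTable:
    """Check vertex-id bounds and weight finiteness; return the table unchanged.

    Raises
    ------
    ValueError
        ``"invalid vertex id"`` for a negative or out-of-range endpoint,
        ``"invalid weight"`` for a NaN or infinite weight.
    """
    n = edges.num_vertices
    if n < 0:
        raise ValueError("invalid vertex id: num_vertices must be non-negative")
    for arr in (edges.sources, edges.targets):
        if arr.size and (arr.min() < 0 or arr.max() >= n):
            bad = arr[(arr < 0) | (arr >= n)][0]
            raise ValueError(f"invalid vertex id: {int(bad)} not in [0, {n})")
    if edges.weights.size and not np.all(np.isfinite(edges.weights)):
        bad = edges.weights[~np.isfinite(edges.weights)][0]
        raise ValueError(f"invalid weight: {bad!r} is not finite")
    return edges


@dataclass(eq=False)
class CSRGraph:
    """Compressed-sparse-row digraph with per-arc weights.

    ``offsets[u]:offsets[u+1]`` indexes the arcs leaving vertex ``u`` in
    ``targets`` and ``weights``.  ``directed=False`` records only that the
    graph was built from undirected input; the arc set is always symmetric
    in that case and traversal kernels treat every graph as directed.
    """

    num_vertices: int
    offsets: np.ndarray
    targets: np.ndarray
    weights: np.ndarray
    directed: bool = True

    @property
    def num_edges(self) -> int:
        """Number of stored arcs (mirror arcs counted individually)."""
        return int(self.targets.size)

    @cached_property
    def arc_sources(self) -> np.ndarray:
        """Per-arc source vertex, aligned with ``targets``/``weights``."""
        return np.repeat(
            np.arange(self.num_vertices, dtype=np.int64),
            np.diff(self.offsets),
        )

    def out_degree(self, u: int) -> int:
        return int(self.offsets[u + 1] - self.offsets[u])

    def neighbors(self, u: int) -> np.ndarray:
        """Targets of arcs leaving ``u``, in canonical ascending order."""
        return self.targets[self.offsets[u] : self.offsets[u + 1]]

    def arcs(self, u: int) -> Iterator[tuple[int, float]]:
        """Iterate ``(target, weight)`` pairs of arcs leaving ``u``."""
        lo, hi = int(self.offsets[u]), int(self.offsets[u + 1])
        for k in range(lo, hi):
            yield int(self.targets[k]), float(self.weights[k])

    def to_edge_table(self) -> EdgeTable:
        """Export the stored arc multiset as an edge table (arcs, not records)."""
        return EdgeTable(
            self.arc_sources.copy(),
            self.targets.copy(),
            self.weights.copy(),
            self.num_vertices,
        )

    def equal(self, other: "CSRGraph") -> bool:
        """Exact equality of the canonical arc structure."""
        return (
            self.num_vertices == other.num_vertices
            and np.array_equal(self.offsets, other.offsets)
            and np.array_equal(self.targets, other.targets)
            and np.array_equal(self.weights, other.weights)
        )


def _csr_from_arcs(
    num_vertices: int,
    src: np.ndarray,
    tgt: np.ndarray,
    w: np.ndarray,
    directed: bool,
) -> CSRGraph:
    """Assemble canonical CSR from a finished arc list (no mirroring here)."""
    order = np.lexsort((w, tgt, src))
    src, tgt, w = src[order], tgt[order], w[order]
    counts = np.bincount(src, minlength=num_vertices)
    offsets = np.zeros(num_vertices + 1, dtype=np.int64)
    np.cumsum(counts, out=offsets[1:])
    return CSRGraph(num_vertices, offsets, tgt, w, directed)


def build_csr(edges: EdgeTable, directed: bool = True) -> CSRGraph:
    """Convert a validated edge table to canonical CSR.

    For undirected input every record ``(u, v, w)`` with ``u != v`` is
    mirrored into the arc pair ``(u, v, w)`` / ``(v, u, w)``; self-loops are
    stored once.
    """
    validate_edges(edges)
    src, tgt, w = edges.sources, edges.targets, edges.weights
    if not directed:
        mirror = src != tgt
        src = np.concatenate([src, tgt[mirror]])
        tgt_new = np.concatenate([tgt, edges.sources[mirror]])
        w = np.concatenate([w, edges.weights[mirror]])
        tgt = tgt_new
    return _csr_from_arcs(edges.num_vertices, src.copy(), tgt.copy(), w.copy(), directed)


def transpose(g: CSRGraph) -> CSRGraph:
    """Reverse every arc: ``(u, v, w)`` becomes ``(v, u, w)``.

    An involution on canonical form; preserves vertex and arc counts.
    """
    return _csr_from_arcs(
        g.num_vertices,
        g.targets.copy(),
        g.arc_sources.copy(),
        g.weights.copy(),
        g.directed,
    )


def induced_subgraph(
    g: CSRGraph, vertices: Iterable[int]
) -> tuple[CSRGraph, dict[int, int]]:
    """Subgraph induced by ``vertices``, relabelled to ``0..k-1``.

    An arc survives iff both endpoints are kept.  New ids follow ascending
    old-id order, so keeping all vertices yields the identity relabelling.

    Returns the new graph and the old-id -> new-id mapping.
    """
    keep = np.unique(np.asarray(list(vertices), dtype=np.int64))
    if keep.size and (keep.min() < 0 or keep.max() >= g.num_vertices):
        bad = keep[(keep < 0) | (keep >= g.num_vertices)][0]
        raise ValueError(
            f"invalid vertex id: {int(bad)} not in [0, {g.num_vertices})"
        )
    new_id = np.full(g.num_vertices, -1, dtype=np.int64)
    new_id[keep] = np.arange(keep.size, dtype=np.int64)
    src = g.arc_sources
    mask = (new_id[src] >= 0) & (new_id[g.targets] >= 0)
    sub = _csr_from_arcs(
        int(keep.size),
        new_id[src[mask]],
        new_id[g.targets[mask]],
        g.weights[mask].copy(),
        g.directed,
    )
    mapping = {int(old): int(new_id[old]) for old in keep}
    return sub, mapping
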