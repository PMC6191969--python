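"""Strongly-connected-component decomposition: trim, forward-backward, coloring.

The decomposition runs in three phases:

1. **Trimming** — repeatedly remove active vertices with no active successor
   or no active predecessor; each is a trivial singleton SCC.  A DAG is fully
   resolved by this phase alone.
2. **Forward-backward** — pick a pivot (maximum active in-degree x out-degree
   product, smallest index on ties), compute its forward and backward
   reachability closures within the current vertex set.  Their intersection
   is the pivot's SCC; the three residual sets (forward-only, backward-only,
   untouched) are SCC-closed and recurse independently.  The number of
   rounds is a parameter; correctness never depends on it.
3. **Coloring** — on whatever remains: give every vertex its own index as a
   color, propagate the maximum color along arcs to a fixed point; each
   vertex keeping its own color is a pivot, and the backward closure within
   its color class is one SCC.  Repeat until no active vertex is left.

Component ids are canonicalised to the smallest vertex index in each
component, so the output is independent of how work was split between the
phases.

Self-loop convention: a self-loop counts as neither an active predecessor
nor an active successor for the trimming test, so a vertex whose only cycle
is its own self-loop is still trimmed as a trivial singleton SCC.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .graph_core import CSRGraph, transpose

__all__ = [
    "trim",
    "select_pivot",
    "forward_backward",
    "coloring_decompose",
    "scc",
]

UNLABELED: int = -1


def _active_degrees(
    g: CSRGraph, active: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Active out-/in-degree per vertex, counting arcs with both endpoints
    active and excluding self-loops."""
    src, tgt = g.arc_sources, g.targets
    live = active[src] & active[tgt] & (src != tgt)
    out_deg = np.bincount(src[live], minlength=g.num_vertices)
    in_deg = np.bincount(tgt[live], minlength=g.num_vertices)
    return out_deg, in_deg


def trim(
    g: CSRGraph,
    gT: CSRGraph,
    active: np.ndarray,
    labels: np.ndarray,
) -> int:
    """Phase 1: iterated removal of trivial singleton SCCs.

    Any active vertex whose active out-degree or active in-degree is zero
    cannot lie on a cycle within the active set; it is labelled as its own
    singleton component and deactivated.  Removal cascades until no vertex
    qualifies.  ``active`` and ``labels`` are updated in place; returns the
    number of vertices trimmed.
    """
    trimmed = 0
    while True:
        if not active.any():
            break
        out_deg, in_deg = _active_degrees(g, active)
        kill = active & ((out_deg == 0) | (in_deg == 0))
        k = int(kill.sum())
        if k == 0:
            break
        labels[kill] = np.nonzero(kill)[0]
        active[kill] = False
        trimmed += k
    return trimmed


def select_pivot(
    g: CSRGraph, gT: CSRGraph, active_subset: Iterable[int]
) -> int:
    """Pivot heuristic: maximise active in-degree x out-degree product.

    A high-degree pivot tends to cover many vertices with one pair of
    closures.  Ties break to the smallest vertex index.
    """
    subset = np.unique(np.asarray(list(active_subset), dtype=np.int64))
    if subset.size == 0:
        raise ValueError("empty pivot set")
    mask = np.zeros(g.num_vertices, dtype=bool)
    mask[subset] = True
    out_deg, in_deg = _active_degrees(g, mask)
    product = out_deg[subset].astype(np.int64) * in_deg[subset]
    return int(subset[np.argmax(product)])  # argmax -> first = smallest index


def _closure(g: CSRGraph, mask: np.ndarray, start: int) -> np.ndarray:
    """Vertices reachable from ``start`` along arcs staying inside ``mask``."""
    seen = np.zeros(g.num_vertices, dtype=bool)
    seen[start] = True
    stack = [int(start)]
    targets, offsets = g.targets, g.offsets
    while stack:
        u = stack.pop()
        for k in range(offsets[u], offsets[u + 1]):
            v = int(targets[k])
            if mask[v] and not seen[v]:
                seen[v] = True
                stack.append(v)
    return seen


def forward_backward(
    g: CSRGraph,
    gT: CSRGraph,
    subset: Iterable[int],
    pivot: int,
) -> tuple[set[int], set[int], set[int], set[int]]:
    """Phase 2 split: 4-way partition of ``subset`` around ``pivot``.

    Returns ``(scc, fwd_only, bwd_only, remainder)`` where ``scc`` is the
    intersection of the pivot's forward and backward closures (its SCC) and
    the other three sets are SCC-closed and can be processed independently.
    """
    subset = set(int(v) for v in subset)
    if int(pivot) not in subset:
        raise ValueError("invalid pivot: not a member of the subset")
    mask = np.zeros(g.num_vertices, dtype=bool)
    mask[list(subset)] = True
    fwd = _closure(g, mask, pivot)
    bwd = _closure(gT, mask, pivot)
    scc_set = set(np.nonzero(fwd & bwd)[0].tolist())
    fwd_only = set(np.nonzero(fwd & ~bwd)[0].tolist())
    bwd_only = set(np.nonzero(bwd & ~fwd)[0].tolist())
    remainder = subset - scc_set - fwd_only - bwd_only
    return scc_set, fwd_only, bwd_only, remainder


def coloring_decompose(
    g: CSRGraph,
    gT: CSRGraph,
    active: np.ndarray,
    labels: np.ndarray,
) -> None:
    """Phase 3: max-color propagation until every active vertex is labelled.

    Each round: colors start as vertex indices; the maximum color is
    propagated to active successors to a fixed point; every vertex whose
    color is unchanged is a pivot, and the backward closure restricted to
    its color class is one SCC.  Updates ``active``/``labels`` in place.
    """
    n = g.num_vertices
    src_all, tgt_all = g.arc_sources, g.targets
    while active.any():
        colors = np.arange(n, dtype=np.int64)
        live = active[src_all] & active[tgt_all]
        src, tgt = src_all[live], tgt_all[live]
        while True:
            before = colors[tgt].copy()
            np.maximum.at(colors, tgt, colors[src])
            if np.array_equal(colors[tgt], before):
                break
        pivots = np.nonzero(active & (colors == np.arange(n)))[0]
        for p in pivots:
            class_mask = active & (colors == p)
            comp = _closure(gT, class_mask, int(p))
            labels[comp] = p
            active[comp] = False


def scc(g: CSRGraph, fb_rounds: int = 1) -> np.ndarray:
    """Full three-phase SCC decomposition.

    Parameters
    ----------
    g
        Directed graph in CSR form.  A symmetric (undirected-origin) graph
        decomposes into its connected components.
    fb_rounds
        Number of forward-backward rounds before the coloring phase takes
        over (default 1).  Any value >= 0 yields the same partition.

    Returns
    -------
    numpy.ndarray
        Per-vertex component ids; each id is the smallest vertex index in
        its component.
    """
    if fb_rounds < 0:
        raise ValueError("fb_rounds must be non-negative")
    n = g.num_vertices
    gT = transpose(g)
    active = np.ones(n, dtype=bool)
    labels = np.full(n, UNLABELED, dtype=np.int64)

    trim(g, gT, active, labels)

    worklist: list[np.ndarray] = []
    if active.any():
        worklist.append(np.nonzero(active)[0])
    for _ in range(fb_rounds):
        if not worklist:
            break
        next_wl: list[np.ndarray] = []
        for subset in worklist:
            mask = np.zeros(n, dtype=bool)
            mask[subset] = True
            trim(g, gT, mask, labels)  # sound on any SCC-closed set
            active[subset] &= mask[subset]
            remaining = np.nonzero(mask)[0]
            if remaining.size == 0:
                continue
            pivot = select_pivot(g, gT, remaining)
            comp, fwd_only, bwd_only, rest = forward_backward(
                g, gT, remaining, pivot
            )
            comp_idx = np.fromiter(comp, dtype=np.int64)
            labels[comp_idx] = pivot
            active[comp_idx] = False
            for part in (fwd_only, bwd_only, rest):
                if part:
                    next_wl.append(np.fromiter(sorted(part), dtype=np.int64))
        worklist = next_wl

    residue = np.zeros(n, dtype=bool)
    for subset in worklist:
        residue[subset] = True
    residue &= active
    if residue.any():
        coloring_decompose(g, gT, residue, labels)
        active &= residue  # all cleared by the coloring phase

    # canonicalise: component id = smallest member index
    canonical = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    np.minimum.at(canonical, labels, np.arange(n, dtype=np.int64))
    return canonical[labels]
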