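"""Seeded synthetic-data generators for every input class the toolkit consumes.

Everything here is deterministic given an integer seed (one
``numpy.random.default_rng`` per call, no global state):

* Erdős–Rényi G(n, p) graphs, directed or undirected;
* STRING-like interaction networks: preferential-attachment topology
  (heavy-tailed degrees, as in real PPI networks) with integer confidence
  scores uniform in a configurable range (default 1-999, mimicking
  STRING's 0-1000 combined scores);
* planted-SCC digraphs: blocks wired as directed cycles plus random
  intra-block arcs, with inter-block arcs only from earlier to later blocks,
  so the blocks are exactly the strongly connected components — ground
  truth for decomposition tests;
* correlated expression matrices: genes within a module share a latent
  sample factor mixed with independent noise, so within-module Pearson
  correlation is controlled by a single mixing coefficient (expected
  ``r = mixing**2``; ``mixing=1`` gives identical rows, ``r = 1`` exactly).

Defaults stay at desk scale (thousands of vertices, tens of thousands of
edges) — enough to exhibit frontier dynamics without full-organism networks.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .graph_core import EdgeTable
from .network_analysis import ExpressionMatrix

__all__ = [
    "gen_erdos_renyi",
    "gen_string_like",
    "gen_planted_scc",
    "gen_expression",
]


def gen_erdos_renyi(
    n: int,
    p: float,
    seed: int,
    directed: bool = False,
    weight: float = 1.0,
) -> EdgeTable:
    """G(n, p): each (ordered or unordered) vertex pair is an edge with
    probability ``p``; no self-loops.  All weights equal ``weight``."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"edge probability must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    if directed:
        src, tgt = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        src, tgt = src.ravel(), tgt.ravel()
        off_diag = src != tgt
        src, tgt = src[off_diag], tgt[off_diag]
    else:
        src, tgt = np.triu_indices(n, k=1)
    keep = rng.random(src.size) < p
    src, tgt = src[keep].astype(np.int64), tgt[keep].astype(np.int64)
    return EdgeTable(src, tgt, np.full(src.size, weight), num_vertices=n)


def gen_string_like(
    n: int,
    m: int = 3,
    seed: int = 0,
    weight_range: tuple[int, int] = (1, 999),
) -> EdgeTable:
    """Score-weighted interaction network with a heavy-tailed degree
    distribution.

    Preferential attachment: vertices arrive one at a time and connect to
    ``m`` distinct existing vertices chosen proportionally to current
    degree.  Undirected; edge scores are integers uniform in
    ``weight_range``.  ``m=1`` yields a tree with exactly ``n-1`` records.
    """
    if n < 2:
        raise ValueError("need at least 2 vertices")
    if not 1 <= m < n:
        raise ValueError(f"attachment count must satisfy 1 <= m < n, got {m}")
    rng = np.random.default_rng(seed)
    src: list[int] = []
    tgt: list[int] = []
    # degree-proportional sampling via the repeated-endpoints list
    repeated: list[int] = list(range(m))
    for v in range(m, n):
        chosen: set[int] = set()
        while len(chosen) < m:
            if v == m:  # first arrival: no degrees yet, choose uniformly
                chosen.add(int(rng.integers(0, m)))
            else:
                chosen.add(repeated[int(rng.integers(0, len(repeated)))])
        for u in sorted(chosen):
            src.append(v)
            tgt.append(u)
        repeated.extend(sorted(chosen))
        repeated.extend([v] * m)
    lo, hi = weight_range
    weights = rng.integers(lo, hi + 1, size=len(src)).astype(np.float64)
    return EdgeTable(
        np.asarray(src, dtype=np.int64),
        np.asarray(tgt, dtype=np.int64),
        weights,
        num_vertices=n,
    )


def gen_planted_scc(
    block_sizes: Sequence[int],
    seed: int,
    p_intra: float = 0.2,
    p_inter: float = 0.05,
) -> tuple[EdgeTable, np.ndarray]:
    """Digraph whose strongly connected components are planted blocks.

    Each block of size >= 2 is wired as a directed Hamiltonian cycle plus
    random intra-block arcs (probability ``p_intra`` per ordered pair);
    arcs between blocks run only from earlier to later blocks (probability
    ``p_inter``), so the between-block structure is acyclic and each block
    is exactly one SCC.

    Returns the edge table and the ground-truth component labels,
    canonicalised to each block's smallest vertex index.
    """
    block_sizes = list(block_sizes)
    if not block_sizes or any(b < 1 for b in block_sizes):
        raise ValueError("block sizes must be a non-empty list of ints >= 1")
    rng = np.random.default_rng(seed)
    n = int(sum(block_sizes))
    labels = np.empty(n, dtype=np.int64)
    src: list[int] = []
    tgt: list[int] = []
    starts = np.cumsum([0] + block_sizes[:-1])
    for start, size in zip(starts, block_sizes):
        members = np.arange(start, start + size)
        labels[members] = start
        if size >= 2:
            for i in range(size):  # Hamiltonian cycle keeps the block strong
                src.append(int(members[i]))
                tgt.append(int(members[(i + 1) % size]))
            uu, vv = np.meshgrid(members, members, indexing="ij")
            uu, vv = uu.ravel(), vv.ravel()
            off = uu != vv
            uu, vv = uu[off], vv[off]
            keep = rng.random(uu.size) < p_intra
            src.extend(uu[keep].tolist())
            tgt.extend(vv[keep].tolist())
    for a in range(len(block_sizes)):
        for b in range(a + 1, len(block_sizes)):
            ua = np.arange(starts[a], starts[a] + block_sizes[a])
            vb = np.arange(starts[b], starts[b] + block_sizes[b])
            uu, vv = np.meshgrid(ua, vb, indexing="ij")
            uu, vv = uu.ravel(), vv.ravel()
            keep = rng.random(uu.size) < p_inter
            src.extend(uu[keep].tolist())
            tgt.extend(vv[keep].tolist())
    edges = EdgeTable(
        np.asarray(src, dtype=np.int64),
        np.asarray(tgt, dtype=np.int64),
        np.ones(len(src), dtype=np.float64),
        num_vertices=n,
    )
    return edges, labels


def gen_expression(
    n_samples: int,
    module_assignments: Sequence[int],
    mixing: float,
    seed: int,
) -> ExpressionMatrix:
    """Expression matrix with planted coexpression modules.

    ``module_assignments[i]`` is the module id of gene ``i``; a negative id
    marks a background gene of pure independent noise.  A gene in module
    ``k`` is ``mixing * z_k + sqrt(1 - mixing**2) * eps`` with ``z_k`` a
    per-module latent factor and ``eps`` gene-specific standard-normal
    noise, so within-module correlation is ``mixing**2`` in expectation and
    exactly 1 when ``mixing = 1``.
    """
    if n_samples < 3:
        raise ValueError("insufficient samples: need at least 3")
    if not 0.0 <= mixing <= 1.0:
        raise ValueError(f"mixing must be in [0, 1], got {mixing}")
    assignments = np.asarray(list(module_assignments), dtype=np.int64)
    n_genes = assignments.size
    rng = np.random.default_rng(seed)
    modules = np.unique(assignments[assignments >= 0])
    factors = {int(k): rng.standard_normal(n_samples) for k in modules}
    noise_scale = float(np.sqrt(max(0.0, 1.0 - mixing**2)))
    values = np.empty((n_genes, n_samples), dtype=np.float64)
    for i, k in enumerate(assignments):
        eps = rng.standard_normal(n_samples)
        if k >= 0:
            values[i] = mixing * factors[int(k)] + noise_scale * eps
        else:
            values[i] = eps
    gene_labels = [f"G{i:04d}" for i in range(n_genes)]
    sample_labels = [f"S{j:03d}" for j in range(n_samples)]
    return ExpressionMatrix(values, gene_labels, sample_labels)
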