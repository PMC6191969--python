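"""Biological network workflows built on the traversal kernels.

Covers the recurring steps of interaction-network studies:

* confidence filtering of score-weighted networks (STRING-style integer
  scores, where raising the threshold yields sparser, higher-confidence
  networks);
* construction of a gene coexpression network from an expression matrix via
  pairwise Pearson correlation;
* extraction of the subnetwork (component) containing a seed gene — the
  guilt-by-association neighbourhood of, e.g., a lncRNA of interest;
* mean shortest-path distance statistics over a set of sources, computed
  within a subnetwork and over the whole graph.

Correlation edges carry the correlation coefficient ``r`` as weight; for
shortest-path use, the CLI offers the ``1 - |r|`` distance transform, since
path length over raw correlations is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph_core import CSRGraph, EdgeTable, induced_subgraph
from .sssp import sssp

__all__ = [
    "ExpressionMatrix",
    "PathStats",
    "score_filter",
    "correlation_network",
    "subnetwork_with_seed",
    "mean_shortest_path",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples expression values with row/column labels."""

    values: np.ndarray
    gene_labels: Sequence[str]
    sample_labels: Sequence[str]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "values", np.asarray(self.values, dtype=np.float64)
        )
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape[0] != len(self.gene_labels):
            raise ValueError("gene label count does not match row count")
        if self.values.shape[1] != len(self.sample_labels):
            raise ValueError("sample label count does not match column count")


@dataclass(frozen=True)
class PathStats:
    """Mean of finite source->target shortest-path distances.

    Pairs with ``target == source`` are excluded; unreachable pairs count
    toward ``n_pairs_total`` but not the mean.  ``mean_distance`` is NaN
    when no pair is finite.
    """

    mean_distance: float
    n_pairs_finite: int
    n_pairs_total: int


def score_filter(edges: EdgeTable, min_score: float) -> EdgeTable:
    """Keep records with weight >= ``min_score``.

    The vertex universe is unchanged: vertices whose every edge is dropped
    remain as isolated vertices, so ids and labels stay valid.
    """
    mask = edges.weights >= min_score
    return EdgeTable(
        edges.sources[mask],
        edges.targets[mask],
        edges.weights[mask],
        edges.num_vertices,
    )


def correlation_network(
    expr: ExpressionMatrix,
    threshold: float,
    mode: str = "absolute",
) -> EdgeTable:
    """Pearson pairwise-correlation network over the genes of ``expr``.

    For every unordered gene pair with a defined correlation ``r``, an
    undirected record weighted ``r`` is emitted when ``r >= threshold``
    (``mode="signed"``) or ``|r| >= threshold`` (``mode="absolute"``).
    Genes with zero variance, or with any missing value (listwise
    deletion), form no edges.  Vertex ids are gene row indices; the vertex
    universe spans all genes.

    Raises
    ------
    ValueError
        ``"insufficient samples"`` with fewer than 3 samples; also for a
        threshold outside [0, 1] or an unknown mode.
    """
    if expr.values.shape[1] < 3:
        raise ValueError("insufficient samples: need at least 3")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if mode not in ("signed", "absolute"):
        raise ValueError(f"mode must be 'signed' or 'absolute', got {mode!r}")
    x = expr.values
    usable = np.all(np.isfinite(x), axis=1) & (np.std(x, axis=1) > 0.0)
    idx = np.nonzero(usable)[0]
    src: list[int] = []
    tgt: list[int] = []
    wts: list[float] = []
    if idx.size >= 2:
        r = np.corrcoef(x[idx])
        np.clip(r, -1.0, 1.0, out=r)
        ii, jj = np.triu_indices(idx.size, k=1)
        vals = r[ii, jj]
        keep = (
            vals >= threshold if mode == "signed" else np.abs(vals) >= threshold
        )
        src = idx[ii[keep]].tolist()
        tgt = idx[jj[keep]].tolist()
        wts = vals[keep].tolist()
    return EdgeTable(
        np.asarray(src, dtype=np.int64),
        np.asarray(tgt, dtype=np.int64),
        np.asarray(wts, dtype=np.float64),
        num_vertices=x.shape[0],
    )


def subnetwork_with_seed(
    g: CSRGraph, labels: np.ndarray, seed: int
) -> tuple[CSRGraph, dict[int, int]]:
    """Induced subgraph of the component containing ``seed``.

    ``labels`` is a per-vertex component labelling — strongly connected
    components for a directed graph, which for a symmetric
    (undirected-origin) graph coincide with connected components.
    """
    if not 0 <= seed < g.num_vertices:
        raise ValueError(
            f"invalid vertex id: {seed} not in [0, {g.num_vertices})"
        )
    members = np.nonzero(np.asarray(labels) == labels[seed])[0]
    return induced_subgraph(g, members)


def mean_shortest_path(g: CSRGraph, sources: Sequence[int]) -> PathStats:
    """Mean shortest-path distance from ``sources`` to all other vertices.

    Runs Bellman-Ford per source and averages the finite distances over all
    ordered (source, target) pairs with ``target != source``.
    """
    result = sssp(g, sources, want_predecessors=False)
    dist = result.distances.copy()
    for i, s in enumerate(result.sources):
        dist[i, s] = np.inf  # exclude the trivial self pair
    finite = np.isfinite(dist)
    n_total = dist.shape[0] * (g.num_vertices - 1) if g.num_vertices else 0
    n_finite = int(finite.sum())
    mean = float(dist[finite].mean()) if n_finite else float("nan")
    return PathStats(mean, n_finite, n_total)
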