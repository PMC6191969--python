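"""Score filtering, coexpression networks, seed subnetworks, path statistics."""

import math

import numpy as np
import pytest

from frontiernet.graph_core import EdgeTable, build_csr
from frontiernet.network_analysis import (
    ExpressionMatrix,
    correlation_network,
    mean_shortest_path,
    score_filter,
    subnetwork_with_seed,
)
from frontiernet.scc import scc
from frontiernet.sssp import sssp


class TestScoreFilter:
    def test_keeps_records_at_or_above_threshold(self):
        e = EdgeTable.from_records(
            [(0, 1, 100.0), (1, 2, 250.0), (0, 2, 950.0)], 3
        )
        kept = score_filter(e, 200.0)
        assert len(kept) == 2
        assert kept.num_vertices == 3  # isolated vertices remain

    def test_zero_threshold_is_identity(self):
        e = EdgeTable.from_records([(0, 1, 5.0), (1, 2, 0.0)], 3)
        assert sorted(score_filter(e, 0.0).records) == sorted(e.records)

    def test_matches_linear_scan_on_stringlike_scores(self):
        rng = np.random.default_rng(42)
        w = rng.integers(1, 1000, size=500).astype(float)
        src = rng.integers(0, 100, size=500)
        tgt = rng.integers(0, 100, size=500)
        e = EdgeTable(src, tgt, w, 100)
        assert len(score_filter(e, 900.0)) == int((w >= 900).sum())

    def test_filter_composition_equals_max_threshold(self):
        rng = np.random.default_rng(7)
        e = EdgeTable(
            rng.integers(0, 20, 200),
            rng.integers(0, 20, 200),
            rng.uniform(0, 1000, 200),
            20,
        )
        a, b = 300.0, 650.0
        double = score_filter(score_filter(e, a), b)
        single = score_filter(e, max(a, b))
        assert sorted(double.records) == sorted(single.records)


def _expr(values, n_samples=None):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        values,
        [f"g{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
    )


class TestCorrelationNetwork:
    def test_identical_rows_are_perfectly_correlated(self):
        e = _expr([[1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]])
        net = correlation_network(e, 1.0)
        assert len(net) == 1
        assert net.weights[0] == pytest.approx(1.0)

    def test_signed_mode_drops_anticorrelated_pair(self):
        e = _expr([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        assert len(correlation_network(e, 0.5, mode="signed")) == 0
        assert len(correlation_network(e, 0.5, mode="absolute")) == 1

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            correlation_network(_expr([[1.0, 2.0], [2.0, 1.0]]), 0.5)

    def test_zero_variance_gene_forms_no_edges(self):
        e = _expr([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0], [3.0, 2.0, 1.0]])
        net = correlation_network(e, 0.0)
        assert 0 not in set(net.sources.tolist() + net.targets.tolist())

    def test_matches_bruteforce_pairwise_pearson(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal((20, 10))
        net = correlation_network(_expr(x), 0.8)
        got = {(int(u), int(v)) for u, v in zip(net.sources, net.targets)}
        expected = set()
        for i in range(20):
            for j in range(i + 1, 20):
                r = np.corrcoef(x[i], x[j])[0, 1]
                if abs(r) >= 0.8:
                    expected.add((i, j))
        assert got == expected

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((6, 30))
        base = correlation_network(_expr(x), 0.2, mode="signed")
        scaled = x * rng.uniform(0.5, 3.0, size=(6, 1)) + rng.normal(size=(6, 1))
        same = correlation_network(_expr(scaled), 0.2, mode="signed")
        assert sorted((int(u), int(v)) for u, v in zip(base.sources, base.targets)) == \
            sorted((int(u), int(v)) for u, v in zip(same.sources, same.targets))
        flipped = x.copy()
        flipped[0] = -flipped[0]
        flip_net = correlation_network(_expr(flipped), 0.0, mode="absolute")
        for u, v, w in flip_net.records:
            r = np.corrcoef(x[u], x[v])[0, 1]
            expected = -r if (u == 0) != (v == 0) else r
            assert w == pytest.approx(expected)


class TestSubnetworkWithSeed:
    def _two_cluster(self):
        recs = [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0),
                (3, 4, 1.0), (4, 5, 1.0)]
        return build_csr(EdgeTable.from_records(recs, 6), directed=False)

    def test_seed_cluster_extracted(self):
        g = self._two_cluster()
        labels = scc(g)
        sub, mapping = subnetwork_with_seed(g, labels, 1)
        assert sorted(mapping) == [0, 1, 2]
        assert sub.num_vertices == 3

    def test_isolated_seed_gives_single_vertex(self):
        g = build_csr(EdgeTable.from_records([(0, 1, 1.0)], 3), directed=False)
        sub, mapping = subnetwork_with_seed(g, scc(g), 2)
        assert sub.num_vertices == 1 and sub.num_edges == 0

    def test_invalid_seed_rejected(self):
        g = self._two_cluster()
        with pytest.raises(ValueError, match="invalid vertex id"):
            subnetwork_with_seed(g, scc(g), 17)

    def test_seed_reaches_every_subnetwork_vertex(self):
        g = self._two_cluster()
        sub, mapping = subnetwork_with_seed(g, scc(g), 4)
        from frontiernet.bfs import UNREACHED, bfs_multi

        depths = bfs_multi(sub, [mapping[4]]).depths[0]
        assert (depths != UNREACHED).all()


class TestMeanShortestPath:
    def test_path_graph_hand_count(self):
        g = build_csr(
            EdgeTable.from_records([(0, 1, 1.0), (1, 2, 1.0)], 3), False
        )
        stats = mean_shortest_path(g, [0, 1, 2])
        # ordered pairs: 0-1,1-0,1-2,2-1 at distance 1; 0-2,2-0 at distance 2
        assert stats.mean_distance == pytest.approx(4 / 3)
        assert stats.n_pairs_finite == 6 and stats.n_pairs_total == 6

    def test_complete_graph_mean_is_one(self):
        recs = [(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)]
        g = build_csr(EdgeTable.from_records(recs, 4), directed=False)
        assert mean_shortest_path(g, range(4)).mean_distance == pytest.approx(1.0)

    def test_unreachable_pairs_counted_but_excluded_from_mean(self):
        g = build_csr(EdgeTable.from_records([(0, 1, 1.0)], 3), directed=False)
        stats = mean_shortest_path(g, [0])
        assert stats.n_pairs_total == 2
        assert stats.n_pairs_finite == 1
        assert stats.mean_distance == pytest.approx(1.0)


def test_subnetwork_distance_never_below_full_graph_distance():
    """Removing vertices can only lengthen (or preserve) shortest paths."""
    rng = np.random.default_rng(5)
    recs = [(int(u), int(v), float(w)) for u, v, w in zip(
        rng.integers(0, 30, 120), rng.integers(0, 30, 120),
        rng.uniform(0.1, 5.0, 120))]
    g = build_csr(EdgeTable.from_records(recs, 30), directed=False)
    labels = scc(g)
    sub, mapping = subnetwork_with_seed(g, labels, 0)
    members = sorted(mapping)
    full = sssp(g, members, want_predecessors=False).distances
    part = sssp(sub, [mapping[v] for v in members], want_predecessors=False).distances
    for i, u in enumerate(members):
        for v in members:
            assert part[i, mapping[v]] >= full[i, v] - 1e-9
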