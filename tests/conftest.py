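import numpy as np
import pytest

from frontiernet.graph_core import EdgeTable, build_csr


def random_digraph(rng, n=None, p=None, weights="unit"):
    """Seeded random digraph for cross-check suites.

    weights: "unit" (all 1), "positive" (uniform (0, 10]), or "mixed"
    (uniform [-2, 8], may produce negative cycles — callers filter).
    """
    if n is None:
        n = int(rng.integers(2, 60))
    if p is None:
        p = float(rng.uniform(0.02, 0.25))
    src, tgt = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    src, tgt = src.ravel(), tgt.ravel()
    off = src != tgt
    src, tgt = src[off], tgt[off]
    keep = rng.random(src.size) < p
    src, tgt = src[keep], tgt[keep]
    if weights == "unit":
        w = np.ones(src.size)
    elif weights == "positive":
        w = rng.uniform(0.0, 10.0, src.size) + 1e-9
    else:
        w = rng.uniform(-2.0, 8.0, src.size)
    return EdgeTable(src, tgt, w, num_vertices=n)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def triangle_undirected():
    e = EdgeTable.from_records([(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)], 3)
    return build_csr(e, directed=False)


@pytest.fixture
def path3_directed():
    e = EdgeTable.from_records([(0, 1, 1.0), (1, 2, 1.0)], 3)
    return build_csr(e, directed=True)
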