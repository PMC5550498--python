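import numpy as np
import pytest

import steppm as sp


@pytest.fixture(scope="session")
def small_sim():
    """An 8x8 x 4-period simulated panel shared by read-only tests."""
    scen = sp.SimulationScenario(rows=8, cols=8, n_periods=4, seed=11)
    return sp.simulate_counts(scen)


@pytest.fixture
def path4():
    """Path graph a-b-c-d as binary weights."""
    return sp.SpatialWeights(
        ids=("a", "b", "c", "d"),
        neighbors=((1,), (0, 2), (1, 3), (2,)),
        weights=((1.0,), (1.0, 1.0), (1.0, 1.0), (1.0,)),
        style="binary",
        component_labels=(0, 0, 0, 0))


def complete_graph(n):
    nbrs = tuple(tuple(j for j in range(n) if j != i) for i in range(n))
    return sp.SpatialWeights(
        ids=tuple(range(n)), neighbors=nbrs,
        weights=tuple(tuple(1.0 for _ in nb) for nb in nbrs),
        style="binary", component_labels=(0,) * n)


def random_graph(n, p, rng):
    """Erdos-Renyi symmetric adjacency as binary SpatialWeights."""
    A = rng.random((n, n)) < p
    A = np.triu(A, 1)
    A = A | A.T
    nbrs = tuple(tuple(np.flatnonzero(A[i])) for i in range(n))
    labels = _component_labels(nbrs)
    islands = frozenset(i for i in range(n) if not nbrs[i])
    return sp.SpatialWeights(
        ids=tuple(range(n)), neighbors=nbrs,
        weights=tuple(tuple(1.0 for _ in nb) for nb in nbrs),
        style="binary", islands=islands, component_labels=labels)


def _component_labels(neighbors):
    n = len(neighbors)
    labels = [-1] * n
    comp = 0
    for s in range(n):
        if labels[s] >= 0:
            continue
        stack = [s]
        labels[s] = comp
        while stack:
            i = stack.pop()
            for j in neighbors[i]:
                if labels[j] < 0:
                    labels[j] = comp
                    stack.append(j)
        comp += 1
    return tuple(labels)


def brute_force_moran(values, w):
    """O(n^2) double-sum oracle for Moran's I."""
    z = np.asarray(values, float) - np.mean(values)
    W = w.to_sparse().toarray()
    num = sum(W[i, j] * z[i] * z[j] for i in range(w.n) for j in range(w.n))
    return (w.n / W.sum()) * num / (z @ z)


def brute_force_bivariate(x, y, w):
    zx = np.asarray(x, float) - np.mean(x)
    zy = np.asarray(y, float) - np.mean(y)
    W = w.to_sparse().toarray()
    num = sum(W[i, j] * zx[i] * zy[j] for i in range(w.n) for j in range(w.n))
    return (w.n / W.sum()) * num / np.sqrt((zx @ zx) * (zy @ zy))
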