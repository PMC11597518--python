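"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (double loops, exhaustive
enumeration) so they cannot share a code path with the package.
"""

from __future__ import annotations

import numpy as np
import pytest

from metabopk.datatypes import PKModelParams
from metabopk.simulate import simulate_cohort, simulate_concentration, simulate_feature_matrix


# --------------------------------------------------------------------------
# independent oracles


def dcor_bruteforce(x, y) -> float:
    """O(n^2) double-loop distance correlation (V-statistic)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    a = np.zeros((n, n))
    b = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            a[i, j] = abs(x[i] - x[j])
            b[i, j] = abs(y[i] - y[j])

    def center(d):
        out = np.zeros_like(d)
        grand = d.mean()
        row = [d[i, :].mean() for i in range(n)]
        col = [d[:, j].mean() for j in range(n)]
        for i in range(n):
            for j in range(n):
                out[i, j] = d[i, j] - row[i] - col[j] + grand
        return out

    A, B = center(a), center(b)
    dcov2 = (A * B).mean()
    dvx = (A * A).mean()
    dvy = (B * B).mean()
    if dvx <= 0 or dvy <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvx * dvy)))


def modularity_of(labels: dict, graph) -> float:
    """Weighted Newman modularity of a labelled partition."""
    m = sum(d.get("weight", 1.0) for _, _, d in graph.edges(data=True))
    strength = {v: 0.0 for v in graph.nodes}
    for u, v, d in graph.edges(data=True):
        w = d.get("weight", 1.0)
        strength[u] += w
        strength[v] += w
    intra: dict = {}
    deg: dict = {}
    for u, v, d in graph.edges(data=True):
        if labels[u] == labels[v]:
            intra[labels[u]] = intra.get(labels[u], 0.0) + d.get("weight", 1.0)
    for v in graph.nodes:
        deg[labels[v]] = deg.get(labels[v], 0.0) + strength[v]
    return sum(
        intra.get(c, 0.0) / m - (deg[c] / (2 * m)) ** 2 for c in deg
    )


def brute_force_max_modularity(graph) -> tuple[float, dict]:
    """Exhaustive max-modularity search over all partitions (<= 12 nodes)."""
    nodes = list(graph.nodes)
    n = len(nodes)
    if n > 12:
        raise ValueError("exhaustive search is for tiny graphs only")
    idx = {v: i for i, v in enumerate(nodes)}
    edges = [
        (idx[u], idx[v], d.get("weight", 1.0)) for u, v, d in graph.edges(data=True)
    ]
    m = sum(w for _, _, w in edges)
    strength = [0.0] * n
    for u, v, w in edges:
        strength[u] += w
        strength[v] += w
    best_q = -np.inf
    best = None
    labels = [0] * n

    def recurse(i: int, k: int) -> None:
        nonlocal best_q, best
        if i == n:
            intra = [0.0] * k
            deg = [0.0] * k
            for u, v, w in edges:
                if labels[u] == labels[v]:
                    intra[labels[u]] += w
            for j in range(n):
                deg[labels[j]] += strength[j]
            q = sum(intra[c] / m - (deg[c] / (2 * m)) ** 2 for c in range(k))
            if q > best_q:
                best_q = q
                best = labels.copy()
            return
        for c in range(k):  # restricted growth: canonical set partitions
            labels[i] = c
            recurse(i + 1, k)
        labels[i] = k
        recurse(i + 1, k + 1)

    recurse(1, 1)
    return float(best_q), {nodes[i]: best[i] for i in range(n)}


def hypergeom_tail_enumeration(N: int, K: int, n: int, k: int):
    """P(X >= k) by exhaustive enumeration of all C(N, n) draws (exact)."""
    from fractions import Fraction
    from itertools import combinations

    hits = total = 0
    marked = set(range(K))
    for draw in combinations(range(N), n):
        total += 1
        if len(marked.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def dcor_oracle():
    return dcor_bruteforce


@pytest.fixture(scope="session")
def cohort35():
    return simulate_cohort(35, seed=11)


@pytest.fixture(scope="session")
def noiseless_profile():
    return simulate_concentration(PKModelParams(), subject_id="S01")


@pytest.fixture(scope="session")
def small_study(cohort35):
    """200-feature matrix with planted differentials and associations."""
    spec = [
        ("F0001", "Systolic pressure", 0.8, 1),
        ("F0002", "Heart rate", 0.8, -1),
        ("F0003", "Uric acid", 0.8, 1),
    ]
    matrix, truth = simulate_feature_matrix(
        cohort35, n_features=200, n_differential=20, association_spec=spec, seed=21
    )
    return matrix, truth
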