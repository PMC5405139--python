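import itertools

import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def k4_weights():
    """The worked 4-node example: weights AB .9, AC .8, AD .4, BC .3, BD .7, CD .6."""
    W = np.zeros((4, 4))
    pairs = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.4, (1, 2): 0.3, (1, 3): 0.7, (2, 3): 0.6}
    for (i, j), w in pairs.items():
        W[i, j] = W[j, i] = w
    return W


def random_weight_matrix(rng, n, low=0.05, high=1.0):
    """Dense random symmetric weight matrix with unique weights a.s."""
    W = rng.uniform(low, high, (n, n))
    W = np.triu(W, 1)
    W = W + W.T
    np.fill_diagonal(W, 0.0)
    return W


def enumerate_min_spanning_tree(D):
    """Brute-force minimum spanning tree total distance by enumerating all
    (N-1)-edge acyclic spanning subsets.  Oracle for Kruskal."""
    n = D.shape[0]
    edges = [(i, j) for i in range(n) for j in range(i + 1, n) if np.isfinite(D[i, j])]
    best = np.inf
    for combo in itertools.combinations(edges, n - 1):
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        ok = True
        for u, v in combo:
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
        if ok:
            best = min(best, sum(D[u, v] for u, v in combo))
    return best


def floyd_warshall(D):
    """Triple-loop all-pairs shortest paths oracle."""
    n = D.shape[0]
    spl = D.copy()
    spl[~np.isfinite(spl)] = np.inf
    np.fill_diagonal(spl, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if spl[i, k] + spl[k, j] < spl[i, j]:
                    spl[i, j] = spl[i, k] + spl[k, j]
    return spl
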