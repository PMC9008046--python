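"""Self-contained naive reference implementations for scripts/acceptance.py.

Plain-loop versions written straight from the defining formulas, kept
independent of the package's vectorised code paths.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def floyd_warshall_loops(lengths: np.ndarray) -> np.ndarray:
    n = lengths.shape[0]
    d = lengths.copy()
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def _distances(W: np.ndarray) -> np.ndarray:
    n = W.shape[0]
    lengths = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                lengths[i, j] = 1.0 / W[i, j]
    np.fill_diagonal(lengths, 0.0)
    return floyd_warshall_loops(lengths)


def local_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    effs = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            effs.append(0.0)
            continue
        d = _distances(W[np.ix_(nbrs, nbrs)])
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    total += (W[i, nbrs[a]] * W[i, nbrs[b]] / d[a, b]) ** (1 / 3)
        effs.append(total / (k * (k - 1)))
    return float(np.mean(effs))


def permutation_p(a, b) -> tuple[float, float]:
    a, b = list(a), list(b)
    pooled = a + b
    na, n = len(a), len(a) + len(b)
    obs = np.mean(a) - np.mean(b)
    count = total = 0
    for idx in combinations(range(n), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        total += 1
        if abs(np.mean(ga) - np.mean(gb)) >= abs(obs) - 1e-12:
            count += 1
    return float(obs), count / total


def bh_adjust(pvals) -> np.ndarray:
    p = np.asarray(pvals, float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        running_min = min(running_min, p[idx] * m / rank)
        adj[idx] = running_min
    return adj
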