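"""Independent brute-force reference implementations used only by tests.

Everything here is written as naive loops straight from the defining
formulas (or delegates to networkx, which the package itself does not use),
so agreement with the package is a genuine dual-route check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import networkx as nx


def to_nx(W: np.ndarray) -> nx.Graph:
    g = nx.Graph()
    n = W.shape[0]
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                g.add_edge(i, j, weight=W[i, j])
    return g


def degree_strength(W: np.ndarray) -> tuple[float, float]:
    n = W.shape[0]
    degs, strens = [], []
    for i in range(n):
        d = s = 0.0
        for j in range(n):
            if i != j and W[i, j] > 0:
                d += 1
                s += W[i, j]
        degs.append(d)
        strens.append(s)
    return float(np.mean(degs)), float(np.mean(strens))


def distances(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on lengths 1/W via networkx Dijkstra."""
    n = W.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if W[i, j] > 0:
                g.add_edge(i, j, length=1.0 / W[i, j])
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for src, lengths in nx.all_pairs_dijkstra_path_length(g, weight="length"):
        for dst, val in lengths.items():
            d[src, dst] = val
    return d


def path_measures(d: np.ndarray) -> tuple[float, float, float, float]:
    n = d.shape[0]
    eccs = []
    finite_vals = []
    inv_sum = 0.0
    n_off = 0
    for i in range(n):
        row = [d[i, j] for j in range(n) if j != i and np.isfinite(d[i, j])]
        if row:
            eccs.append(max(row))
        for j in range(n):
            if j != i:
                n_off += 1
                if np.isfinite(d[i, j]):
                    finite_vals.append(d[i, j])
                    inv_sum += 1.0 / d[i, j]
    radius = min(eccs) if eccs else float("nan")
    diameter = max(eccs) if eccs else float("nan")
    cpl = float(np.mean(finite_vals)) if finite_vals else float("nan")
    return radius, diameter, cpl, inv_sum / n_off


def clustering(W: np.ndarray) -> float:
    """Mean Onnela weighted clustering; cross-checked against networkx."""
    n = W.shape[0]
    wmax = W.max()
    if wmax <= 0:
        return 0.0
    wh = W / wmax
    cs = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        total = 0.0
        for j, h in combinations(nbrs, 2):
            total += (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
        cs.append(2 * total / (k * (k - 1)))
    return float(np.mean(cs))


def transitivity(W: np.ndarray) -> float:
    n = W.shape[0]
    wmax = W.max()
    if wmax <= 0:
        return 0.0
    wh = W / wmax
    tri = 0.0
    triples = 0.0
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        triples += k * (k - 1)
        for j, h in combinations(nbrs, 2):
            tri += 2 * (wh[i, j] * wh[i, h] * wh[j, h]) ** (1 / 3)
    return float(tri / triples) if triples > 0 else 0.0


def local_efficiency(W: np.ndarray) -> float:
    n = W.shape[0]
    effs = []
    for i in range(n):
        nbrs = [j for j in range(n) if W[i, j] > 0]
        k = len(nbrs)
        if k < 2:
            effs.append(0.0)
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        d = distances(sub)
        total = 0.0
        for a in range(k):
            for b in range(k):
                if a != b and np.isfinite(d[a, b]) and d[a, b] > 0:
                    total += (W[i, nbrs[a]] * W[i, nbrs[b]] / d[a, b]) ** (1 / 3)
        effs.append(total / (k * (k - 1)))
    return float(np.mean(effs))


def assortativity(W: np.ndarray) -> float:
    n = W.shape[0]
    s = W.sum(axis=1)
    xs, ys, ws = [], [], []
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:  # both orientations
                xs.append(s[i])
                ys.append(s[j])
                ws.append(W[i, j])
    xs, ys, ws = np.array(xs), np.array(ys), np.array(ws)
    ws = ws / ws.sum()
    mx, my = ws @ xs, ws @ ys
    cov = ws @ ((xs - mx) * (ys - my))
    vx = ws @ (xs - mx) ** 2
    vy = ws @ (ys - my) ** 2
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def modularity_value(W: np.ndarray, membership, gamma: float = 1.0) -> float:
    n = W.shape[0]
    two_m = W.sum()
    k = W.sum(axis=1)
    q = 0.0
    for i in range(n):
        for j in range(n):
            if membership[i] == membership[j]:
                q += W[i, j] - gamma * k[i] * k[j] / two_m
    return float(q / two_m)


def _set_partitions(items: list[int]):
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def best_partition_modularity(W: np.ndarray, gamma: float = 1.0) -> float:
    """Globally optimal modularity by exhaustive set-partition search."""
    n = W.shape[0]
    best = -np.inf
    for part in _set_partitions(list(range(n))):
        memb = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            for node in block:
                memb[node] = c
        best = max(best, modularity_value(W, memb, gamma))
    return float(best)


def permutation_p(a, b) -> tuple[float, float]:
    """Exact two-sided permutation p by full enumeration of relabelings."""
    a, b = list(a), list(b)
    pooled = a + b
    na, n = len(a), len(a) + len(b)
    obs = np.mean(a) - np.mean(b)
    count = total = 0
    for idx in combinations(range(n), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(n) if i not in idx]
        diff = np.mean(ga) - np.mean(gb)
        total += 1
        if abs(diff) >= abs(obs) - 1e-12:
            count += 1
    return float(obs), count / total


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up by direct formula."""
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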