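"""Twelve global measures on weighted undirected graphs.

The networks analysed here are dense coherence graphs: symmetric,
non-negative, zero-diagonal matrices with weights in [0, 1].  All measures
use the weighted-graph conventions of the standard brain-connectivity
toolboxes:

* connection lengths for path-based measures are the inverse weights,
  L_ij = 1 / W_ij (infinite for absent edges) — a stronger coherence means a
  shorter functional distance;
* clustering and transitivity use the geometric-mean triangle intensity
  (Onnela variant) with weights rescaled by the maximum weight;
* local efficiency uses the weighted per-node formula combining the node's
  edge weights with inverse shortest paths inside the neighbour subgraph;
* modularity is weighted Newman modularity maximised by Louvain restarts;
* assortativity is the weighted Pearson correlation of endpoint strengths
  over edges;
* small-worldness compares clustering and path length against
  degree-preserving surrogate networks.

Disconnected node pairs are excluded from the characteristic-path-length
mean, contribute zero to efficiency, and eccentricities are taken over
finite distances only.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ZeroWeightGraphError, logger

__all__ = [
    "WeightedGraph",
    "GraphMetricsRecord",
    "degree_strength",
    "distance_matrix",
    "path_measures",
    "clustering_transitivity",
    "local_efficiency",
    "louvain_modularity",
    "modularity_value",
    "exhaustive_modularity",
    "assortativity",
    "small_worldness",
    "rewired_null",
    "all_metrics",
    "metrics_table",
]


@dataclass(frozen=True)
class WeightedGraph:
    """Symmetric non-negative weighted graph with zero diagonal."""

    W: np.ndarray
    node_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError(f"W must be square, got {W.shape}")
        if not np.all(np.isfinite(W)):
            raise ValueError("W must be finite")
        if not np.allclose(W, W.T):
            raise ValueError("W must be symmetric")
        if W.min() < 0:
            raise ValueError("W must be non-negative")
        W = (W + W.T) / 2.0
        np.fill_diagonal(W, 0.0)
        object.__setattr__(self, "W", W)
        if self.node_labels is not None:
            labels = tuple(self.node_labels)
            if len(labels) != W.shape[0]:
                raise ValueError("node_labels length must match W")
            object.__setattr__(self, "node_labels", labels)

    @property
    def n_nodes(self) -> int:
        return self.W.shape[0]


@dataclass
class GraphMetricsRecord:
    """The twelve global measures for one subject × band."""

    subject_id: str
    band: str
    degree: float
    strength: float
    radius: float
    diameter: float
    characteristic_path_length: float
    global_efficiency: float
    local_efficiency: float
    clustering_coefficient: float
    transitivity: float
    modularity: float
    assortativity: float
    small_worldness: float
    metadata: dict = field(default_factory=dict)


def _as_matrix(g: WeightedGraph | np.ndarray) -> np.ndarray:
    if isinstance(g, WeightedGraph):
        return g.W
    return WeightedGraph(np.asarray(g, float)).W


def _apply_threshold(W: np.ndarray, threshold: float) -> np.ndarray:
    """Zero out edges with weight <= threshold (threshold 0 keeps all
    positive weights, i.e. the dense weighted graph)."""
    if threshold <= 0:
        return W
    return np.where(W > threshold, W, 0.0)


# ---------------------------------------------------------------------------
# Degree / strength
# ---------------------------------------------------------------------------

def degree_strength(g: WeightedGraph | np.ndarray, threshold: float = 0.0) -> tuple[float, float]:
    """Average node degree (edges with weight above threshold) and average
    node strength (sum of incident weights)."""
    W = _apply_threshold(_as_matrix(g), threshold)
    degree = (W > 0).sum(axis=1).mean()
    strength = W.sum(axis=1).mean()
    return float(degree), float(strength)


# ---------------------------------------------------------------------------
# Distances and path-based measures
# ---------------------------------------------------------------------------

def _shortest_paths(W: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths on connection lengths 1/W (Floyd–Warshall,
    vectorised; no input validation)."""
    n = W.shape[0]
    d = np.where(W > 0, 1.0, np.inf) / np.where(W > 0, W, 1.0)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        np.minimum(d, d[:, k, None] + d[None, k, :], out=d)
    return d


def distance_matrix(g: WeightedGraph | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with connection lengths 1/W.

    Absent edges have infinite length; disconnected pairs remain infinite.
    The diagonal is zero.
    """
    return _shortest_paths(_as_matrix(g))


def path_measures(d: np.ndarray) -> tuple[float, float, float, float]:
    """(radius, diameter, characteristic path length, global efficiency)
    from a distance matrix.

    Eccentricities are maxima over finite distances; radius/diameter are the
    min/max eccentricity over nodes having at least one finite distance.
    CPL is the mean of finite off-diagonal distances; global efficiency is
    the mean of inverse distances over all off-diagonal pairs (1/inf = 0).
    """
    d = np.asarray(d, float)
    n = d.shape[0]
    if n < 2:
        raise ValueError("path measures need at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    with np.errstate(invalid="ignore"):
        ecc = np.where(finite, d, -np.inf).max(axis=1)
    ecc = ecc[np.isfinite(ecc)]  # drop fully isolated nodes
    if ecc.size == 0:
        radius = diameter = float("nan")
    else:
        radius, diameter = float(ecc.min()), float(ecc.max())
    cpl = float(d[finite].mean()) if finite.any() else float("nan")
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    geff = float(inv[off].mean())
    return radius, diameter, cpl, geff


# ---------------------------------------------------------------------------
# Clustering / transitivity (Onnela geometric-mean variant)
# ---------------------------------------------------------------------------

def clustering_transitivity(g: WeightedGraph | np.ndarray) -> tuple[float, float]:
    """(mean weighted clustering coefficient, weighted transitivity).

    Weights are rescaled by the maximum weight; the triangle intensity of
    (i, j, h) is the geometric mean (ŵ_ij ŵ_ih ŵ_jh)^(1/3).  Per-node
    clustering normalises by k_i (k_i - 1); isolated or degree-1 nodes
    contribute 0.  Transitivity is total triangle intensity over total
    connected triples.
    """
    return _clustering_transitivity_raw(_as_matrix(g))


def _clustering_transitivity_raw(W: np.ndarray) -> tuple[float, float]:
    wmax = W.max()
    if wmax <= 0:
        return 0.0, 0.0
    cube = np.cbrt(W / wmax)
    tri = np.diag(cube @ cube @ cube)  # 2 x (weighted triangles at node)
    k = (W > 0).sum(axis=1).astype(float)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / denom, 0.0)
    clustering = float(c.mean())
    total = denom.sum()
    transitivity = float(tri.sum() / total) if total > 0 else 0.0
    return clustering, transitivity


# ---------------------------------------------------------------------------
# Local efficiency (weighted)
# ---------------------------------------------------------------------------

def local_efficiency(g: WeightedGraph | np.ndarray) -> float:
    """Mean weighted local efficiency.

    For node i with neighbours N_i (k_i >= 2):

        E_loc(i) = sum_{j != h in N_i} (w_ij w_ih / d_jh(N_i))^(1/3)
                   / (k_i (k_i - 1)),

    where d_jh(N_i) is the shortest path between j and h restricted to the
    neighbour subgraph, with connection lengths 1/W.  Nodes with fewer than
    two neighbours contribute 0; the result is averaged over all nodes.
    """
    W = _as_matrix(g)
    n = W.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nbrs = np.where(W[i] > 0)[0]
        k = nbrs.size
        if k < 2:
            continue
        sub = W[np.ix_(nbrs, nbrs)]
        d = _shortest_paths(sub)
        np.fill_diagonal(d, np.inf)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(d), 1.0 / d, 0.0)
        wi = W[i, nbrs]
        terms = np.cbrt(np.outer(wi, wi) * inv_d)
        np.fill_diagonal(terms, 0.0)
        eff[i] = terms.sum() / (k * (k - 1))
    return float(eff.mean())


# ---------------------------------------------------------------------------
# Modularity (Louvain with restarts + exhaustive reference)
# ---------------------------------------------------------------------------

def modularity_value(
    W: np.ndarray, membership: Sequence[int], gamma: float = 1.0
) -> float:
    """Weighted Newman modularity of a node partition.

    Q = (1/2m) * sum_ij [ W_ij - gamma * k_i k_j / 2m ] delta(c_i, c_j)
    with k the node strengths and 2m the total weight.
    """
    W = np.asarray(W, float)
    membership = np.asarray(membership)
    two_m = W.sum()
    if two_m <= 0:
        raise ZeroWeightGraphError("modularity undefined on a zero-weight graph")
    k = W.sum(axis=1)
    q = 0.0
    for c in np.unique(membership):
        idx = membership == c
        q += W[np.ix_(idx, idx)].sum() - gamma * k[idx].sum() ** 2 / two_m
    return float(q / two_m)


def _igraph_louvain(W: np.ndarray, gamma: float) -> np.ndarray:
    import igraph as ig

    g = ig.Graph.Weighted_Adjacency(W.tolist(), mode="undirected", attr="weight", loops=False)
    part = g.community_multilevel(weights="weight", resolution=gamma)
    return np.asarray(part.membership)


def _refine_partition(
    W: np.ndarray, membership: np.ndarray, gamma: float, max_sweeps: int = 50
) -> np.ndarray:
    """Greedy single-node moves until no move increases modularity.

    Standard Kernighan–Lin-style polish of a Louvain partition; every
    accepted move strictly increases Q, so the result stays bounded by the
    exhaustive optimum.
    """
    membership = membership.copy()
    n = W.shape[0]
    s = W.sum()
    k = W.sum(axis=1)
    for _ in range(max_sweeps):
        improved = False
        for i in range(n):
            a = membership[i]
            # weight from i into each community (W_ii = 0)
            w_to = np.bincount(membership, weights=W[i], minlength=membership.max() + 2)
            K = np.bincount(membership, weights=k, minlength=w_to.size)
            # gain of moving i from a to c, up to the positive factor 2/s
            gain = (w_to - w_to[a] + W[i, i]) - gamma * k[i] * (K - K[a] + k[i]) / s
            gain[a] = 0.0
            c = int(np.argmax(gain))
            if gain[c] > 1e-15 * max(1.0, s):
                membership[i] = c
                improved = True
        if not improved:
            break
    # compact labels
    _, membership = np.unique(membership, return_inverse=True)
    return membership


def louvain_modularity(
    g: WeightedGraph | np.ndarray,
    gamma: float = 1.0,
    restarts: int = 10,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, np.ndarray]:
    """Best (Q, membership) over Louvain restarts with randomised node order.

    Each restart permutes the node order (Louvain's greedy sweeps are
    order-dependent), polishes the resulting partition with greedy
    single-node moves, and the partition with the highest modularity is
    kept.  Deterministic under a fixed ``rng`` seed.
    """
    W = _as_matrix(g)
    n = W.shape[0]
    if W.sum() <= 0:
        raise ZeroWeightGraphError("Louvain requires positive total weight")
    rng = np.random.default_rng(rng)
    best_q, best_membership = -np.inf, np.zeros(n, dtype=int)
    state = _pyrandom.getstate()
    try:
        for _ in range(max(1, restarts)):
            perm = rng.permutation(n)
            _pyrandom.seed(int(rng.integers(0, 2**31 - 1)))
            memb_perm = _igraph_louvain(W[np.ix_(perm, perm)], gamma)
            membership = np.empty(n, dtype=int)
            membership[perm] = memb_perm
            membership = _refine_partition(W, membership, gamma)
            q = modularity_value(W, membership, gamma)
            if q > best_q:
                best_q, best_membership = q, membership
    finally:
        _pyrandom.setstate(state)
    return float(best_q), best_membership


def _partitions(n: int):
    """All set partitions of range(n) as membership arrays (restricted
    growth strings: a[0] = 0 and a[i] <= max(a[:i]) + 1).  Feasible for
    n <= ~10 (Bell numbers)."""
    a = np.zeros(n, dtype=int)

    def rec(i: int, mx: int):
        if i == n:
            yield a.copy()
            return
        for c in range(mx + 2):
            a[i] = c
            yield from rec(i + 1, max(mx, c))

    yield from rec(1, 0)


def exhaustive_modularity(
    g: WeightedGraph | np.ndarray, gamma: float = 1.0
) -> tuple[float, np.ndarray]:
    """Globally optimal (Q, membership) by enumerating all partitions.

    Exact reference for small graphs (Bell(8) = 4140 partitions); used to
    audit the Louvain heuristic.
    """
    W = _as_matrix(g)
    n = W.shape[0]
    if n > 12:
        raise ValueError("exhaustive_modularity is intended for n <= 12")
    two_m = W.sum()
    if two_m <= 0:
        raise ZeroWeightGraphError("modularity undefined on a zero-weight graph")
    k = W.sum(axis=1)
    best_q, best = -np.inf, np.zeros(n, dtype=int)
    for memb in _partitions(n):
        q = 0.0
        for c in range(memb.max() + 1):
            idx = memb == c
            q += W[np.ix_(idx, idx)].sum() - gamma * k[idx].sum() ** 2 / two_m
        q /= two_m
        if q > best_q:
            best_q, best = q, memb
    return float(best_q), best


# ---------------------------------------------------------------------------
# Assortativity (weighted)
# ---------------------------------------------------------------------------

def assortativity(g: WeightedGraph | np.ndarray) -> float:
    """Weighted strength assortativity.

    Pearson correlation of the strengths of edge endpoints, with every edge
    contributing proportionally to its weight (both orientations included,
    which symmetrises the formula).  Degenerate variance (all endpoint
    strengths equal, e.g. a regular ring) is defined as 0 with a warning.
    """
    W = _as_matrix(g)
    ii, jj = np.nonzero(np.triu(W, k=1))
    if ii.size < 2:
        raise ValueError("assortativity needs at least 2 edges")
    s = W.sum(axis=1)
    x = np.concatenate([s[ii], s[jj]])
    y = np.concatenate([s[jj], s[ii]])
    w = np.concatenate([W[ii, jj], W[ii, jj]])
    w = w / w.sum()
    mx = float(w @ x)
    my = float(w @ y)
    cov = float(w @ ((x - mx) * (y - my)))
    vx = float(w @ (x - mx) ** 2)
    vy = float(w @ (y - my) ** 2)
    scale = float(np.mean(x**2))
    if vx <= 1e-15 * max(scale, 1.0) or vy <= 1e-15 * max(scale, 1.0):
        logger.warning("assortativity: degenerate endpoint-strength variance; returning 0")
        return 0.0
    return float(cov / np.sqrt(vx * vy))


# ---------------------------------------------------------------------------
# Small-worldness
# ---------------------------------------------------------------------------

def rewired_null(
    W: np.ndarray,
    rewires_per_edge: int,
    rng: np.random.Generator,
    permute_weights: bool = True,
) -> np.ndarray:
    """Degree-preserving surrogate network with the same weight multiset.

    Maslov–Sneppen edge swaps (weights travel with their edges) randomise
    the topology while preserving each node's degree.  On dense graphs —
    coherence networks are complete — no swap can succeed, so the weight
    values are additionally permuted uniformly across the (rewired) edge
    set (``permute_weights=True``), which keeps the null informative while
    still preserving degrees and the weight multiset.
    """
    W = W.copy()
    n = W.shape[0]
    iu, ju = np.nonzero(np.triu(W, k=1))
    m = iu.size
    if m < 2:
        return W
    edges = np.stack([iu, ju], axis=1)
    if m == n * (n - 1) // 2:
        n_attempts = 0  # complete graph: every swap would create a multi-edge
    else:
        n_attempts = rewires_per_edge * m
    picks = rng.integers(0, m, size=(n_attempts, 2))
    flips = rng.random(n_attempts) < 0.5
    for (e1, e2), flip in zip(picks, flips):
        if e1 == e2:
            continue
        a, b = edges[e1]
        c, d = edges[e2]
        if flip:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if W[a, d] > 0 or W[c, b] > 0:
            continue  # would create a multi-edge
        wab, wcd = W[a, b], W[c, d]
        W[a, b] = W[b, a] = 0.0
        W[c, d] = W[d, c] = 0.0
        W[a, d] = W[d, a] = wab
        W[c, b] = W[b, c] = wcd
        edges[e1] = (a, d)
        edges[e2] = (c, b)
    if permute_weights:
        iu, ju = np.nonzero(np.triu(W, k=1))
        vals = W[iu, ju]
        perm = rng.permutation(vals.size)
        W[iu, ju] = vals[perm]
        W[ju, iu] = vals[perm]
    return W


def small_worldness(
    g: WeightedGraph | np.ndarray,
    n_null: int = 20,
    rewires_per_edge: int = 10,
    rng: np.random.Generator | int | None = None,
    permute_weights: bool = True,
) -> float:
    """Small-world index sigma = (C / <C_null>) / (L / <L_null>).

    C is the mean weighted clustering coefficient and L the weighted
    characteristic path length; the null averages are taken over ``n_null``
    degree-preserving surrogates from :func:`rewired_null`.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    W = _as_matrix(g)
    rng = np.random.default_rng(rng)
    c, _ = _clustering_transitivity_raw(W)
    _, _, l, _ = path_measures(_shortest_paths(W))
    c_null = np.empty(n_null)
    l_null = np.empty(n_null)
    for k in range(n_null):
        Wn = rewired_null(W, rewires_per_edge, rng, permute_weights=permute_weights)
        c_null[k], _ = _clustering_transitivity_raw(Wn)
        _, _, l_null[k], _ = path_measures(_shortest_paths(Wn))
    c_bar, l_bar = c_null.mean(), l_null.mean()
    if c_bar <= 0 or l_bar <= 0 or not np.isfinite(l) or l <= 0:
        logger.warning("small_worldness: degenerate normalisation; returning nan")
        return float("nan")
    return float((c / c_bar) / (l / l_bar))


# ---------------------------------------------------------------------------
# All twelve measures
# ---------------------------------------------------------------------------

def all_metrics(
    g: WeightedGraph | np.ndarray,
    subject_id: str = "",
    band: str = "",
    edge_threshold: float = 0.0,
    louvain_gamma: float = 1.0,
    louvain_restarts: int = 10,
    sw_nulls: int = 20,
    sw_rewires_per_edge: int = 10,
    rng: np.random.Generator | int | None = None,
) -> GraphMetricsRecord:
    """Compute all twelve global measures with one seeded rng for the
    stochastic ones (Louvain restarts, small-world surrogates)."""
    Wg = WeightedGraph(_apply_threshold(_as_matrix(g), edge_threshold))
    W = Wg.W
    rng = np.random.default_rng(rng)
    deg, stren = degree_strength(Wg)
    d = _shortest_paths(W)
    radius, diameter, cpl, geff = path_measures(d)
    clust, trans = _clustering_transitivity_raw(W)
    leff = local_efficiency(Wg)
    q, _ = louvain_modularity(Wg, gamma=louvain_gamma, restarts=louvain_restarts, rng=rng)
    assort = assortativity(Wg)
    sigma = small_worldness(
        Wg, n_null=sw_nulls, rewires_per_edge=sw_rewires_per_edge, rng=rng
    )
    return GraphMetricsRecord(
        subject_id=subject_id,
        band=band,
        degree=deg,
        strength=stren,
        radius=radius,
        diameter=diameter,
        characteristic_path_length=cpl,
        global_efficiency=geff,
        local_efficiency=leff,
        clustering_coefficient=clust,
        transitivity=trans,
        modularity=q,
        assortativity=assort,
        small_worldness=sigma,
        metadata={
            "edge_threshold": edge_threshold,
            "clustering_variant": "onnela_geometric_mean",
            "assortativity_variant": "weighted_endpoint_strength",
            "length_transform": "inverse_weight",
            "louvain_gamma": louvain_gamma,
            "louvain_restarts": louvain_restarts,
            "sw_nulls": sw_nulls,
            "sw_rewires_per_edge": sw_rewires_per_edge,
        },
    )


def metrics_table(
    subject_graphs: Sequence[tuple[str, Sequence]],
    config=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Long-format metric table for a cohort.

    ``subject_graphs`` is a sequence of (subject_id, coherence-graph list)
    pairs as produced by :func:`eegraph.connectivity.subject_connectivity`.
    A per-subject rng stream is derived from ``seed`` so results do not
    depend on processing order.
    """
    from .io import PipelineConfig, metrics_to_frame

    config = config or PipelineConfig()
    if seed is None:
        seed = config.seed
    records = []
    for s_idx, (subject_id, graphs) in enumerate(subject_graphs):
        for g_idx, graph in enumerate(graphs):
            rng = np.random.default_rng([seed, s_idx, g_idx])
            records.append(
                all_metrics(
                    graph.W,
                    subject_id=subject_id,
                    band=graph.band.name,
                    edge_threshold=config.edge_threshold,
                    louvain_gamma=config.louvain_gamma,
                    louvain_restarts=config.louvain_restarts,
                    sw_nulls=config.sw_nulls,
                    sw_rewires_per_edge=config.sw_rewires_per_edge,
                    rng=rng,
                )
            )
    return metrics_to_frame(records)
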