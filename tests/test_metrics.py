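"""Graph measures against closed-form cases and independent brute-force
oracles, plus scale-invariance and determinism properties."""

import numpy as np
import networkx as nx
import pytest

import eegraph as eg
from eegraph.io import ZeroWeightGraphError
from eegraph.metrics import rewired_null

from _oracles import (
    assortativity as o_assort,
    best_partition_modularity,
    clustering as o_clustering,
    degree_strength as o_degstr,
    distances as o_distances,
    local_efficiency as o_leff,
    modularity_value as o_modularity,
    path_measures as o_paths,
    transitivity as o_transitivity,
)
from conftest import random_weighted_graph


def complete_graph(n: int, w: float = 1.0) -> np.ndarray:
    W = np.full((n, n), w)
    np.fill_diagonal(W, 0.0)
    return W


def star_graph(n: int, w: float = 1.0) -> np.ndarray:
    W = np.zeros((n, n))
    W[0, 1:] = W[1:, 0] = w
    return W


class TestClosedForms:
    def test_degree_strength_complete(self):
        assert eg.degree_strength(complete_graph(19)) == (18.0, 18.0)
        deg, stren = eg.degree_strength(complete_graph(4, 0.5))
        assert (deg, stren) == (3.0, 1.5)

    def test_chain_distance(self):
        W = np.zeros((3, 3))
        W[0, 1] = W[1, 0] = 0.5
        W[1, 2] = W[2, 1] = 0.5
        d = eg.distance_matrix(W)
        assert d[0, 2] == pytest.approx(4.0)

    def test_complete_unit_distances_and_paths(self):
        d = eg.distance_matrix(complete_graph(6))
        assert np.all(d[~np.eye(6, dtype=bool)] == 1.0)
        radius, diameter, cpl, geff = eg.path_measures(d)
        assert (radius, diameter, cpl, geff) == (1.0, 1.0, 1.0, 1.0)

    def test_star_radius_diameter(self):
        d = eg.distance_matrix(star_graph(5))
        radius, diameter, _, _ = eg.path_measures(d)
        assert (radius, diameter) == (1.0, 2.0)

    def test_triangle_clustering_and_star_zero(self):
        assert eg.clustering_transitivity(complete_graph(3)) == (1.0, 1.0)
        assert eg.clustering_transitivity(star_graph(5)) == (0.0, 0.0)

    def test_local_efficiency_complete_and_star(self):
        assert eg.local_efficiency(complete_graph(4)) == pytest.approx(1.0)
        assert eg.local_efficiency(star_graph(5)) == 0.0

    def test_complete_graph_modularity_nonpositive(self):
        q, memb = eg.louvain_modularity(complete_graph(8), rng=0)
        assert q <= 1e-12

    def test_two_triangles_with_bridge(self):
        W = np.zeros((6, 6))
        for i, j in [(0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5)]:
            W[i, j] = W[j, i] = 1.0
        W[2, 3] = W[3, 2] = 0.1
        q, memb = eg.louvain_modularity(W, rng=0)
        assert len(set(memb[:3])) == 1 and len(set(memb[3:])) == 1
        assert memb[0] != memb[3]
        q_exh, _ = eg.exhaustive_modularity(W)
        assert q == pytest.approx(q_exh, abs=1e-12)
        assert q_exh == pytest.approx(best_partition_modularity(W), abs=1e-12)

    def test_ring_assortativity_degenerate_is_zero(self):
        W = np.zeros((6, 6))
        for i in range(6):
            W[i, (i + 1) % 6] = W[(i + 1) % 6, i] = 1.0
        assert eg.assortativity(W) == 0.0

    def test_star_assortativity_negative(self):
        assert eg.assortativity(star_graph(8)) < -0.5

    def test_small_worldness_identity_null(self):
        W = random_weighted_graph(np.random.default_rng(0), 10, density=0.5)
        sigma = eg.small_worldness(
            W, n_null=1, rewires_per_edge=0, rng=0, permute_weights=False
        )
        assert sigma == pytest.approx(1.0, abs=1e-12)

    def test_zero_weight_graph_rejected(self):
        with pytest.raises(ZeroWeightGraphError):
            eg.louvain_modularity(np.zeros((4, 4)))


@pytest.fixture(scope="module")
def graphs():
    rng = np.random.default_rng(2024)
    out = []
    for i in range(100):
        n = int(rng.integers(4, 9))
        density = 1.0 if i % 2 == 0 else float(rng.uniform(0.4, 0.9))
        out.append(random_weighted_graph(rng, n, density=density))
    return out


class TestOracleEquivalence:
    """Deterministic measures agree with naive-loop / networkx oracles to
    1e-9 on random weighted graphs (dense and sparsified) with n <= 8."""

    def test_degree_strength(self, graphs):
        for W in graphs:
            np.testing.assert_allclose(eg.degree_strength(W), o_degstr(W), atol=1e-9)

    def test_distances_vs_networkx_dijkstra(self, graphs):
        for W in graphs:
            np.testing.assert_allclose(eg.distance_matrix(W), o_distances(W), atol=1e-9)

    def test_path_measures(self, graphs):
        for W in graphs:
            d = eg.distance_matrix(W)
            np.testing.assert_allclose(eg.path_measures(d), o_paths(d), atol=1e-9)

    def test_clustering_and_transitivity(self, graphs):
        for W in graphs:
            c, t = eg.clustering_transitivity(W)
            assert c == pytest.approx(o_clustering(W), abs=1e-9)
            assert t == pytest.approx(o_transitivity(W), abs=1e-9)

    def test_clustering_vs_networkx(self, graphs):
        for W in graphs[:20]:
            g = nx.from_numpy_array(W)
            assert eg.clustering_transitivity(W)[0] == pytest.approx(
                nx.average_clustering(g, weight="weight"), abs=1e-9
            )

    def test_local_efficiency(self, graphs):
        for W in graphs:
            assert eg.local_efficiency(W) == pytest.approx(o_leff(W), abs=1e-9)

    def test_assortativity(self, graphs):
        for W in graphs:
            assert eg.assortativity(W) == pytest.approx(o_assort(W), abs=1e-9)

    def test_modularity_value_vs_oracle_and_networkx(self, graphs):
        rng = np.random.default_rng(5)
        for W in graphs[:20]:
            n = W.shape[0]
            memb = rng.integers(0, 3, size=n)
            q = eg.modularity_value(W, memb)
            assert q == pytest.approx(o_modularity(W, memb), abs=1e-9)
            communities = [set(np.where(memb == c)[0]) for c in np.unique(memb)]
            g = nx.from_numpy_array(W)
            assert q == pytest.approx(
                nx.community.modularity(g, communities, weight="weight"), abs=1e-9
            )


class TestProperties:
    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(9)
        W = random_weighted_graph(rng, 8, density=0.8)
        k = 3.7
        c1, t1 = eg.clustering_transitivity(W)
        c2, t2 = eg.clustering_transitivity(k * W)
        assert (c1, t1) == pytest.approx((c2, t2), abs=1e-12)
        memb = rng.integers(0, 2, size=8)
        assert eg.modularity_value(W, memb) == pytest.approx(
            eg.modularity_value(k * W, memb), abs=1e-12
        )
        d1, d2 = eg.distance_matrix(W), eg.distance_matrix(k * W)
        np.testing.assert_allclose(d2, d1 / k, atol=1e-12)
        r1 = eg.path_measures(d1)
        r2 = eg.path_measures(d2)
        np.testing.assert_allclose(r2[:3], np.asarray(r1[:3]) / k, atol=1e-12)

    def test_radius_le_diameter_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            W = random_weighted_graph(rng, int(rng.integers(4, 10)), density=0.6)
            radius, diameter, *_ = eg.path_measures(eg.distance_matrix(W))
            if np.isfinite(radius):
                assert radius <= diameter

    def test_rewired_null_preserves_degrees_and_weight_multiset(self):
        rng = np.random.default_rng(13)
        W = random_weighted_graph(rng, 12, density=0.4)
        null = rewired_null(W, rewires_per_edge=10, rng=rng)
        np.testing.assert_array_equal((null > 0).sum(axis=1), (W > 0).sum(axis=1))
        np.testing.assert_allclose(
            np.sort(null[np.triu_indices(12, 1)]), np.sort(W[np.triu_indices(12, 1)])
        )

    def test_small_worldness_calibration(self):
        """ER-like weighted graphs give sigma ~ 1; a weighted ring lattice
        with a few shortcuts gives sigma > 1."""
        rng = np.random.default_rng(17)
        sigmas = [
            eg.small_worldness(
                random_weighted_graph(rng, 16, density=0.4), n_null=10,
                rewires_per_edge=5, rng=i,
            )
            for i in range(10)
        ]
        assert abs(np.mean(sigmas) - 1.0) < 0.15
        # Watts-Strogatz-style: ring of 20 nodes, k=4 neighbours, shortcuts
        n = 20
        W = np.zeros((n, n))
        for i in range(n):
            for step in (1, 2):
                j = (i + step) % n
                W[i, j] = W[j, i] = 1.0
        for a, b in [(0, 10), (3, 13), (7, 17)]:
            W[a, b] = W[b, a] = 1.0
        sigma = eg.small_worldness(W, n_null=10, rewires_per_edge=10, rng=0)
        assert sigma > 1.1

    def test_all_metrics_deterministic_and_complete_graph_values(self):
        rec1 = eg.all_metrics(complete_graph(19), subject_id="s", band="beta", rng=7)
        rec2 = eg.all_metrics(complete_graph(19), subject_id="s", band="beta", rng=7)
        assert rec1 == rec2
        assert rec1.degree == 18.0 and rec1.strength == 18.0
        assert rec1.characteristic_path_length == 1.0
        assert rec1.global_efficiency == 1.0
        assert rec1.clustering_coefficient == pytest.approx(1.0)
        assert rec1.radius <= rec1.diameter

    def test_all_metrics_matches_component_functions(self):
        W = random_weighted_graph(np.random.default_rng(23), 8, density=0.7)
        rec = eg.all_metrics(W, rng=3)
        assert rec.degree == eg.degree_strength(W)[0]
        assert rec.strength == eg.degree_strength(W)[1]
        d = eg.distance_matrix(W)
        assert rec.radius == eg.path_measures(d)[0]
        assert rec.characteristic_path_length == eg.path_measures(d)[2]
        assert rec.clustering_coefficient == eg.clustering_transitivity(W)[0]
        assert rec.local_efficiency == eg.local_efficiency(W)
        assert rec.assortativity == eg.assortativity(W)

    def test_louvain_reproducible_under_seed(self):
        W = random_weighted_graph(np.random.default_rng(29), 12, density=0.8)
        q1, memb1 = eg.louvain_modularity(W, rng=5)
        q2, memb2 = eg.louvain_modularity(W, rng=5)
        assert q1 == q2
        np.testing.assert_array_equal(memb1, memb2)
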