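import numpy as np
import pytest
from scipy.spatial.distance import cdist

from mvmanifold import (
    MultiViewDataset,
    ViewWeights,
    build_knn_graph,
    classical_mds_embed,
    geodesic_distances,
    m_isomap_embed,
    multi_isomap_embed,
    single_view_isomap,
)
from mvmanifold.isomap import DisconnectedGraphError, NeighborGraph


def floyd_warshall_oracle(lengths):
    D = lengths.copy()
    n = D.shape[0]
    for k in range(n):
        D = np.minimum(D, D[:, k, None] + D[None, k, :])
    return D


class TestKnnGraph:
    def test_complete_graph_at_full_k(self, rng):
        X = rng.normal(size=(10, 3))
        g = build_knn_graph(X, K=9)
        np.testing.assert_allclose(g.edge_lengths, cdist(X, X), atol=1e-12)

    def test_hand_enumerated_line_k1(self):
        X = np.array([[0.0], [1.0], [3.0], [7.0]])
        g = build_knn_graph(X, K=1)
        finite = np.isfinite(g.edge_lengths)
        expected = np.zeros((4, 4), dtype=bool)
        for i, j in [(0, 1), (1, 2), (2, 3)]:
            expected[i, j] = expected[j, i] = True
        np.fill_diagonal(expected, True)
        np.testing.assert_array_equal(finite, expected)
        assert g.edge_lengths[0, 1] == 1.0
        assert g.edge_lengths[1, 2] == 2.0
        assert g.edge_lengths[2, 3] == 4.0

    def test_symmetric_zero_diagonal(self, rng):
        g = build_knn_graph(rng.normal(size=(15, 2)), K=3)
        np.testing.assert_array_equal(g.edge_lengths, g.edge_lengths.T)
        assert np.all(np.diag(g.edge_lengths) == 0)

    def test_k_capped_at_n_minus_one(self, rng):
        g = build_knn_graph(rng.normal(size=(8, 2)), K=300)
        assert g.K == 7


class TestGeodesics:
    def test_convex_position_complete_graph_euclidean(self, rng):
        theta = np.linspace(0, 2 * np.pi, 9, endpoint=False)
        X = np.c_[np.cos(theta), np.sin(theta)]
        geo = geodesic_distances(build_knn_graph(X, K=8))
        np.testing.assert_allclose(geo.D_G, cdist(X, X), atol=1e-10)

    def test_chain_path_sum(self):
        X = np.array([[0.0], [1.0], [3.0], [7.0]])
        geo = geodesic_distances(build_knn_graph(X, K=1))
        assert geo.D_G[0, 3] == pytest.approx(7.0)
        assert geo.component_count == 1

    def test_two_components_inf_across(self):
        X = np.array([[0.0], [1.0], [100.0], [101.0]])
        geo = geodesic_distances(build_knn_graph(X, K=1))
        assert geo.component_count == 2
        assert np.isinf(geo.D_G[0, 2])

    def test_dijkstra_matches_floyd_warshall(self, rng):
        X = rng.normal(size=(40, 3))
        g = build_knn_graph(X, K=4)
        geo = geodesic_distances(g)
        np.testing.assert_allclose(
            geo.D_G, floyd_warshall_oracle(g.edge_lengths), atol=1e-12
        )


class TestClassicalMds:
    def test_exact_on_euclidean_distances(self, rng):
        X = rng.normal(size=(12, 2))
        D = cdist(X, X)
        e = classical_mds_embed(D, d=2)
        np.testing.assert_allclose(cdist(e.coords, e.coords), D, atol=1e-8)

    def test_collinear_three_points(self):
        D = cdist(np.array([[0.0], [1.0], [3.0]]), np.array([[0.0], [1.0], [3.0]]))
        with pytest.warns(RuntimeWarning):
            e = classical_mds_embed(D, d=2)  # only one positive eigenvalue
        np.testing.assert_allclose(cdist(e.coords, e.coords), D, atol=1e-8)
        assert np.all(e.coords[:, 1] == 0)

    def test_columns_centred(self, rng):
        D = cdist(rng.normal(size=(10, 3)), rng.normal(size=(10, 3)))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        e = classical_mds_embed(D, d=2)
        assert np.all(np.abs(e.coords.mean(axis=0)) < 1e-10)

    def test_disconnected_raises_with_remedy(self):
        D = np.array([[0.0, np.inf], [np.inf, 0.0]])
        with pytest.raises(DisconnectedGraphError, match="increase K"):
            classical_mds_embed(D, d=1)


class TestMultiIsomap:
    def test_single_view_reduction(self, rng):
        X = rng.normal(size=(20, 3))
        e1 = multi_isomap_embed(MultiViewDataset(views=[X]), K=6)
        e2 = single_view_isomap(X, K=6)
        np.testing.assert_allclose(e1.coords, e2.coords, atol=1e-8)

    def test_duplicated_views_reduction(self, rng):
        X = rng.normal(size=(20, 3))
        e1 = multi_isomap_embed(MultiViewDataset(views=[X, X.copy()]), K=6)
        e2 = single_view_isomap(X, K=6)
        np.testing.assert_allclose(e1.coords, e2.coords, atol=1e-8)

    def test_union_edge_average_lengths(self, rng):
        X1 = rng.normal(size=(10, 2))
        X2 = rng.normal(size=(10, 2))
        ds = MultiViewDataset(views=[X1, X2])
        g1 = build_knn_graph(X1, 2).edge_lengths
        g2 = build_knn_graph(X2, 2).edge_lengths
        # reconstruct the combined graph the way the method defines it
        f1, f2 = np.isfinite(g1), np.isfinite(g2)
        both = f1 & f2
        only1 = f1 & ~f2
        num = np.where(both, (g1 + g2) / 2, np.where(only1, g1, g2))
        # verify through geodesics of a connected instance if possible
        from mvmanifold.isomap import _masked_csr, geodesic_distances as gd

        combined = NeighborGraph(
            edge_lengths=np.where(f1 | f2, num, np.inf), K=2
        )
        geo = gd(combined)
        if geo.component_count == 1:
            e = multi_isomap_embed(ds, K=2)
            expected = classical_mds_embed(geo, d=2)
            np.testing.assert_allclose(e.coords, expected.coords, atol=1e-8)

    def test_largest_component_optin(self):
        X = np.array([[0.0], [1.0], [2.0], [50.0], [51.0]])
        ds = MultiViewDataset(views=[X])
        with pytest.raises(DisconnectedGraphError):
            multi_isomap_embed(ds, K=1)
        e = multi_isomap_embed(ds, K=1, largest_component=True, d=1)
        np.testing.assert_array_equal(e.sample_index, [0, 1, 2])

    def test_m_isomap_is_weighted_average(self, rng):
        ds = MultiViewDataset(
            views=[rng.normal(size=(15, 3)), rng.normal(size=(15, 3))]
        )
        beta = ViewWeights(values=np.array([0.25, 0.75]))
        e = m_isomap_embed(ds, K=14, beta=beta)
        parts = [single_view_isomap(v, K=14).coords for v in ds.views]
        np.testing.assert_allclose(
            e.coords, 0.25 * parts[0] + 0.75 * parts[1], atol=1e-10
        )
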