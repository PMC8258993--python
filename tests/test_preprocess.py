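import numpy as np
import pytest

from murkscreen import (
    PreprocessConfig,
    build_neighbor_graph,
    filter_genes_shared_counts,
    knn_impute,
    normalize_layers,
)
from murkscreen.errors import ConfigError, EmptyPanelError, InvalidParameterError
from murkscreen.preprocess import NeighborGraph, shared_counts

from .conftest import toy_layers


class TestSharedCountFilter:
    def test_toy_score_from_coexpressing_cells(self):
        # cells expressing both layers: rows 0 and 3; spliced sum 7, unspliced 5
        U = np.array([[1], [0], [2], [4], [0]])
        S = np.array([[3], [2], [0], [4], [0]])
        layers = toy_layers(U, S)
        assert shared_counts(layers)[0] == 5
        assert filter_genes_shared_counts(layers, 5).n_genes == 1
        with pytest.raises(EmptyPanelError):
            filter_genes_shared_counts(layers, 6)

    def test_all_zero_unspliced_gene_removed(self):
        U = np.array([[0, 1], [0, 2]])
        S = np.array([[5, 1], [7, 2]])
        out = filter_genes_shared_counts(toy_layers(U, S), 1)
        assert list(out.gene_ids) == ["g1"]

    def test_threshold_zero_is_identity(self):
        U = np.array([[0, 1], [0, 2]])
        S = np.array([[5, 1], [7, 2]])
        layers = toy_layers(U, S)
        out = filter_genes_shared_counts(layers, 0)
        assert out.n_genes == 2
        np.testing.assert_array_equal(out.U, U)


class TestNormalize:
    def test_identical_totals_reduce_to_log1p(self):
        U = np.array([[1, 3], [2, 2]])  # totals 4, 4
        S = np.array([[2, 2], [3, 1]])
        out = normalize_layers(toy_layers(U, S))
        np.testing.assert_allclose(out.U, np.log1p(U))
        np.testing.assert_allclose(out.S, np.log1p(S))
        assert out.stage == "normalized"

    def test_two_cell_size_factors(self):
        # totals 100 and 300, median 200: cell 0 scaled x2, cell 1 x 2/3
        S = np.array([[60, 40], [200, 100]])
        U = np.array([[50, 50], [150, 150]])
        out = normalize_layers(toy_layers(U, S))
        np.testing.assert_allclose(out.S[0], np.log1p(np.array([120, 80])))
        np.testing.assert_allclose(out.S[1], np.log1p(np.array([200, 100]) * 2 / 3))

    def test_size_factor_invariance_to_cell_scaling(self):
        # doubling every count of one cell leaves its normalized profile
        # unchanged, provided the median cell total is unaffected
        S = np.array([[25, 15], [5, 5], [6, 6], [7, 7]])  # cell 0 is the largest
        U = S.copy()
        out1 = normalize_layers(toy_layers(U, S))
        out2 = normalize_layers(toy_layers(U * np.array([[2], [1], [1], [1]]),
                                           S * np.array([[2], [1], [1], [1]])))
        np.testing.assert_allclose(out2.S[0], out1.S[0])
        np.testing.assert_allclose(out2.U[0], out1.U[0])

    def test_zero_total_cell_warns_and_gets_unit_factor(self):
        U = np.array([[0, 0], [3, 1]])
        S = np.array([[1, 1], [2, 2]])
        with pytest.warns(UserWarning, match="zero layer total"):
            out = normalize_layers(toy_layers(U, S))
        np.testing.assert_allclose(out.U[0], 0.0)


class TestNeighborGraph:
    def test_matches_brute_force_on_toy_points(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(10, 2))
        layers = toy_layers(np.zeros((10, 3)), np.zeros((10, 3)), stage="normalized")
        cfg = PreprocessConfig(k_neighbors=4, min_shared_counts=0)
        graph = build_neighbor_graph(layers, cfg, embedding=X)
        D = np.linalg.norm(X[:, None] - X[None], axis=2)
        for i in range(10):
            expected = np.argsort(D[i])[1:5]
            assert set(graph.indices[i]) == set(expected)

    def test_identical_cells_are_mutual_nearest_at_zero_distance(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0]])
        layers = toy_layers(np.zeros((3, 2)), np.zeros((3, 2)), stage="normalized")
        graph = build_neighbor_graph(layers, PreprocessConfig(k_neighbors=1), embedding=X)
        assert graph.indices[0][0] == 1 and graph.indices[1][0] == 0
        assert graph.distances[0][0] == 0.0

    def test_k_too_large_raises(self):
        layers = toy_layers(np.zeros((5, 2)), np.zeros((5, 2)), stage="normalized")
        with pytest.raises(ConfigError):
            build_neighbor_graph(layers, PreprocessConfig(k_neighbors=5))

    def test_k_equals_n_minus_one_covers_everyone(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 2))
        layers = toy_layers(np.zeros((6, 2)), np.zeros((6, 2)), stage="normalized")
        graph = build_neighbor_graph(layers, PreprocessConfig(k_neighbors=5), embedding=X)
        for i in range(6):
            assert set(graph.indices[i]) == set(range(6)) - {i}


class TestImpute:
    def test_hand_computed_neighborhood_means(self):
        vals = np.array([[0.0], [1.0], [2.0], [3.0], [10.0]])
        layers = toy_layers(vals, vals * 2, stage="normalized")
        idx = np.array([[1], [0], [3], [2], [3]])
        graph = NeighborGraph(indices=idx, distances=np.zeros_like(idx, float))
        out = knn_impute(layers, graph)
        np.testing.assert_allclose(out.U[:, 0], [0.5, 0.5, 2.5, 2.5, 6.5])
        np.testing.assert_allclose(out.S, out.U * 2)
        assert out.stage == "imputed"

    def test_constant_gene_unchanged(self):
        vals = np.full((6, 1), 3.3)
        layers = toy_layers(vals, vals, stage="normalized")
        idx = np.array([[1, 2], [0, 2], [3, 4], [5, 0], [1, 3], [2, 4]])
        graph = NeighborGraph(indices=idx, distances=np.zeros_like(idx, float))
        out = knn_impute(layers, graph)
        np.testing.assert_allclose(out.U, vals)

    def test_full_graph_gives_global_mean(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(size=(5, 2))
        layers = toy_layers(vals, vals, stage="normalized")
        idx = np.array([[j for j in range(5) if j != i] for i in range(5)])
        graph = NeighborGraph(indices=idx, distances=np.zeros_like(idx, float))
        out = knn_impute(layers, graph)
        np.testing.assert_allclose(out.U, np.tile(vals.mean(0), (5, 1)))

    def test_smoother_bounds_and_mean_preservation_on_symmetric_graph(self):
        # ring graph: symmetric, uniform weights -> per-gene mean preserved
        rng = np.random.default_rng(8)
        n = 12
        vals = rng.normal(size=(n, 3))
        layers = toy_layers(vals, vals, stage="normalized")
        idx = np.array([[(i - 1) % n, (i + 1) % n] for i in range(n)])
        graph = NeighborGraph(indices=idx, distances=np.zeros_like(idx, float))
        out = knn_impute(layers, graph)
        assert np.all(out.U.min(0) >= vals.min(0) - 1e-12)
        assert np.all(out.U.max(0) <= vals.max(0) + 1e-12)
        np.testing.assert_allclose(out.U.mean(0), vals.mean(0), atol=1e-12)

    def test_graph_cell_mismatch_raises(self):
        layers = toy_layers(np.zeros((4, 1)), np.zeros((4, 1)), stage="normalized")
        graph = NeighborGraph(indices=np.zeros((3, 1), int),
                              distances=np.zeros((3, 1)))
        with pytest.raises(InvalidParameterError):
            knn_impute(layers, graph)


def test_cell_permutation_equivariance():
    rng = np.random.default_rng(11)
    U = rng.poisson(5, (30, 8))
    S = rng.poisson(8, (30, 8))
    layers = toy_layers(U, S)
    perm = rng.permutation(30)
    permuted = toy_layers(U[perm], S[perm])

    f1 = normalize_layers(filter_genes_shared_counts(layers, 3))
    f2 = normalize_layers(filter_genes_shared_counts(permuted, 3))
    np.testing.assert_allclose(f1.U[perm], f2.U)
    np.testing.assert_allclose(f1.S[perm], f2.S)

    # imputation with the correspondingly permuted graph commutes as well
    idx = np.array([[(i + 1) % 30, (i + 2) % 30] for i in range(30)])
    inv = np.argsort(perm)
    g1 = NeighborGraph(indices=idx, distances=np.zeros_like(idx, float))
    g2 = NeighborGraph(indices=inv[idx][perm], distances=np.zeros_like(idx, float))
    out1 = knn_impute(f1, g1)
    out2 = knn_impute(f2, g2)
    np.testing.assert_allclose(out1.U[perm], out2.U)
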