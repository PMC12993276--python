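"""Normalization, log transform, HVG selection, KNN graph, augmentations."""

import numpy as np
import pytest

from scdmac import (AugmentationConfig, CountMatrix, augment, build_knn_graph,
                    log1p_transform, normalize_library_size, select_hvg)


def cm(values, prefix=""):
    values = np.asarray(values, dtype=float)
    return CountMatrix(values,
                       [f"{prefix}c{i}" for i in range(values.shape[0])],
                       [f"{prefix}g{j}" for j in range(values.shape[1])])


class TestCountMatrix:
    def test_rejects_negative_values(self):
        with pytest.raises(ValueError, match="negative"):
            cm([[1, -1]])

    def test_rejects_mismatched_identifiers(self):
        with pytest.raises(ValueError):
            CountMatrix(np.ones((2, 2)), ["a"], ["g1", "g2"])

    def test_rejects_duplicate_identifiers(self):
        with pytest.raises(ValueError):
            CountMatrix(np.ones((2, 2)), ["a", "a"], ["g1", "g2"])


class TestNormalize:
    def test_row_rescaled_to_target(self):
        norm = normalize_library_size(cm([[1, 1, 2]]), s0=10000)
        assert np.allclose(norm.values, [[2500, 2500, 5000]])

    def test_row_already_at_target_unchanged(self):
        norm = normalize_library_size(cm([[10000, 0]]), s0=10000)
        assert np.allclose(norm.values, [[10000, 0]])

    def test_all_rows_sum_to_s0(self, rng):
        X = cm(rng.poisson(3.0, size=(40, 25)) + 1)
        norm = normalize_library_size(X, s0=1e4)
        assert np.allclose(norm.values.sum(axis=1), 1e4, rtol=1e-6)

    def test_zero_cell_dropped_with_warning(self, caplog):
        X = cm([[1, 2], [0, 0], [3, 1]])
        with caplog.at_level("WARNING"):
            norm = normalize_library_size(X)
        assert norm.values.shape[0] == 2
        assert list(norm.kept_cells) == [0, 2]
        assert any("all-zero" in r.message for r in caplog.records)

    def test_size_factors_are_library_over_median(self):
        X = cm([[2, 0], [0, 4], [8, 0]])
        norm = normalize_library_size(X)
        assert np.allclose(norm.size_factors, [0.5, 1.0, 2.0])


class TestLog1p:
    def test_closed_forms(self):
        assert log1p_transform(np.array([0.0]))[0] == 0.0
        assert np.isclose(log1p_transform(np.array([np.e - 1]))[0], 1.0)

    def test_roundtrip(self, rng):
        x = rng.uniform(0, 50, size=(20, 10))
        assert np.allclose(np.expm1(log1p_transform(x)), x, atol=1e-9)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            log1p_transform(np.array([-0.1]))


class TestSelectHVG:
    def test_all_genes_is_identity(self):
        X = cm(np.arange(12).reshape(3, 4))
        assert np.array_equal(select_hvg(X, 4), np.arange(4))

    def test_nonpositive_n_top_rejected(self):
        with pytest.raises(ValueError):
            select_hvg(cm(np.ones((3, 4))), 0)

    def test_planted_signal_genes_selected(self):
        # 10 planted genes carry cluster signal (same overall mean as the 490
        # flat Poisson noise genes, so only their dispersion differs)
        rng = np.random.default_rng(5)
        n, g = 300, 500
        labels = rng.integers(0, 2, size=n)
        base = np.exp(rng.uniform(np.log(1.0), np.log(20.0), size=g))
        means = np.tile(base, (n, 1))
        means[labels == 0, :10] = 1.0
        means[labels == 1, :10] = 9.0
        X = cm(rng.poisson(means))
        top = select_hvg(X, 50)
        assert len(top) == 50
        assert set(range(10)) <= set(top.tolist())
        # cross-check: the planted genes have the largest raw dispersion
        norm = normalize_library_size(X)
        disp = (norm.values.var(axis=0)
                / np.maximum(norm.values.mean(axis=0), 1e-12))
        assert set(np.argsort(disp)[-10:]) == set(range(10))

    def test_constant_gene_ranks_below_variable_genes(self):
        # equal library sizes keep a constant-count gene constant after
        # normalization, hence zero dispersion
        rng = np.random.default_rng(8)
        n, g = 100, 30
        rest = rng.multinomial(233, np.full(g - 1, 1 / (g - 1)), size=n)
        vals = np.insert(rest, 7, 7, axis=1).astype(float)  # rows all sum 240
        X = cm(vals)
        assert 7 not in select_hvg(X, 29)


class TestKNNGraph:
    def test_identical_cells_are_mutual_nearest(self):
        X = np.array([[1.0, 0], [1.0, 0], [0, 5.0], [3, 4.0]])
        g = build_knn_graph(X, k=1)
        assert g.neighbor_indices[0, 0] == 1
        assert g.neighbor_indices[1, 0] == 0

    def test_invariant_to_positive_rescaling(self, rng):
        X = rng.uniform(0.1, 5, size=(20, 6))
        scaled = X * rng.uniform(0.5, 10, size=(20, 1))
        g1 = build_knn_graph(X, k=4)
        g2 = build_knn_graph(scaled, k=4)
        assert np.array_equal(g1.neighbor_indices, g2.neighbor_indices)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.uniform(0.1, 3, size=(30, 5))
        k = 6
        g = build_knn_graph(X, k=k)
        unit = X / np.linalg.norm(X, axis=1, keepdims=True)
        for i in range(30):
            d = 1.0 - unit @ unit[i]
            d[i] = np.inf
            expected = sorted(range(30), key=lambda j: (d[j], j))[:k]
            assert list(g.neighbor_indices[i]) == expected

    def test_no_self_neighbors_and_k_validation(self, rng):
        X = rng.uniform(0.1, 1, size=(10, 4))
        g = build_knn_graph(X, k=3)
        assert all(i not in g.neighbor_indices[i] for i in range(10))
        with pytest.raises(ValueError):
            build_knn_graph(X, k=10)

    def test_zero_norm_row_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            build_knn_graph(np.array([[1.0, 0], [0.0, 0]]), k=1)


class TestAugment:
    def setup_method(self):
        rng = np.random.default_rng(1)
        self.X = rng.uniform(0.5, 4, size=(30, 20))
        self.graph = build_knn_graph(self.X, k=5)

    def test_identity_configuration(self):
        cfg = AugmentationConfig(mask_fraction=0, noise_variance=0, swap_ratio=0)
        out = augment(self.X, self.graph, cfg)
        assert np.array_equal(out, self.X)

    def test_full_masking_zeroes_everything(self):
        cfg = AugmentationConfig(mask_fraction=1.0, noise_variance=0, swap_ratio=0)
        assert np.all(augment(self.X, self.graph, cfg) == 0)

    def test_noise_moments(self):
        rng = np.random.default_rng(11)
        X = np.zeros((1000, 100))
        g = build_knn_graph(np.ones((1000, 2)) + np.arange(1000)[:, None] * 1e-4, k=2)
        cfg = AugmentationConfig(mask_fraction=0, noise_variance=0.6, swap_ratio=0)
        diff = augment(X, g, cfg, rng) - X
        assert abs(diff.mean()) < 0.01
        assert abs(diff.var() - 0.6) < 0.03  # within 5%

    def test_swap_preserves_global_multiset(self):
        cfg = AugmentationConfig(mask_fraction=0, noise_variance=0, swap_ratio=0.4)
        out = augment(self.X, self.graph, cfg, np.random.default_rng(2))
        assert not np.array_equal(out, self.X)
        assert np.allclose(np.sort(out.ravel()), np.sort(self.X.ravel()))

    def test_seeded_reproducibility(self):
        cfg = AugmentationConfig(seed=9)
        a = augment(self.X, self.graph, cfg, np.random.default_rng(9))
        b = augment(self.X, self.graph, cfg, np.random.default_rng(9))
        assert np.array_equal(a, b)

    def test_input_unmodified(self):
        before = self.X.copy()
        augment(self.X, self.graph, AugmentationConfig(seed=1))
        assert np.array_equal(self.X, before)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            AugmentationConfig(mask_fraction=1.5)
        with pytest.raises(ValueError):
            AugmentationConfig(noise_variance=-1)
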