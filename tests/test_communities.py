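"""Pooling and spectral community discovery over supercell descriptors."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from supercellgraph import (
    CommunityModel, assign_communities, eigengap_select, gaussian_affinity,
    laplacian_spectrum, normalized_laplacian, pool_descriptors, spectral_cluster,
)
from supercellgraph.errors import DataSizeError, DegenerateDataError, SchemaError
from supercellgraph.supercells import Supercell


def _fake_supercells(image_id, n):
    return [Supercell(i, image_id, np.array([i]), np.zeros(2)) for i in range(n)]


def _blob_matrix(seed, n_per=60, k=2, sep=20.0, D=4):
    rng = np.random.default_rng(seed)
    means = sep * np.eye(k, D)
    labels = np.repeat(np.arange(k), n_per)
    return means[labels] + rng.normal(size=(k * n_per, D)), labels


def block_affinity(rng, block_sizes):
    """Block-diagonal affinity with random positive within-block weights."""
    n = sum(block_sizes)
    A = np.zeros((n, n))
    start = 0
    for size in block_sizes:
        B = rng.uniform(0.5, 1.0, size=(size, size))
        B = (B + B.T) / 2
        np.fill_diagonal(B, 0.0)
        A[start:start + size, start:start + size] = B
        start += size
    return A


class TestPoolDescriptors:
    def test_bookkeeping_and_provenance(self):
        rng = np.random.default_rng(0)
        per_image = [
            (f"img{i}", _fake_supercells(f"img{i}", 4), rng.normal(size=(4, 3)))
            for i in range(3)
        ]
        pooled = pool_descriptors(per_image)
        assert pooled.matrix.shape == (12, 3)
        assert len(pooled.index) == 12
        # provenance round-trip: scattered labels land on the right image
        labels = np.arange(12)
        back = {}
        for row, (image_id, sc_id) in enumerate(pooled.index):
            back.setdefault(image_id, {})[sc_id] = labels[row]
        assert back["img1"][2] == 6

    def test_column_means_are_zero_after_pooling(self):
        rng = np.random.default_rng(1)
        pooled = pool_descriptors([("a", _fake_supercells("a", 12), rng.normal(5, 3, (12, 4)))])
        np.testing.assert_allclose(pooled.matrix.mean(axis=0), 0.0, atol=1e-12)

    def test_fewer_than_ten_supercells_is_an_error(self):
        with pytest.raises(DataSizeError):
            pool_descriptors([("a", _fake_supercells("a", 9), np.zeros((9, 2)))])


class TestSpectralMachinery:
    def test_block_diagonal_affinity_has_one_zero_eigenvalue_per_block(self):
        rng = np.random.default_rng(0)
        for sizes in ([10, 15], [8, 8, 12], [5, 6, 7, 8]):
            A = block_affinity(rng, sizes)
            vals, _ = laplacian_spectrum(A)
            assert int((vals < 1e-8).sum()) == len(sizes)
            assert eigengap_select(vals) == len(sizes)

    def test_laplacian_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        A = block_affinity(rng, [6, 6])
        D = np.diag(A.sum(1))
        L_direct = np.eye(12) - np.linalg.inv(np.sqrt(D)) @ A @ np.linalg.inv(np.sqrt(D))
        np.testing.assert_allclose(normalized_laplacian(A), L_direct, atol=1e-12)

    def test_eigengap_tie_goes_to_smallest_k(self):
        vals = np.array([0.0, 0.0, 0.5, 0.5, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0])
        assert eigengap_select(vals) == 2  # gaps at k=2 and k=4 both 0.5


class TestSpectralCluster:
    def test_two_separated_blobs_auto_selects_two_and_recovers(self):
        X, truth = _blob_matrix(0)
        model = spectral_cluster(X, "auto", seed=0)
        assert model.n_communities == 2
        assert adjusted_rand_score(truth, model.training_labels) == 1.0

    def test_explicit_k_overrides_eigengap(self):
        X, _ = _blob_matrix(1)
        assert spectral_cluster(X, 3, seed=0).n_communities == 3

    def test_eigenvalues_lie_in_zero_two(self):
        X, _ = _blob_matrix(2, n_per=30)
        model = spectral_cluster(X, "auto", seed=0)
        assert model.eigenvalues.min() >= -1e-8
        assert model.eigenvalues.max() <= 2.0 + 1e-8
        assert model.eigenvalues[0] <= 1e-8

    def test_identical_rows_is_a_degenerate_affinity_error(self):
        with pytest.raises(DegenerateDataError):
            spectral_cluster(np.ones((20, 3)), 2, seed=0)

    def test_same_matrix_same_seed_identical_labels(self):
        X, _ = _blob_matrix(3, k=3)
        a = spectral_cluster(X, "auto", seed=9)
        b = spectral_cluster(X, "auto", seed=9)
        np.testing.assert_array_equal(a.training_labels, b.training_labels)
        np.testing.assert_array_equal(a.embedding_basis, b.embedding_basis)

    def test_too_few_rows_is_an_error(self):
        with pytest.raises(DataSizeError):
            spectral_cluster(np.random.default_rng(0).normal(size=(5, 2)), 4, seed=0)


class TestAssignCommunities:
    def _fitted(self, seed=0):
        X, truth = _blob_matrix(seed)
        means, sds = X.mean(0), X.std(0, ddof=1)
        Z = (X - means) / sds
        model = spectral_cluster(Z, 2, seed=seed, standardization=(means, sds))
        return model, X, truth

    def test_training_rows_keep_fit_time_labels(self):
        model, X, _ = self._fitted()
        np.testing.assert_array_equal(assign_communities(model, X), model.training_labels)

    def test_duplicate_of_training_row_gets_same_label(self):
        model, X, _ = self._fitted()
        lab = assign_communities(model, X[17:18])
        assert lab[0] == model.training_labels[17]

    def test_out_of_sample_blob_draws_get_blob_labels(self):
        model, X, truth = self._fitted()
        rng = np.random.default_rng(99)
        new = X[truth == 1][:20] + rng.normal(0, 0.3, size=(20, X.shape[1]))
        blob1_label = model.training_labels[truth == 1][0]
        assert (assign_communities(model, new) == blob1_label).mean() >= 0.95

    def test_dimension_mismatch_is_a_schema_error(self):
        model, X, _ = self._fitted()
        with pytest.raises(SchemaError):
            assign_communities(model, X[:, :2])


def test_model_save_load_round_trip(tmp_path):
    X, _ = _blob_matrix(5)
    model = spectral_cluster(X, 2, seed=1)
    model.save(tmp_path / "cm.yaml")
    back = CommunityModel.load(tmp_path / "cm.yaml")
    assert back.n_communities == model.n_communities
    np.testing.assert_array_equal(back.training_labels, model.training_labels)
    np.testing.assert_array_equal(back.embedding_basis, model.embedding_basis)
    assert back.kernel_bandwidth == pytest.approx(model.kernel_bandwidth)
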