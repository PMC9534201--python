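"""Standardization and unsupervised phenotype discovery."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from supercellgraph import (
    CellTable, PhenotypeModel, assign_phenotypes, fit_cell_phenotypes, standardize,
)
from supercellgraph.errors import ConfigError, DataSizeError, DegenerateDataError, SchemaError


def _table(features, image_id="i", feature_names=None):
    features = np.atleast_2d(np.asarray(features, dtype=float))
    n, F = features.shape
    return CellTable(
        image_id, np.arange(n), np.zeros((n, 2)), features,
        feature_names or [f"f{j}" for j in range(F)],
    )


def _blobs(seed, n_per=100, sep=10.0, k=3, F=3, sd=1.0):
    rng = np.random.default_rng(seed)
    means = sep * np.eye(k, F)
    labels = np.repeat(np.arange(k), n_per)
    X = means[labels] + rng.normal(0, sd, size=(k * n_per, F))
    return X, labels


class TestStandardize:
    def test_zscore_has_mean_zero_and_sample_sd_one(self):
        std = standardize([_table([[2.0], [4.0]])])
        np.testing.assert_allclose(std.matrix.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(std.matrix.std(axis=0, ddof=1), 1.0)
        np.testing.assert_allclose(std.matrix[:, 0], [-np.sqrt(0.5), np.sqrt(0.5)])

    def test_constant_column_is_dropped_and_reported(self):
        t = _table([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]], feature_names=["area", "solidity"])
        std = standardize([t])
        assert std.dropped_features == ["solidity"]
        assert std.feature_names == ["area"]
        assert std.matrix.shape == (3, 1)

    def test_standardizing_standardized_data_is_a_fixed_point(self):
        rng = np.random.default_rng(0)
        std = standardize([_table(rng.normal(2.0, 3.0, size=(50, 2)))])
        again = standardize([_table(std.matrix)])
        np.testing.assert_allclose(again.matrix, std.matrix, atol=1e-12)

    def test_mismatched_feature_names_is_a_schema_error(self):
        a = _table([[1.0], [2.0]], feature_names=["area"])
        b = _table([[1.0], [2.0]], feature_names=["perimeter"])
        with pytest.raises(SchemaError):
            standardize([a, b])

    def test_all_constant_features_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            standardize([_table([[1.0], [1.0], [1.0]])])


class TestFitCellPhenotypes:
    def test_recovers_three_planted_blobs(self):
        X, truth = _blobs(0)
        model = fit_cell_phenotypes(X, (2, 6), seed=0)
        assert model.k_cells == 3
        labels = model.training_labels
        assert adjusted_rand_score(truth, labels) >= 0.99

    def test_single_candidate_k_is_forced(self):
        X, _ = _blobs(1)
        assert fit_cell_phenotypes(X, (4, 4), seed=0).k_cells == 4

    def test_same_seed_gives_bitwise_identical_centroids(self):
        X, _ = _blobs(2)
        a = fit_cell_phenotypes(X, (2, 4), seed=5)
        b = fit_cell_phenotypes(X, (2, 4), seed=5)
        np.testing.assert_array_equal(a.centroids, b.centroids)
        assert a.silhouette_by_k == b.silhouette_by_k

    def test_k_range_below_two_is_a_config_error(self):
        X, _ = _blobs(0)
        with pytest.raises(ConfigError):
            fit_cell_phenotypes(X, (1, 3), seed=0)

    def test_too_few_rows_is_a_data_size_error(self):
        with pytest.raises(DataSizeError):
            fit_cell_phenotypes(np.random.default_rng(0).normal(size=(30, 2)), (2, 6), seed=0)


class TestAssignPhenotypes:
    def _fitted(self, seed=0):
        X, truth = _blobs(seed)
        tables = [_table(X[:150], "a"), _table(X[150:], "b")]
        std = standardize(tables)
        model = fit_cell_phenotypes(std.matrix, (3, 3), seed=seed, standardization=std)
        return model, tables, std

    def test_cell_at_centroid_gets_that_label(self):
        model, _, _ = self._fitted()
        raw = model.centroids[2] * model.feature_sds + model.feature_means
        t = _table(raw[None, :])
        assert assign_phenotypes(model, t)[0] == 2

    def test_equidistant_tie_goes_to_lowest_index(self):
        model = PhenotypeModel(
            k_cells=2, centroids=np.array([[-1.0], [1.0]]),
            feature_means=np.zeros(1), feature_sds=np.ones(1),
            feature_names=["f0"], dropped_features=[], silhouette_by_k={2: 1.0}, seed=0,
        )
        assert assign_phenotypes(model, _table([[0.0]]))[0] == 0

    def test_training_data_keeps_fit_time_labels(self):
        model, tables, std = self._fitted()
        assigned = np.concatenate([assign_phenotypes(model, t) for t in tables])
        np.testing.assert_array_equal(assigned, model.training_labels)

    def test_invariant_to_affine_rescaling_of_raw_features(self):
        """Standardization with stored means/sds makes assignment scale-free."""
        X, _ = _blobs(3)
        tables = [_table(X)]
        std = standardize(tables)
        model = fit_cell_phenotypes(std.matrix, (3, 3), seed=0, standardization=std)
        base = assign_phenotypes(model, tables[0])
        # rescale the raw data *and* the model's stored statistics consistently
        scale, shift = np.array([3.0, 0.5, 10.0]), np.array([100.0, -4.0, 0.0])
        rescaled_model = PhenotypeModel(
            model.k_cells, model.centroids,
            model.feature_means * scale + shift, model.feature_sds * scale,
            model.feature_names, model.dropped_features, model.silhouette_by_k, model.seed,
        )
        rescaled = assign_phenotypes(rescaled_model, _table(X * scale + shift))
        np.testing.assert_array_equal(rescaled, base)

    def test_missing_model_feature_is_a_schema_error(self):
        model, _, _ = self._fitted()
        with pytest.raises(SchemaError):
            assign_phenotypes(model, _table([[1.0]], feature_names=["other"]))


def test_model_save_load_round_trip(tmp_path):
    X, _ = _blobs(4)
    model = fit_cell_phenotypes(X, (2, 4), seed=1)
    model.save(tmp_path / "model.yaml")
    back = PhenotypeModel.load(tmp_path / "model.yaml")
    assert back.k_cells == model.k_cells
    np.testing.assert_array_equal(back.centroids, model.centroids)
    assert back.silhouette_by_k == pytest.approx(model.silhouette_by_k)
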