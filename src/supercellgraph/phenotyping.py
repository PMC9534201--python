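"""Cell phenotyping: cohort-level feature standardization and unsupervised
discovery of cell subtypes.

Features are z-scored *pooled across all images* (cohort-level), so that a
phenotype means the same thing in every image — the framework compares
phenotype composition across images, which a per-image standardization would
break. Phenotypes are found by k-means with the number of clusters selected
by mean silhouette over a candidate range; ties go to the smallest k, and
nearest-centroid ties at assignment time go to the lowest centroid index.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import yaml
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .errors import ConfigError, DataSizeError, DegenerateDataError, SchemaError
from .io import CellTable

#: silhouette is evaluated on at most this many (seeded) sample rows
SILHOUETTE_SAMPLE_SIZE = 5000


class Standardization(NamedTuple):
    """Pooled z-score transform: matrix of standardized rows plus the
    statistics and the surviving/dropped feature names."""

    matrix: np.ndarray          # (n_total, F_kept)
    feature_means: np.ndarray   # (F_kept,)
    feature_sds: np.ndarray     # (F_kept,) sample sd (ddof=1), all > 0
    feature_names: list[str]
    dropped_features: list[str]


def standardize(tables: Sequence[CellTable]) -> Standardization:
    """Pool all cells and z-score each feature across the whole cohort.

    Constant features carry no phenotype information and would produce a zero
    sd; they are removed and reported in ``dropped_features``.
    """
    if not tables:
        raise DataSizeError("no cell tables given")
    names = tables[0].feature_names
    for t in tables[1:]:
        if t.feature_names != names:
            raise SchemaError(
                f"feature_names mismatch between images {tables[0].image_id!r} "
                f"({names}) and {t.image_id!r} ({t.feature_names})"
            )
    X = np.concatenate([t.features for t in tables], axis=0)
    if X.shape[0] < 2:
        raise DataSizeError("need at least 2 pooled cells to standardize")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    keep = sds > 0
    if not keep.any():
        raise DegenerateDataError("all features are constant across the cohort")
    dropped = [n for n, k in zip(names, keep) if not k]
    kept_names = [n for n, k in zip(names, keep) if k]
    Z = (X[:, keep] - means[keep]) / sds[keep]
    return Standardization(Z, means[keep], sds[keep], kept_names, dropped)


@dataclass
class PhenotypeModel:
    """Fitted cell-level clustering in standardized feature space."""

    k_cells: int
    centroids: np.ndarray            # (k_cells, F_kept), standardized space
    feature_means: np.ndarray
    feature_sds: np.ndarray
    feature_names: list[str]
    dropped_features: list[str]
    silhouette_by_k: dict[int, float]
    seed: int
    training_labels: np.ndarray | None = None  # fit-time labels of the pooled rows

    def __post_init__(self) -> None:
        if (self.feature_sds <= 0).any():
            raise DegenerateDataError("feature_sds must all be > 0")
        for i in range(self.k_cells):
            for j in range(i + 1, self.k_cells):
                if np.array_equal(self.centroids[i], self.centroids[j]):
                    raise DegenerateDataError(f"centroids {i} and {j} coincide")

    def save(self, path: str | Path) -> None:
        """Persist as YAML metadata + an npz array container next to it."""
        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            centroids=self.centroids,
            feature_means=self.feature_means,
            feature_sds=self.feature_sds,
            training_labels=(self.training_labels if self.training_labels is not None else np.array([])),
        )
        meta = {
            "k_cells": int(self.k_cells),
            "feature_names": list(self.feature_names),
            "dropped_features": list(self.dropped_features),
            "silhouette_by_k": {int(k): float(v) for k, v in self.silhouette_by_k.items()},
            "seed": int(self.seed),
            "arrays": path.with_suffix(".npz").name,
        }
        path.write_text(yaml.safe_dump(meta, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "PhenotypeModel":
        path = Path(path)
        meta = yaml.safe_load(path.read_text())
        arrs = np.load(path.parent / meta["arrays"])
        tl = arrs["training_labels"]
        return cls(
            k_cells=meta["k_cells"],
            centroids=arrs["centroids"],
            feature_means=arrs["feature_means"],
            feature_sds=arrs["feature_sds"],
            feature_names=meta["feature_names"],
            dropped_features=meta["dropped_features"],
            silhouette_by_k={int(k): v for k, v in meta["silhouette_by_k"].items()},
            seed=meta["seed"],
            training_labels=(tl.astype(np.int64) if tl.size else None),
        )


def fit_cell_phenotypes(
    matrix: np.ndarray,
    k_range: tuple[int, int],
    seed: int,
    n_init: int = 10,
    standardization: Standardization | None = None,
) -> PhenotypeModel:
    """Fit k-means for every k in ``k_range`` (inclusive) and keep the k with
    the highest mean silhouette (ties -> smallest k).

    ``matrix`` must already be standardized; pass the ``Standardization`` so
    the model can re-apply the same transform to new tables.
    """
    matrix = np.asarray(matrix, dtype=np.float64)
    k_lo, k_hi = int(k_range[0]), int(k_range[1])
    if k_lo < 2:
        raise ConfigError("k_range lower bound must be >= 2")
    if k_hi < k_lo:
        raise ConfigError("k_range upper bound must be >= lower bound")
    n = matrix.shape[0]
    if n < k_hi * 10:
        raise DataSizeError(f"need >= {k_hi * 10} rows to scan k up to {k_hi}, got {n}")

    silhouette_by_k: dict[int, float] = {}
    fits: dict[int, KMeans] = {}
    for k in range(k_lo, k_hi + 1):
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(matrix)
        if len(np.unique(labels)) < 2:
            silhouette_by_k[k] = -1.0
        else:
            silhouette_by_k[k] = float(
                silhouette_score(
                    matrix, labels,
                    sample_size=min(n, SILHOUETTE_SAMPLE_SIZE), random_state=seed,
                )
            )
        fits[k] = km
    best_k = max(sorted(silhouette_by_k), key=lambda k: silhouette_by_k[k])  # ties -> smallest k
    best = fits[best_k]
    if standardization is not None:
        means, sds = standardization.feature_means, standardization.feature_sds
        names, dropped = standardization.feature_names, standardization.dropped_features
    else:
        F = matrix.shape[1]
        means, sds = np.zeros(F), np.ones(F)
        names, dropped = [f"z{j}" for j in range(F)], []
    return PhenotypeModel(
        k_cells=best_k,
        centroids=best.cluster_centers_.copy(),
        feature_means=np.asarray(means, dtype=np.float64),
        feature_sds=np.asarray(sds, dtype=np.float64),
        feature_names=list(names),
        dropped_features=list(dropped),
        silhouette_by_k=silhouette_by_k,
        seed=int(seed),
        training_labels=best.labels_.astype(np.int64),
    )


def transform_features(model: PhenotypeModel, table: CellTable) -> np.ndarray:
    """Apply the model's stored standardization to a table's features."""
    missing = [n for n in model.feature_names if n not in table.feature_names]
    if missing:
        raise SchemaError(
            f"table {table.image_id!r} lacks features required by the model: {missing}"
        )
    cols = [table.feature_names.index(n) for n in model.feature_names]
    return (table.features[:, cols] - model.feature_means) / model.feature_sds


def assign_phenotypes(model: PhenotypeModel, table: CellTable) -> np.ndarray:
    """Label each cell with its nearest centroid (Euclidean, standardized
    space); exact distance ties go to the lowest centroid index."""
    Z = transform_features(model, table)
    d2 = ((Z[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return d2.argmin(axis=1)  # argmin returns the first (lowest-index) minimum
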