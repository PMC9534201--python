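"""Synthetic tissue generator with planted ground truth.

Emulates the statistical structure the pipeline assumes: several cell
phenotypes separated in appearance-feature space, cells spatially clumped
into clusters (the future supercells), and image classes that differ only in
the *mixture* of cluster archetypes — i.e. in community composition — so
end-to-end discrimination specifically exercises the community and
global-graph stages rather than trivial feature shifts.

Geometry guarantees
-------------------
Cluster centers are rejection-sampled with pairwise separation at least
``4 * cluster_radius``; cell positions around a center follow an isotropic
Gaussian with sd ``cluster_radius / 2`` *truncated* at ``cluster_radius``
(2 sd). With that truncation, cells of different clusters are always more
than ``2 * cluster_radius`` apart, so a local-graph threshold
``d_max = cluster_radius`` recovers exactly the planted clusters — an exact,
testable contract rather than a high-probability one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .errors import ConfigError, SpacingError, DataSizeError
from .io import CellTable, write_cell_table


def _default_means(n_phenotypes: int, separation: float = 6.0) -> np.ndarray:
    """Phenotype means at ``separation`` along orthogonal feature axes."""
    return separation * np.eye(n_phenotypes)


def _default_archetypes(n_phenotypes: int, dominant: float = 0.8) -> np.ndarray:
    """One archetype per phenotype: ``dominant`` mass on its phenotype, rest uniform."""
    rest = (1.0 - dominant) / max(n_phenotypes - 1, 1)
    comp = np.full((n_phenotypes, n_phenotypes), rest)
    np.fill_diagonal(comp, dominant)
    return comp


def _default_mixture(n_classes: int, n_archetypes: int, dominant: float = 0.7) -> np.ndarray:
    """Each class prefers one archetype (cyclically) with weight ``dominant``."""
    rest = (1.0 - dominant) / max(n_archetypes - 1, 1)
    mix = np.full((n_classes, n_archetypes), rest)
    for c in range(n_classes):
        mix[c, c % n_archetypes] = dominant
    return mix


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults define the standard test cohort:
    3 classes x 30 images, 3 phenotypes at 6-sd separation, 8-12 clusters of
    15-30 cells per 512x512 image."""

    n_images_per_class: int = 30
    n_classes: int = 3
    image_size: tuple[int, int] = (512, 512)
    n_phenotypes: int = 3
    phenotype_feature_means: np.ndarray | None = None   # (n_phenotypes, F)
    phenotype_feature_sd: float = 1.0
    n_clusters_per_image: tuple[int, int] = (8, 12)
    cluster_radius: float = 20.0
    cells_per_cluster: tuple[int, int] = (15, 30)
    archetype_compositions: np.ndarray | None = None     # (n_archetypes, n_phenotypes)
    class_community_mixture: np.ndarray | None = None    # (n_classes, n_archetypes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype_feature_means is None:
            self.phenotype_feature_means = _default_means(self.n_phenotypes)
        self.phenotype_feature_means = np.asarray(self.phenotype_feature_means, dtype=np.float64)
        if self.phenotype_feature_means.shape[0] != self.n_phenotypes:
            raise ConfigError("phenotype_feature_means must have one row per phenotype")
        d = self.phenotype_feature_means
        for i in range(len(d)):
            for j in range(i + 1, len(d)):
                if np.allclose(d[i], d[j]):
                    raise ConfigError(f"phenotype mean rows {i} and {j} coincide")
        if self.archetype_compositions is None:
            self.archetype_compositions = _default_archetypes(self.n_phenotypes)
        self.archetype_compositions = np.asarray(self.archetype_compositions, dtype=np.float64)
        if self.archetype_compositions.shape[1] != self.n_phenotypes:
            raise ConfigError("archetype compositions must have one column per phenotype")
        if self.class_community_mixture is None:
            self.class_community_mixture = _default_mixture(
                self.n_classes, self.archetype_compositions.shape[0]
            )
        self.class_community_mixture = np.asarray(self.class_community_mixture, dtype=np.float64)
        if self.class_community_mixture.shape != (self.n_classes, self.archetype_compositions.shape[0]):
            raise ConfigError("class_community_mixture must be (n_classes, n_archetypes)")
        for name, mat in (
            ("archetype_compositions", self.archetype_compositions),
            ("class_community_mixture", self.class_community_mixture),
        ):
            sums = mat.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ConfigError(f"{name} rows must each sum to 1 (got {sums})")
        if self.cluster_radius >= min(self.image_size) / 4:
            raise ConfigError("cluster_radius must be < min(image_size)/4")
        lo, hi = self.n_clusters_per_image
        if not (1 <= lo <= hi):
            raise ConfigError("n_clusters_per_image interval invalid")
        lo, hi = self.cells_per_cluster
        if not (1 <= lo <= hi):
            raise ConfigError("cells_per_cluster interval invalid")

    @property
    def n_archetypes(self) -> int:
        return self.archetype_compositions.shape[0]

    @property
    def n_features(self) -> int:
        return self.phenotype_feature_means.shape[1]

    @property
    def feature_names(self) -> list[str]:
        return [f"f{j}" for j in range(self.n_features)]


@dataclass
class ImageTruth:
    """Planted ground truth for one synthetic image."""

    phenotype: np.ndarray       # (n_cells,) phenotype index per cell
    cluster: np.ndarray         # (n_cells,) planted cluster id per cell
    cluster_archetype: np.ndarray  # (n_clusters,) archetype per planted cluster
    class_index: int


def _place_centers(
    spec: SyntheticSpec, n_clusters: int, rng: np.random.Generator,
    max_restarts: int = 50, max_attempts: int = 2000,
) -> np.ndarray:
    """Uniform centers with pairwise separation >= 4 * cluster_radius, kept a
    cluster_radius margin inside the image so truncated cells stay in bounds."""
    w, h = spec.image_size
    margin = spec.cluster_radius
    min_sep = 4.0 * spec.cluster_radius
    for _ in range(max_restarts):
        centers: list[np.ndarray] = []
        attempts = 0
        while len(centers) < n_clusters and attempts < max_attempts:
            attempts += 1
            cand = rng.uniform([margin, margin], [w - margin, h - margin])
            if all(np.linalg.norm(cand - c) >= min_sep for c in centers):
                centers.append(cand)
        if len(centers) == n_clusters:
            return np.asarray(centers)
    raise SpacingError(
        f"could not place {n_clusters} cluster centers with separation "
        f">= {min_sep:.1f} px in a {w}x{h} image; reduce n_clusters_per_image "
        f"or cluster_radius"
    )


def _truncated_gaussian_offsets(
    n: int, sd: float, truncation: float, rng: np.random.Generator
) -> np.ndarray:
    """Isotropic 2-D Gaussian offsets with radius rejection-resampled to <= truncation."""
    out = rng.normal(0.0, sd, size=(n, 2))
    while True:
        r = np.linalg.norm(out, axis=1)
        bad = r > truncation
        if not bad.any():
            return out
        out[bad] = rng.normal(0.0, sd, size=(int(bad.sum()), 2))


def generate_image(
    spec: SyntheticSpec, class_index: int, rng: np.random.Generator,
    image_id: str = "synthetic",
) -> tuple[CellTable, ImageTruth]:
    """Generate one image of the given class with full planted truth."""
    if not (0 <= class_index < spec.n_classes):
        raise ConfigError(f"class_index {class_index} out of range [0, {spec.n_classes})")
    n_clusters = int(rng.integers(spec.n_clusters_per_image[0], spec.n_clusters_per_image[1] + 1))
    centers = _place_centers(spec, n_clusters, rng)
    archetypes = rng.choice(
        spec.n_archetypes, size=n_clusters, p=spec.class_community_mixture[class_index]
    )
    w, h = spec.image_size
    xy_parts, phen_parts, clus_parts = [], [], []
    for ci in range(n_clusters):
        n_cells = int(rng.integers(spec.cells_per_cluster[0], spec.cells_per_cluster[1] + 1))
        offsets = _truncated_gaussian_offsets(
            n_cells, spec.cluster_radius / 2.0, spec.cluster_radius, rng
        )
        pos = np.clip(centers[ci] + offsets, 0.0, [w - 1.0, h - 1.0])
        phen = rng.choice(spec.n_phenotypes, size=n_cells, p=spec.archetype_compositions[archetypes[ci]])
        xy_parts.append(pos)
        phen_parts.append(phen)
        clus_parts.append(np.full(n_cells, ci))
    xy = np.concatenate(xy_parts)
    phenotype = np.concatenate(phen_parts)
    cluster = np.concatenate(clus_parts)
    features = spec.phenotype_feature_means[phenotype] + rng.normal(
        0.0, spec.phenotype_feature_sd, size=(len(xy), spec.n_features)
    )
    table = CellTable(
        image_id=image_id,
        cell_ids=np.arange(1, len(xy) + 1),
        xy=xy,
        features=features,
        feature_names=spec.feature_names,
        phenotype_true=phenotype,
        cluster_true=cluster,
    )
    return table, ImageTruth(phenotype, cluster, archetypes, class_index)


def generate_dataset(
    spec: SyntheticSpec,
) -> tuple[list[CellTable], np.ndarray, list[ImageTruth]]:
    """Generate the full cohort: ``n_classes * n_images_per_class`` images.

    Per-image RNG substreams are spawned from ``spec.seed`` so each image is
    independent yet bit-reproducible regardless of generation order.
    """
    if spec.n_images_per_class < 1:
        raise DataSizeError("n_images_per_class must be >= 1 for a dataset")
    tables: list[CellTable] = []
    labels: list[int] = []
    truths: list[ImageTruth] = []
    idx = 0
    for c in range(spec.n_classes):
        for i in range(spec.n_images_per_class):
            ss = np.random.SeedSequence(entropy=spec.seed, spawn_key=(idx,))
            rng = np.random.default_rng(ss)
            image_id = f"class{c}_img{i:03d}"
            try:
                table, truth = generate_image(spec, c, rng, image_id=image_id)
            except SpacingError as exc:
                raise SpacingError(f"image {idx} ({image_id}): {exc}") from exc
            tables.append(table)
            labels.append(c)
            truths.append(truth)
            idx += 1
    return tables, np.asarray(labels), truths


def write_dataset(
    spec: SyntheticSpec, out_dir: str | Path, force: bool = False,
) -> dict:
    """Materialize a dataset on disk: one cell CSV and one truth CSV per image
    plus a YAML manifest (image_id, class, seed). Returns the manifest dict."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise ConfigError(f"output directory {out_dir} is not empty (use force=True to overwrite)")
    (out_dir / "cells").mkdir(parents=True, exist_ok=True)
    (out_dir / "truth").mkdir(parents=True, exist_ok=True)
    tables, labels, truths = generate_dataset(spec)
    records = []
    for table, label in zip(tables, labels):
        cell_path = out_dir / "cells" / f"{table.image_id}.csv"
        truth_path = out_dir / "truth" / f"{table.image_id}_truth.csv"
        # cells CSV holds coordinates+features only; truth goes to its own file
        plain = CellTable(table.image_id, table.cell_ids, table.xy, table.features, table.feature_names)
        write_cell_table(plain, cell_path)
        table.to_dataframe()[["cell_id", "phenotype_true", "cluster_true"]].to_csv(truth_path, index=False)
        records.append({
            "image_id": table.image_id,
            "class": int(label),
            "cells": str(cell_path.relative_to(out_dir)),
            "truth": str(truth_path.relative_to(out_dir)),
        })
    manifest = {"seed": int(spec.seed), "n_classes": int(spec.n_classes), "images": records}
    (out_dir / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest
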