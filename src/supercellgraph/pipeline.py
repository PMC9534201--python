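"""End-to-end orchestration of the five pipeline stages.

The only cross-image couplings are the two cohort-level fits: the phenotype
model (pooled standardization + k-means) and the community model (pooled
spectral clustering). Everything else is computed per image from those
shared models, so runs are embarrassingly decomposable and exactly
reproducible from (config, seed, inputs).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import ClassificationResult, cross_validate
from .communities import CommunityModel, assign_communities, pool_descriptors, spectral_cluster
from .config import PipelineConfig
from .errors import SupercellGraphError, ValidationError
from .globalgraph import GlobalGraph, build_global_graph, extract_global_features, feature_vector_names
from .io import CellTable, write_cell_table, write_graph
from .phenotyping import PhenotypeModel, assign_phenotypes, fit_cell_phenotypes, standardize, transform_features
from .supercells import (
    LocalGraph, Supercell, build_local_graph, descriptor_names, extract_supercells,
    supercell_descriptor,
)

logger = logging.getLogger(__name__)

STAGES = ("phenotype", "supercell", "community", "features", "classify")


@dataclass
class RunManifest:
    """Record of one pipeline run: config hash, inputs, per-stage records."""

    config_hash: str
    seed: int
    inputs: list[str]
    stages: list[dict] = field(default_factory=list)
    artifacts: dict[str, str] = field(default_factory=dict)

    def add_stage(self, name: str, n_in: int, n_out: int, params: dict, wall: float) -> None:
        self.stages.append({
            "stage": name, "n_in": int(n_in), "n_out": int(n_out),
            "params": params, "wall_seconds": round(float(wall), 3),
        })

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash, "seed": self.seed,
            "inputs": self.inputs, "stages": self.stages, "artifacts": self.artifacts,
        }

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


@dataclass
class PipelineRun:
    """All products of a run, in memory; heavyweight artifacts optionally on disk."""

    manifest: RunManifest
    phenotype_model: PhenotypeModel
    phenotypes: list[np.ndarray]                 # per image, per cell
    local_graphs: list[LocalGraph]
    supercells: list[list[Supercell]]
    descriptors: list[np.ndarray]                # per image (n_sc, D) raw descriptors
    community_model: CommunityModel
    communities: list[np.ndarray]                # per image, per supercell
    global_graphs: list[GlobalGraph]
    feature_matrix: np.ndarray                   # (n_images, P)
    feature_names: list[str]
    classification: ClassificationResult | None


def _stage(manifest: RunManifest, name: str):
    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                logger.error("stage %s: failed: %s", name, exc)
                if isinstance(exc, SupercellGraphError):
                    exc.args = (f"[stage {name}] {exc.args[0]}",) + exc.args[1:]
            return False

        def record(self, n_in, n_out, **params):
            manifest.add_stage(name, n_in, n_out, params, time.perf_counter() - self.t0)

    return _Ctx()


def run_pipeline(
    config: PipelineConfig,
    tables: list[CellTable],
    labels: np.ndarray | list | None = None,
    out_dir: str | Path | None = None,
) -> PipelineRun:
    """Run phenotyping -> supercells -> communities -> global features
    [-> classification] over a cohort of cell tables.

    ``labels`` are per-image class labels; with fewer than two classes (or
    ``None``) the classification stage is skipped with a notice. When
    ``out_dir`` is given, every intermediate artifact (labeled cell CSVs,
    supercell roster, graphs, feature matrix, models, manifest) is written
    beneath it.
    """
    if not tables:
        raise ValidationError("no input cell tables")
    if labels is not None and len(labels) != len(tables):
        raise ValidationError("one class label per image required")
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    seed = config.random_seed
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=seed,
        inputs=[t.image_id for t in tables],
    )

    # --- stage 1: phenotyping (cohort fit + per-image assignment) ----------
    with _stage(manifest, "phenotype") as st:
        std = standardize(tables)
        model = fit_cell_phenotypes(std.matrix, config.k_cell_range, seed, standardization=std)
        phenotypes = [assign_phenotypes(model, t) for t in tables]
        st.record(sum(t.n_cells for t in tables), model.k_cells,
                  k_range=list(config.k_cell_range),
                  silhouette_by_k={k: round(v, 6) for k, v in model.silhouette_by_k.items()},
                  dropped_features=model.dropped_features)
    z_by_image = [transform_features(model, t) for t in tables]

    # --- stage 2: supercell construction ------------------------------------
    with _stage(manifest, "supercell") as st:
        local_graphs, sc_lists, desc_mats = [], [], []
        discarded = 0
        for t, ph, z in zip(tables, phenotypes, z_by_image):
            g = build_local_graph(t, ph, config.d_max, config.k_nn, config.local_graph_mode)
            scs, report = extract_supercells(g, t, config.min_supercell_size)
            discarded += report.n_cells_discarded
            D = np.asarray([
                supercell_descriptor(sc, t, ph, model.k_cells, z) for sc in scs
            ]).reshape(len(scs), -1)
            local_graphs.append(g)
            sc_lists.append(scs)
            desc_mats.append(D)
        n_sc = sum(len(s) for s in sc_lists)
        st.record(sum(t.n_cells for t in tables), n_sc,
                  d_max=config.d_max, k_nn=config.k_nn, mode=config.local_graph_mode,
                  min_supercell_size=config.min_supercell_size,
                  n_cells_discarded=int(discarded))

    # --- stage 3: community identification ----------------------------------
    with _stage(manifest, "community") as st:
        pooled = pool_descriptors([
            (t.image_id, scs, D) for t, scs, D in zip(tables, sc_lists, desc_mats)
        ])
        cmodel = spectral_cluster(
            pooled.matrix, config.n_communities, seed,
            standardization=(pooled.means, pooled.sds),
        )
        # scatter fit-time labels back to images via the provenance index
        communities: list[np.ndarray] = [np.empty(len(s), dtype=np.int64) for s in sc_lists]
        image_pos = {t.image_id: i for i, t in enumerate(tables)}
        for row, (image_id, sc_id) in enumerate(pooled.index):
            communities[image_pos[image_id]][sc_id] = cmodel.training_labels[row]
        st.record(n_sc, cmodel.n_communities,
                  requested=config.n_communities, kernel_bandwidth=round(cmodel.kernel_bandwidth, 6))

    # --- stage 4: global graphs + image features -----------------------------
    with _stage(manifest, "features") as st:
        global_graphs, rows = [], []
        fnames = feature_vector_names(cmodel.n_communities, config.n_laplacian_eigenvalues)
        for t, scs, comm in zip(tables, sc_lists, communities):
            gg = build_global_graph(scs, comm, config.delaunay_prune_percentile,
                                    image_id=t.image_id, seed=seed)
            rows.append(extract_global_features(gg, cmodel.n_communities,
                                                config.n_laplacian_eigenvalues))
            global_graphs.append(gg)
        X = np.asarray(rows)
        st.record(n_sc, X.shape[0],
                  prune_percentile=config.delaunay_prune_percentile,
                  n_laplacian_eigenvalues=config.n_laplacian_eigenvalues,
                  n_features=X.shape[1])

    # --- stage 5: classification (optional) ----------------------------------
    classification = None
    y = np.asarray(labels) if labels is not None else None
    if y is not None and len(np.unique(y)) >= 2:
        with _stage(manifest, "classify") as st:
            classification = cross_validate(X, y, config.cv_folds, config.cv_repeats, seed)
            st.record(X.shape[0], len(classification.classes),
                      folds=config.cv_folds, repeats=config.cv_repeats,
                      accuracy_mean=round(classification.accuracy_mean, 6))
    else:
        logger.info("classification skipped: %s",
                    "no labels given" if y is None else "fewer than 2 classes")

    run = PipelineRun(
        manifest=manifest, phenotype_model=model, phenotypes=phenotypes,
        local_graphs=local_graphs, supercells=sc_lists, descriptors=desc_mats,
        community_model=cmodel, communities=communities, global_graphs=global_graphs,
        feature_matrix=X, feature_names=fnames, classification=classification,
    )
    if out is not None:
        _write_artifacts(run, tables, y, config, out)
    return run


def _write_artifacts(run: PipelineRun, tables, labels, config: PipelineConfig, out: Path) -> None:
    (out / "cells").mkdir(exist_ok=True)
    (out / "graphs").mkdir(exist_ok=True)
    art = run.manifest.artifacts
    config.to_yaml(out / "config.yaml")
    art["config"] = "config.yaml"
    run.phenotype_model.save(out / "phenotype_model.yaml")
    art["phenotype_model"] = "phenotype_model.yaml"
    run.community_model.save(out / "community_model.yaml")
    art["community_model"] = "community_model.yaml"
    for t, ph in zip(tables, run.phenotypes):
        write_cell_table(t, out / "cells" / f"{t.image_id}.csv", extra={"phenotype": ph})
    art["cells"] = "cells/"
    # supercell roster with descriptors and community labels
    dnames = descriptor_names(run.phenotype_model.k_cells, run.phenotype_model.feature_names)
    recs = []
    for t, scs, D, comm in zip(tables, run.supercells, run.descriptors, run.communities):
        for sc, drow, c in zip(scs, D, comm):
            rec = {"supercell_id": sc.supercell_id, "image_id": sc.image_id,
                   "x": sc.centroid[0], "y": sc.centroid[1],
                   "n_cells": len(sc.member_cells), "community": int(c)}
            rec.update({name: val for name, val in zip(dnames, drow)})
            recs.append(rec)
    pd.DataFrame(recs).to_csv(out / "supercells.csv", index=False)
    art["supercells"] = "supercells.csv"
    for lg, gg in zip(run.local_graphs, run.global_graphs):
        write_graph(lg, out / "graphs" / f"{lg.image_id}_local.graphml")
        if gg.n_nodes:
            write_graph(gg, out / "graphs" / f"{gg.image_id}_global.graphml")
    art["graphs"] = "graphs/"
    feat = pd.DataFrame(run.feature_matrix, columns=run.feature_names)
    feat.insert(0, "image_id", [t.image_id for t in tables])
    feat.insert(1, "class", labels if labels is not None else "")
    feat.to_csv(out / "features.csv", index=False)
    art["features"] = "features.csv"
    if run.classification is not None:
        run.classification.to_yaml(out / "classification.yaml")
        (out / "classification_table.txt").write_text(run.classification.render_table() + "\n")
        art["classification"] = "classification.yaml"
    run.manifest.to_yaml(out / "manifest.yaml")
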