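"""Readers/writers for cell tables, label masks, and graphs, plus feature
extraction from label masks.

Conventions
-----------
Coordinates are 0-based pixel indices with ``x`` = column and ``y`` = row,
origin at the top-left of the image — the raster convention of the masks the
tables are usually derived from.

Cell tables are UTF-8 CSV files with a header row. The columns ``cell_id``,
``x`` and ``y`` are reserved; ``phenotype``, ``phenotype_true`` and
``cluster_true`` are recognised annotation columns; every *other* numeric
column is treated as an appearance feature unless an explicit feature list
is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .errors import FormatError, ValidationError

#: columns that are never auto-detected as appearance features
RESERVED_COLUMNS = ("cell_id", "x", "y", "phenotype", "phenotype_true", "cluster_true", "image_id")


@dataclass
class CellTable:
    """Per-image roster of cells: coordinates plus appearance features.

    Row order is stable: every downstream per-cell label vector (phenotypes,
    cluster ids) indexes this order.
    """

    image_id: str
    cell_ids: np.ndarray          # (n,) int
    xy: np.ndarray                # (n, 2) float, columns (x, y)
    features: np.ndarray          # (n, F) float
    feature_names: list[str]
    phenotype_true: np.ndarray | None = None
    cluster_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        self.features = np.asarray(self.features, dtype=np.float64)
        n = self.cell_ids.shape[0]
        if self.xy.shape != (n, 2):
            raise ValidationError(f"coordinate array must be ({n}, 2), got {self.xy.shape}")
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise ValidationError("feature matrix must have one row per cell")
        if self.features.shape[1] != len(self.feature_names):
            raise ValidationError("feature_names length must match feature matrix width")
        uniq, counts = np.unique(self.cell_ids, return_counts=True)
        if (counts > 1).any():
            dup = uniq[counts > 1]
            raise ValidationError(f"duplicate cell_id values in image {self.image_id!r}: {dup.tolist()}")
        if not np.isfinite(self.xy).all():
            raise ValidationError("cell coordinates must be finite")
        if (self.xy < 0).any():
            raise ValidationError("cell coordinates must be non-negative")
        if not np.isfinite(self.features).all():
            raise ValidationError("cell features must be finite (no NaN/Inf)")
        for arr_name in ("phenotype_true", "cluster_true"):
            arr = getattr(self, arr_name)
            if arr is not None:
                arr = np.asarray(arr, dtype=np.int64)
                if arr.shape != (n,):
                    raise ValidationError(f"{arr_name} must have one entry per cell")
                setattr(self, arr_name, arr)

    @property
    def n_cells(self) -> int:
        return int(self.cell_ids.shape[0])

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def to_dataframe(self, extra: dict[str, np.ndarray] | None = None) -> pd.DataFrame:
        """Tabular view; ``extra`` columns (e.g. assigned phenotypes) are appended."""
        data: dict[str, np.ndarray] = {
            "cell_id": self.cell_ids,
            "x": self.xy[:, 0],
            "y": self.xy[:, 1],
        }
        for j, name in enumerate(self.feature_names):
            data[name] = self.features[:, j]
        if self.phenotype_true is not None:
            data["phenotype_true"] = self.phenotype_true
        if self.cluster_true is not None:
            data["cluster_true"] = self.cluster_true
        if extra:
            data.update(extra)
        return pd.DataFrame(data)


def read_cell_table(
    path: str | Path,
    image_id: str | None = None,
    feature_columns: Sequence[str] | None = None,
) -> CellTable:
    """Read a cell table CSV.

    Feature columns are auto-detected (all numeric non-reserved columns, in
    file order) unless ``feature_columns`` names them explicitly.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} missing")
    if feature_columns is None:
        candidates = [c for c in df.columns if c not in RESERVED_COLUMNS]
    else:
        missing = [c for c in feature_columns if c not in df.columns]
        if missing:
            raise FormatError(f"{path}: requested feature columns missing: {missing}")
        candidates = list(feature_columns)
    feats = []
    for col in candidates:
        numeric = pd.to_numeric(df[col], errors="coerce")
        unparsable = numeric.isna() & df[col].notna()
        if unparsable.all() and len(df) and feature_columns is None:
            continue  # wholly non-numeric column (e.g. free text): not a feature
        if unparsable.any():
            row = int(np.flatnonzero(unparsable.to_numpy())[0])
            raise FormatError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in feature column "
                f"{col!r} at data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0])
            raise FormatError(f"{path}: missing value in feature column {col!r} at data row {row}")
        df[col] = numeric
        feats.append(col)
    if not feats:
        raise FormatError(f"{path}: no numeric feature column found")
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate cell_id {dup}")
    return CellTable(
        image_id=image_id if image_id is not None else path.stem,
        cell_ids=df["cell_id"].to_numpy(dtype=np.int64),
        xy=df[["x", "y"]].to_numpy(dtype=np.float64),
        features=df[feats].to_numpy(dtype=np.float64),
        feature_names=feats,
        phenotype_true=(df["phenotype_true"].to_numpy(dtype=np.int64) if "phenotype_true" in df else None),
        cluster_true=(df["cluster_true"].to_numpy(dtype=np.int64) if "cluster_true" in df else None),
    )


def write_cell_table(table: CellTable, path: str | Path, extra: dict[str, np.ndarray] | None = None) -> None:
    """Write a cell table to CSV (full float precision, lossless round-trip)."""
    table.to_dataframe(extra=extra).to_csv(Path(path), index=False)


# ---------------------------------------------------------------------------
# Label masks and feature extraction
# ---------------------------------------------------------------------------

@dataclass
class LabelMask:
    """Integer-labeled segmentation mask; 0 is background, labels need not be
    contiguous. Touching-but-distinct labels remain distinct cells."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValidationError(f"label mask must be 2-D, got {self.pixels.ndim}-D")
        if not np.issubdtype(self.pixels.dtype, np.integer):
            raise ValidationError("label mask must have an integer dtype")
        if self.pixels.size and self.pixels.min() < 0:
            raise ValidationError("label mask must not contain negative labels")

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.pixels)
        return lab[lab > 0]


def read_label_mask(path: str | Path) -> LabelMask:
    """Read a single-channel integer TIFF or PNG label image."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        arr = arr[:, :, 0]
    if not np.issubdtype(arr.dtype, np.integer):
        if np.allclose(arr, np.round(arr)):
            arr = arr.astype(np.int64)
        else:
            raise FormatError(f"{path}: mask pixels are not integers")
    return LabelMask(arr.astype(np.int64))


#: morphology features extracted for every cell, in output order
MASK_FEATURE_NAMES = ["area_px", "perimeter_px", "eccentricity", "solidity", "circularity"]
INTENSITY_FEATURE_NAMES = ["mean_intensity", "std_intensity"]


def extract_cell_features(
    mask: LabelMask,
    intensity: np.ndarray | None = None,
    image_id: str = "image",
) -> CellTable:
    """Extract per-cell appearance features from a label mask.

    Each positive label becomes one cell. ``x, y`` is the centroid of the
    label's pixels (x = column, y = row). Morphology features are
    ``area_px`` (pixel count), ``perimeter_px`` (the marching-squares contour
    estimator of ``skimage.measure.regionprops``), ``eccentricity``,
    ``solidity`` and ``circularity = 4*pi*area / perimeter**2`` (defined as 0
    for regions whose estimated perimeter is 0, e.g. single pixels). With an
    intensity image, ``mean_intensity`` and ``std_intensity`` are appended.
    """
    from skimage.measure import regionprops

    if intensity is not None:
        intensity = np.asarray(intensity, dtype=np.float64)
        if intensity.shape != mask.pixels.shape:
            raise ValidationError(
                f"intensity shape {intensity.shape} does not match mask shape {mask.pixels.shape}"
            )
    props = regionprops(mask.pixels, intensity_image=intensity)
    if not props:
        raise ValidationError("label mask contains no positive labels")
    props = sorted(props, key=lambda p: p.label)  # ascending label order

    names = list(MASK_FEATURE_NAMES) + (list(INTENSITY_FEATURE_NAMES) if intensity is not None else [])
    rows, xy, ids = [], [], []
    for p in props:
        area = float(p.area)
        perim = float(p.perimeter)
        circ = 4.0 * np.pi * area / perim**2 if perim > 0 else 0.0
        feats = [area, perim, float(p.eccentricity), float(p.solidity), circ]
        if intensity is not None:
            feats += [float(p.intensity_mean), float(p.intensity_std)]
        rows.append(feats)
        cy, cx = p.centroid  # regionprops returns (row, col)
        xy.append((cx, cy))
        ids.append(p.label)
    return CellTable(
        image_id=image_id,
        cell_ids=np.asarray(ids),
        xy=np.asarray(xy),
        features=np.asarray(rows),
        feature_names=names,
    )


# ---------------------------------------------------------------------------
# Graph I/O
# ---------------------------------------------------------------------------

def write_graph(graph, path: str | Path) -> None:
    """Serialize a graph to GraphML.

    Accepts any object with a ``to_networkx()`` method (LocalGraph,
    GlobalGraph) or a ``networkx.Graph`` whose nodes carry ``x``/``y``/
    ``label`` attributes and edges carry ``length``.
    """
    g = graph.to_networkx() if hasattr(graph, "to_networkx") else graph
    if g.number_of_nodes() == 0:
        raise ValidationError("refusing to serialize a graph with no nodes")
    nx.write_graphml(g, str(path))


def read_graph(path: str | Path) -> nx.Graph:
    """Read a GraphML file back as a networkx graph (node ids as ints)."""
    g = nx.read_graphml(str(path))
    return nx.relabel_nodes(g, {n: int(n) for n in g.nodes})
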