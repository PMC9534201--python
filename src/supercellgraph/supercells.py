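"""Supercell construction: local cell graphs and their connected components.

A local graph connects each cell to its k nearest neighbours (symmetrized by
union) and then keeps only edges not longer than ``d_max`` — two
interpretable knobs standing in for "closely interacting". In ``stratified``
mode edges additionally require equal phenotype labels, so supercells are
groups of interacting *same-subtype* cells; in the default ``agnostic`` mode
subtypes enter only through the composition block of the supercell
descriptor.

Supercells are the connected components with at least ``min_supercell_size``
members; smaller components are discarded and counted. Each supercell gets a
fixed-order descriptor vector:

    [n_cells,
     phenotype composition fractions        (k_cells entries, sum 1),
     convex hull area (px^2, 0 if degenerate),
     cell density = n_cells / hull area     (0 if hull degenerate),
     mean nearest-neighbour distance among members (0 for singletons),
     mean standardized appearance feature vector    (F entries)]
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import networkx as nx
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree, ConvexHull, QhullError

from .errors import ValidationError
from .io import CellTable


@dataclass
class LocalGraph:
    """Per-image graph over individual cells with distance-limited edges."""

    image_id: str
    n_nodes: int
    edges: np.ndarray    # (E, 2) int, each row (i, j) with i < j, no duplicates
    lengths: np.ndarray  # (E,) float, Euclidean px
    mode: str            # "agnostic" | "stratified"
    d_max: float
    xy: np.ndarray       # (n_nodes, 2) node coordinates (for export)
    node_labels: np.ndarray  # (n_nodes,) phenotype labels (for export)

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.lengths = np.asarray(self.lengths, dtype=np.float64).reshape(-1)
        if (self.edges[:, 0] >= self.edges[:, 1]).any():
            raise ValidationError("edges must satisfy i < j (no self-loops)")
        if len(np.unique(self.edges, axis=0)) != len(self.edges):
            raise ValidationError("duplicate edges")
        if len(self.lengths) and self.lengths.max() > self.d_max + 1e-9:
            raise ValidationError("edge longer than d_max")

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(image_id=self.image_id, mode=self.mode)
        for i in range(self.n_nodes):
            g.add_node(i, x=float(self.xy[i, 0]), y=float(self.xy[i, 1]),
                       label=int(self.node_labels[i]))
        for (i, j), length in zip(self.edges, self.lengths):
            g.add_edge(int(i), int(j), length=float(length))
        return g


def build_local_graph(
    table: CellTable,
    phenotypes: np.ndarray,
    d_max: float,
    k_nn: int,
    mode: str = "agnostic",
) -> LocalGraph:
    """Symmetrized k-NN graph with a hard distance cut.

    Candidate edges are the union of every cell's ``k_nn`` nearest
    neighbours; an edge survives iff its Euclidean length is <= ``d_max``
    and, in ``stratified`` mode, both endpoints share a phenotype label.
    """
    if table.n_cells == 0:
        raise ValidationError("empty cell table")
    if d_max <= 0:
        raise ValidationError("d_max must be > 0")
    if mode not in ("agnostic", "stratified"):
        raise ValidationError(f"unknown local-graph mode {mode!r}")
    phenotypes = np.asarray(phenotypes, dtype=np.int64)
    if phenotypes.shape != (table.n_cells,):
        raise ValidationError("phenotypes must have one label per cell")
    n = table.n_cells
    if k_nn >= n:
        warnings.warn(f"k_nn={k_nn} >= n_cells={n}; clamping to {n - 1}", stacklevel=2)
        k_nn = n - 1
    if n == 1 or k_nn < 1:
        edges = np.empty((0, 2), dtype=np.int64)
        lengths = np.empty(0)
    else:
        tree = cKDTree(table.xy)
        dist, idx = tree.query(table.xy, k=k_nn + 1)  # first neighbour is self
        src = np.repeat(np.arange(n), k_nn)
        dst = idx[:, 1:].reshape(-1)
        d = dist[:, 1:].reshape(-1)
        keep = (d <= d_max) & (src != dst)
        if mode == "stratified":
            keep &= phenotypes[src] == phenotypes[dst]
        src, dst, d = src[keep], dst[keep], d[keep]
        lo, hi = np.minimum(src, dst), np.maximum(src, dst)
        pairs = np.stack([lo, hi], axis=1)
        pairs, uniq_idx = np.unique(pairs, axis=0, return_index=True)
        edges, lengths = pairs, d[uniq_idx]
    return LocalGraph(
        image_id=table.image_id, n_nodes=n, edges=edges, lengths=lengths,
        mode=mode, d_max=float(d_max), xy=table.xy, node_labels=phenotypes,
    )


@dataclass
class Supercell:
    """A connected group of closely interacting cells."""

    supercell_id: int
    image_id: str
    member_cells: np.ndarray  # indices into the CellTable row order
    centroid: np.ndarray      # (x, y) arithmetic mean of member coordinates


@dataclass
class DiscardReport:
    """Accounting of components below the minimum supercell size."""

    n_components_discarded: int
    n_cells_discarded: int
    n_cells_total: int

    @property
    def discarded_cell_fraction(self) -> float:
        return self.n_cells_discarded / self.n_cells_total if self.n_cells_total else 0.0


def extract_supercells(
    graph: LocalGraph, table: CellTable, min_supercell_size: int = 1,
) -> tuple[list[Supercell], DiscardReport]:
    """Connected components of the local graph with >= ``min_supercell_size``
    members; ids are assigned by ascending minimum member cell index."""
    n = graph.n_nodes
    if graph.n_edges:
        adj = coo_matrix(
            (np.ones(graph.n_edges), (graph.edges[:, 0], graph.edges[:, 1])),
            shape=(n, n),
        )
    else:
        adj = coo_matrix((n, n))
    n_comp, comp = connected_components(adj, directed=False)
    members_by_comp: dict[int, np.ndarray] = {
        c: np.flatnonzero(comp == c) for c in range(n_comp)
    }
    kept = [m for m in members_by_comp.values() if len(m) >= min_supercell_size]
    kept.sort(key=lambda m: int(m.min()))
    discarded = [m for m in members_by_comp.values() if len(m) < min_supercell_size]
    supercells = [
        Supercell(
            supercell_id=sid,
            image_id=graph.image_id,
            member_cells=m,
            centroid=table.xy[m].mean(axis=0),
        )
        for sid, m in enumerate(kept)
    ]
    report = DiscardReport(
        n_components_discarded=len(discarded),
        n_cells_discarded=int(sum(len(m) for m in discarded)),
        n_cells_total=n,
    )
    return supercells, report


def descriptor_names(k_cells: int, feature_names: list[str]) -> list[str]:
    """Column names of the descriptor vector, in order."""
    return (
        ["n_cells"]
        + [f"phenotype_frac_{p}" for p in range(k_cells)]
        + ["hull_area_px2", "cell_density", "mean_nn_dist_px"]
        + [f"mean_{f}" for f in feature_names]
    )


def supercell_descriptor(
    sc: Supercell,
    table: CellTable,
    phenotypes: np.ndarray,
    k_cells: int,
    standardized_features: np.ndarray,
) -> np.ndarray:
    """Descriptor vector of one supercell (length ``k_cells + F + 4``).

    ``standardized_features`` is the cohort-standardized feature matrix of
    the supercell's image (same row order as the table), so descriptors are
    comparable across images.
    """
    m = sc.member_cells
    n = len(m)
    comp = np.bincount(np.asarray(phenotypes)[m], minlength=k_cells).astype(np.float64)
    comp /= comp.sum()
    pts = table.xy[m]
    hull_area = 0.0
    if n >= 3:
        try:
            hull_area = float(ConvexHull(pts).volume)  # "volume" is area in 2-D
        except QhullError:
            hull_area = 0.0  # collinear members
    density = n / hull_area if hull_area > 0 else 0.0
    if n >= 2:
        d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2)
        np.fill_diagonal(d2, np.inf)
        mean_nn = float(np.sqrt(d2.min(axis=1)).mean())
    else:
        mean_nn = 0.0
    mean_feat = standardized_features[m].mean(axis=0)
    return np.concatenate([[n], comp, [hull_area, density, mean_nn], mean_feat])
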