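"""Global supercell graph construction and image-level feature extraction.

Per image, supercell centroids are joined by a Delaunay triangulation — the
dominant convention for cell-graph construction in pathology — and edges
longer than a chosen percentile of that image's Delaunay edge lengths are
pruned (default 95th), removing the long boundary edges triangulation
inevitably creates. Degenerate inputs fall back deterministically: two
supercells give a single edge, one gives an edgeless graph, and collinear
centroids give a path along the sorted axis.

The image feature vector reads the pruned graph together with the community
labels of its nodes. Its fixed order is:

    [n_nodes, n_edges,
     mean/sd/max degree, average local clustering coefficient,
     mean/sd edge length (px),
     community composition fractions                  (C entries),
     community-pair edge fractions, pairs (a,b) a<=b  (C(C+1)/2 entries),
     same-label edge fraction,
     the m largest normalized-Laplacian eigenvalues, ascending,
     left-padded with zeros when the graph has fewer than m nodes]

The community-pair block is the carrier of supercell-interaction structure
and the core of the representation; the spectrum block summarizes global
graph shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import networkx as nx
from scipy.spatial import Delaunay, QhullError

from .errors import ValidationError
from .communities import normalized_laplacian
from .supercells import Supercell


@dataclass
class GlobalGraph:
    """Per-image graph over supercell centroids with community node labels."""

    image_id: str
    xy: np.ndarray            # (n, 2) supercell centroids
    communities: np.ndarray   # (n,) node community labels
    edges: np.ndarray         # (E, 2) int, i < j
    lengths: np.ndarray       # (E,) px
    construction: str         # e.g. "delaunay(prune=95.0)"

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.lengths = np.asarray(self.lengths, dtype=np.float64).reshape(-1)
        if (self.edges[:, 0] >= self.edges[:, 1]).any():
            raise ValidationError("edges must satisfy i < j (no self-loops)")
        if (self.communities < 0).any():
            raise ValidationError("community labels must be non-negative")

    @property
    def n_nodes(self) -> int:
        return int(self.xy.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(image_id=self.image_id, construction=self.construction)
        for i in range(self.n_nodes):
            g.add_node(i, x=float(self.xy[i, 0]), y=float(self.xy[i, 1]),
                       label=int(self.communities[i]))
        for (i, j), length in zip(self.edges, self.lengths):
            g.add_edge(int(i), int(j), length=float(length))
        return g


def _delaunay_edges(pts: np.ndarray) -> np.ndarray:
    tri = Delaunay(pts)
    pairs = set()
    for simplex in tri.simplices:
        for a in range(3):
            for b in range(a + 1, 3):
                i, j = int(simplex[a]), int(simplex[b])
                pairs.add((min(i, j), max(i, j)))
    return np.asarray(sorted(pairs), dtype=np.int64)


def build_global_graph(
    supercells: Sequence[Supercell],
    communities: np.ndarray,
    prune_percentile: float = 95.0,
    image_id: str | None = None,
    seed: int = 0,
) -> GlobalGraph:
    """Delaunay graph over supercell centroids with percentile edge pruning.

    Duplicate centroids are jittered by 1e-6 px (deterministically from
    ``seed``) with a warning so the triangulation is well-posed.
    """
    if len(supercells) == 0:
        raise ValidationError("need at least one supercell")
    if not (0 < prune_percentile <= 100):
        raise ValidationError("prune_percentile must be in (0, 100]")
    communities = np.asarray(communities, dtype=np.int64)
    if communities.shape != (len(supercells),):
        raise ValidationError("one community label per supercell required")
    if image_id is None:
        image_id = supercells[0].image_id
    pts = np.asarray([sc.centroid for sc in supercells], dtype=np.float64)
    n = len(pts)

    uniq, inverse, counts = np.unique(pts, axis=0, return_inverse=True, return_counts=True)[0:3]
    if (counts > 1).any():
        warnings.warn("duplicate supercell centroids; applying deterministic 1e-6 px jitter",
                      stacklevel=2)
        rng = np.random.default_rng(seed)
        jitter = rng.uniform(-1e-6, 1e-6, size=pts.shape)
        dup_rows = np.isin(inverse, np.flatnonzero(counts > 1))
        pts = pts + np.where(dup_rows[:, None], jitter, 0.0)

    if n == 1:
        edges = np.empty((0, 2), dtype=np.int64)
    elif n == 2:
        edges = np.array([[0, 1]], dtype=np.int64)
    else:
        try:
            edges = _delaunay_edges(pts)
        except QhullError:
            # collinear centroids: path graph along the sorted axis
            order = np.lexsort((pts[:, 1], pts[:, 0]))
            edges = np.sort(np.stack([order[:-1], order[1:]], axis=1), axis=1)
            edges = edges[np.lexsort((edges[:, 1], edges[:, 0]))]
        assert len(edges) <= 3 * n - 6 or n < 3
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1) if len(edges) else np.empty(0)
    if len(edges) and n >= 3:
        # "higher" interpolation: the threshold is an actual edge length, so
        # prune=95 on a 3-edge graph keeps the triangle instead of cutting
        # its longest side; indistinguishable from linear at cohort scale
        thresh = np.percentile(lengths, prune_percentile, method="higher")
        keep = lengths <= thresh
        edges, lengths = edges[keep], lengths[keep]
    return GlobalGraph(
        image_id=image_id, xy=pts, communities=communities,
        edges=edges, lengths=lengths,
        construction=f"delaunay(prune={float(prune_percentile)})",
    )


def feature_vector_names(C: int, m: int) -> list[str]:
    """Column names of the image feature vector, in order."""
    names = ["n_nodes", "n_edges", "degree_mean", "degree_sd", "degree_max",
             "avg_clustering", "edge_len_mean", "edge_len_sd"]
    names += [f"community_frac_{c}" for c in range(C)]
    names += [f"pair_frac_{a}_{b}" for a in range(C) for b in range(a, C)]
    names += ["same_label_edge_frac"]
    names += [f"laplacian_eig_{i}" for i in range(m)]
    return names


def extract_global_features(graph: GlobalGraph, C: int, m: int = 8) -> np.ndarray:
    """Image-level feature vector (length ``9 + C + C(C+1)/2 + m``)."""
    if C < int(graph.communities.max(initial=-1)) + 1:
        raise ValidationError("C must cover every node community label")
    n, E = graph.n_nodes, graph.n_edges
    deg = np.zeros(n)
    if E:
        np.add.at(deg, graph.edges[:, 0], 1)
        np.add.at(deg, graph.edges[:, 1], 1)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, graph.edges))
    avg_clust = nx.average_clustering(g) if n else 0.0

    comp = np.bincount(graph.communities, minlength=C).astype(np.float64) / n

    pair_frac = np.zeros(C * (C + 1) // 2)
    same_frac = 0.0
    if E:
        la = graph.communities[graph.edges[:, 0]]
        lb = graph.communities[graph.edges[:, 1]]
        a, b = np.minimum(la, lb), np.maximum(la, lb)
        # index of unordered pair (a, b), a <= b, in lexicographic order
        pair_idx = (a * (2 * C - a + 1)) // 2 + (b - a)
        np.add.at(pair_frac, pair_idx, 1.0)
        pair_frac /= E
        same_frac = float((la == lb).mean())

    if E:
        adj = np.zeros((n, n))
        adj[graph.edges[:, 0], graph.edges[:, 1]] = 1.0
        adj[graph.edges[:, 1], graph.edges[:, 0]] = 1.0
    else:
        adj = np.zeros((n, n))
    eigs = np.sort(np.linalg.eigvalsh(normalized_laplacian(adj)))
    top = eigs[-m:] if n >= m else eigs
    spectrum = np.concatenate([np.zeros(m - len(top)), top])  # ascending, left-padded

    return np.concatenate([
        [n, E, deg.mean() if n else 0.0, deg.std() if n else 0.0,
         deg.max() if n else 0.0, avg_clust,
         graph.lengths.mean() if E else 0.0,
         graph.lengths.std() if E else 0.0],
        comp, pair_frac, [same_frac], spectrum,
    ])
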