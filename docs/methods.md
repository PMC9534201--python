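# Methods

## Model and assumptions

The pipeline treats a tissue image as a spatial point pattern of cells with
appearance features and summarizes it hierarchically:

- **Cell phenotypes** are latent discrete subtypes expressed in appearance
  features. Because the cellular composition of the tumor microenvironment
  is not assumed known, phenotypes are discovered without labels: features
  are z-scored pooled across the *whole cohort* (so a phenotype identity is
  comparable across images — per-image scaling would decouple identities)
  and clustered with k-means. The candidate phenotype count is scanned over
  `k_cell_range` (default 2–6) and chosen by mean silhouette, ties to the
  smallest k. K-means is one defensible choice among several for "which
  unsupervised algorithm"; it is deterministic under a seed, fast at
  10^5-cell scale, and swappable behind the same operation signature.

- **Supercells** formalize "closely interacting cells" as connected
  components of a local graph: the union-symmetrized `k_nn`-nearest-
  neighbour graph with edges cut at `d_max` pixels. Two knobs, both
  interpretable: `k_nn` (default 10) bounds the candidate neighbourhood,
  `d_max` (default 20 px) is the interaction range. With `k_nn ≥ n` the
  construction reduces exactly to the ≤ d_max pairwise-distance relation
  (a property the tests check against brute-force union-find). "Factoring
  in subtypes" is a mode switch: the default `agnostic` mode lets subtypes
  enter through the descriptor's composition block; `stratified` restricts
  edges to equal-phenotype pairs. Components with fewer than
  `min_supercell_size` (default 5) cells are discarded and counted.

- **Supercell descriptors** are fixed-order vectors
  `[n_cells, phenotype fractions (k), hull area, density, mean NN distance,
  mean standardized features (F)]` of length `k + F + 4`. Degenerate hulls
  (< 3 members or collinear) get area 0 and density 0; singletons get mean
  NN distance 0.

- **Communities** are clusters of supercells in descriptor space, fitted
  once on the pooled cohort (Ng–Jordan–Weiss normalized spectral
  clustering). The affinity is Gaussian with bandwidth σ = median pairwise
  distance — scale-free and parameter-light; the diagonal is zeroed. The
  community count is the eigengap argmax over k ∈ [2, 10] unless given
  explicitly. Out-of-sample supercells are embedded by a kernel-weighted
  (Nyström-style) average of the training embedding and assigned to the
  nearest embedding centroid; rows identical to a training row inherit its
  fit-time label. Fitting once and extending out-of-sample, rather than
  refitting per image, is what makes community identities — and therefore
  the global-graph features — comparable across images.

- **The global graph** joins supercell centroids by Delaunay triangulation,
  the dominant convention in cell-graph pathology, and prunes edges longer
  than the image's `delaunay_prune_percentile` (default 95th) of Delaunay
  edge lengths to remove the long boundary edges triangulation creates.
  The image feature vector contains degree/clustering/edge-length
  statistics, community composition, **community-pair edge fractions** (the
  designated carrier of supercell-interaction structure), the same-label
  edge fraction, and the `m` largest normalized-Laplacian eigenvalues
  (default m = 8, ascending, left-zero-padded) so the vector length
  `9 + C + C(C+1)/2 + m` is constant across a cohort.

- **Classification** is repeated stratified CV (default 5 folds × 20
  repeats) with an L2-regularized multinomial logistic regression;
  standardization is fit inside each training fold only. Accuracy and
  per-class one-vs-rest AUC are reported as mean ± sample std (ddof = 1)
  across repeats. What the ± should span (folds, repeats, bootstrap) is a
  reporting choice; here it is repeats, echoed in the result object.

## Numerical choices and tie-breaks

- Ties everywhere resolve to the lowest index / smallest k: silhouette and
  eigengap selection, nearest-centroid assignment (`argmin` first hit).
- Seeds: every stochastic step (k-means restarts, silhouette subsampling,
  embedding k-means, CV shuffles, synthetic generation) draws from the
  single configured seed; per-image generator substreams use
  `SeedSequence(seed, spawn_key=(image_index,))` so images are independent
  and bit-reproducible.
- Silhouette is evaluated on at most 5000 seeded sample rows; above that
  size the O(n²) exact score costs more than it informs model selection.
- The edge-pruning threshold uses the "higher" percentile method, so the
  threshold is an actual edge length and small graphs (e.g. a triangle at
  the 95th percentile) are not disconnected by interpolation artifacts.
- Degenerate global-graph inputs: 2 supercells → one edge; 1 → edgeless;
  collinear centroids → path along the lexicographically sorted axis;
  duplicate centroids → deterministic 1e-6 px jitter with a warning.
- Circularity is `4πA/P²` with the marching-squares perimeter estimator of
  `skimage.measure.regionprops`; it is defined as 0 when the estimated
  perimeter is 0 (single-pixel regions).
- Constant features are dropped (with a recorded list) before phenotyping;
  constant descriptor dimensions are kept with sd forced to 1 so the
  descriptor layout is stable.

## What the synthetic generator emulates — and what it does not

The generator plants exactly the structure the pipeline is built to
recover: Gaussian phenotype clusters in feature space (default 3 phenotypes
at 6-sd mean separation), spatially clumped cell clusters (8–12 per
512×512 image, 15–30 cells each), and image classes that differ *only* in
the mixture of cluster archetypes — each archetype fixes a cluster's
phenotype composition (default: 0.8 dominant / 0.1 rest), each class
prefers one archetype (default 0.7 / 0.15 / 0.15). Class signal therefore
lives purely in community composition and interaction structure, which is
the pipeline stage worth stress-testing.

Cluster centers are rejection-sampled with pairwise separation ≥ 4 × the
cluster radius (default 20 px), and cell offsets follow an isotropic
Gaussian (sd = radius/2) truncated at the radius. The truncation is what
turns "clusters are usually separate" into a guarantee: cells of different
clusters are always > 2 × radius apart, so `d_max = radius` recovers the
planted clusters exactly — the recovery tests can assert exact counts
rather than high-probability ones.

Real tissue violates most of these simplifications: appearance features are
correlated and heavy-tailed, phenotype boundaries are soft, cell clusters
abut and overlap, densities vary within an image, and segmentation errors
add or merge cells. Passing the synthetic suite therefore shows that the
machinery is correct (each stage recovers what was planted, invariants
hold, the pipeline is deterministic), not that any particular clinical
discrimination is achievable; on real cohorts the knobs (`d_max`,
`min_supercell_size`, community count) need domain tuning.

On the default cohort the eigengap typically selects around 5 communities
against the 3 planted archetypes: with per-cluster multinomial sampling of
15–30 cells, empirical composition blobs have internal structure that a
purely geometric eigengap can legitimately split. Classification is
unaffected — community fractions remain class-informative under
refinement — which is why the end-to-end contract is stated in terms of
discrimination, not community count parity.

## Problem sizes

The default study conditions are 3 classes × 30 images (~20k cells, ~900
supercells); the full pipeline runs in well under a minute on one CPU, and
the acceptance script (pipeline + permutation null) in about one minute.
Unit and property tests use smaller cohorts (3 × 5 images) or closed-form
micro-geometries.

## Known limitations

- Feature noise in the generator is isotropic and uncorrelated (v1).
- No soft/overlapping supercell assignment; a cell belongs to exactly one
  component. No Voronoi/alpha-shape supercell boundaries.
- Communities come from descriptor-space clustering, not from graph
  community detection (Louvain/Leiden) on the global graph — the global
  graph is a feature source, not a clustering substrate.
- No nucleus segmentation, slide tiling, or stain normalization: the
  package starts from label masks or cell tables.
- The eigengap heuristic can over- or under-split when descriptor clusters
  are non-compact; pass an explicit `n_communities` when a domain prior
  exists.
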