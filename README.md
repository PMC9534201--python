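# supercellgraph

Hierarchical graph modeling of tissue spatial architecture from digital
pathology. Given per-image cell tables (centroids + appearance features) or
integer label masks from any upstream nucleus segmentation, the pipeline

1. **phenotypes cells** by unsupervised clustering — features are z-scored
   across the whole cohort and clustered with k-means, with the number of
   phenotypes `k` chosen by mean silhouette over a candidate range;
2. **merges closely interacting cells into supercells** — a per-image local
   graph connects each cell to its `k_nn` nearest neighbours, keeps edges of
   length ≤ `d_max` px (optionally only between same-phenotype cells), and
   takes connected components with ≥ `min_supercell_size` members;
3. **discovers supercell communities at population level** — supercell
   descriptors (size, phenotype composition, convex-hull geometry, density,
   mean appearance) are pooled across all images and clustered with
   normalized spectral clustering (Gaussian affinity
   `A_ij = exp(−‖z_i−z_j‖²/2σ²)` with median-distance bandwidth, Laplacian
   `L = I − D^{−1/2} A D^{−1/2}`, eigengap selection of the community
   count);
4. **builds a per-image global graph** — a Delaunay triangulation over
   supercell centroids with percentile edge pruning — and reads off a
   fixed-length feature vector (degree and clustering statistics, community
   composition, community-pair edge fractions, Laplacian spectrum);
5. **classifies images** with L2-regularized multinomial logistic regression
   under repeated stratified cross-validation, reporting accuracy and
   one-vs-rest AUC per class as mean ± std over repeats.

The intended users are computational-pathology researchers who want an
interpretable, multi-scale alternative to end-to-end CNN/GCN pipelines for
profiling intratumoral heterogeneity: every intermediate object (phenotype,
supercell, community, graph edge) is an inspectable artifact.

A synthetic tissue generator with planted ground truth (phenotypes, spatial
clusters, class-specific community mixtures) makes every stage testable
without access to clinical slides.

## Worked example

```bash
supercellgraph fixtures --out data --seed 3 --images-per-class 5
supercellgraph run data --seed 3 --out out
```

prints (numbers from this exact command):

```
stages run: phenotype, supercell, community, features, classify
Method           Accuracy       AUC (class 0)  AUC (class 1)  AUC (class 2)
supercell-graph  0.980 ± 0.031  1.000 ± 0.000  1.000 ± 0.000  1.000 ± 0.000
```

The fixture cohort is 3 classes × 5 images; classes share the same three
cell phenotypes and differ only in the mixture of cluster archetypes
(community composition), so the near-perfect accuracy and AUCs show the
community/global-graph stages carrying the class signal. `out/`
contains the labeled cell tables, the supercell roster with descriptors and
community labels (`supercells.csv`), GraphML local/global graphs, the image
feature matrix (`features.csv`), both fitted models, and a run manifest
with a config hash and per-stage records.

The same pipeline is available as a library:

```python
from supercellgraph import PipelineConfig, SyntheticSpec, generate_dataset, run_pipeline

tables, labels, truth = generate_dataset(SyntheticSpec(seed=3))
run = run_pipeline(PipelineConfig(random_seed=3), tables, labels)
print(run.classification.render_table())
```

Notes on conventions: coordinates are 0-based pixel indices (x = column,
y = row, origin top-left). Cell circularity is `4πA/P²` with the perimeter
taken from scikit-image's marching-squares contour estimator
(`regionprops.perimeter`); other perimeter definitions shift circularity by
a few percent, so compare like with like.

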