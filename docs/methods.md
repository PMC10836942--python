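# Methods

## Overview

`shmkit` renders *spatial heatmaps* (SHMs): anatomical SVG images whose
annotated spatial features (organs, tissues, cell layers) are filled with
colors proportional to quantitative assay values through a numeric color
key. Around that core it provides one-vs-rest detection of spatially
enriched/depleted biomolecules, co-expression mining (similarity search,
hierarchical clustering, soft-threshold network modules, gene-set
enrichment), and co-visualization of single-cell embeddings with the
anatomy through explicit tissue-to-cell mappings.

## The aSVG model

An annotated SVG is an ordinary SVG 1.1 file in which the colorable
elements carry unique `id` attributes. Any drawable (`path`, `rect`,
`circle`, `ellipse`, `polygon`, `polyline`, `line`) with an id is a
spatial feature; a `g` element with an id is a feature that covers its
id-less descendant drawables (they inherit the group's fill), while
id-bearing descendants become features of their own. This matches the
structure of public anatomogram collections, where not every path is
individually annotated. Document order defines the layer index (0 =
bottom). Coordinates stay in the SVG-native frame (user units, y down);
renderers flip at draw time.

Geometry is kept in its verbatim source encoding, so writing is lossless;
a small path-data decoder (all SVG 1.1 commands, absolute and relative)
extracts end and control points when bounding boxes or rasterization need
actual coordinates. Control points make the path bbox a conservative
hull; for the polygonal anatomies this package generates the hull is
exact. Canvas tiling (`combine_docs`) translates each document by a
running offset with a gap of 2% of the largest input canvas dimension;
colliding ids get the deterministic suffix `__k` (k = 2-based document
position). Styling precedence: inline `style` overrides presentation
attributes; unknown inline keys are preserved verbatim. All edit
operations are pure (deep-copy in, new document out), and the writer uses
fixed float formatting so identical documents produce byte-identical
files.

## Assay containers and normalization

Bulk data are a genes x samples matrix with per-sample metadata (feature
label, condition, replicate) and an explicit `value_space` tag (`counts`,
`normalized`, `log`, `lfc`) so every downstream consumer knows the scale.
Normalization is either median-of-ratios size factors (per sample j,
the median over genes with a positive geometric mean of count_gj /
geomean_g, rescaled to geometric mean 1) or counts-per-million, followed
optionally by log2(x + pseudo) with pseudo-count 1. Relative values are
per-feature treatment-minus-control means of log values, i.e. log2 fold
changes; the operation is antisymmetric under swapping the two condition
labels. Assay feature labels are matched to SVG ids exactly and
case-sensitively, optionally through a user translation table; unmatched
labels on either side are reported, never fatal.

## Color keys and SHM rendering

A color key is k ordered colors over k+1 equally spaced breaks spanning
the data range. Bin assignment is half-open (`breaks[i] <= v <
breaks[i+1]`), the last bin right-closed, out-of-range values clamp to
the end bins, NaN maps to a light grey reserved NA color. When all
values coincide at v the key degenerates to [v-1, v+1] and every value
lands in the middle bin. Palettes are matplotlib colormaps: YlOrRd for
absolute values; for fold changes the default is a blue-white-red
diverging map with the range forced symmetric around 0, so sign maps to
hue. Replicates are aggregated by mean (median selectable) before
coloring. With a shared scale one key spans all panels of a figure; with
`per_gene` each gene row gets its own. Panels are written one SVG per
(gene, condition) with deterministic names (`{gene}__{condition}.svg`);
PNG rasterization (matplotlib Agg, 150 dpi default) approximates curved
path segments by their control polygons, which is exact for the
polygonal toy anatomies. A raster photograph can be attached as the
bottom layer with adjustable opacity and optional grayscale reduction.

## Spatial enrichment

Given K query features, a gene is *enriched* in feature F when, in at
least (K-1) - outliers of the K-1 pairwise comparisons F vs G, the
BH-adjusted Welch-t p-value is <= alpha and the log2 fold change is >=
lfc_min (depleted: <= -lfc_min). The `outliers` parameter relaxes the
strict one-vs-all requirement so a gene shared by a few features can
still be called. The same machinery runs on condition labels to find
treatment-specific genes. The per-comparison test is Welch's two-sample
t on log-normalized replicate values with the Welch-Satterthwaite df,
vectorized over genes; within-group variances of exactly zero are floored
at 1e-8 so constant genes yield t = 0, p = 1. P-values are adjusted by
Benjamini-Hochberg across the genes of each comparison. A pre-filter
removes genes with zero variance across the compared replicates and
genes that fail a weak-expression floor (log2 value >= 1, i.e. CPM >= 1
under pseudo-count 1) in fewer than the smaller replicate-group size of
samples. Per gene and feature the result reports the most conservative
supporting evidence: the smallest |lfc| and largest adjusted p among the
supporting comparisons, plus the support count.

Two structural properties follow from the rule and are verified in
tests: at outliers = 0 the enriched sets of different features are
disjoint (a gene cannot be up against all others in two places at once),
and the called set grows monotonically with the outlier allowance.

### Measured operating characteristics

On the simulation the test suite uses for recovery (2000 genes, 5
features x 4 replicates, 5% of genes planted at log2 fold change 3, NB
dispersion 0.1, alpha 0.05, lfc_min 1, outliers 0) the procedure is
strongly conservative: measured FDR is 0 and the null false-call rate is
far below alpha, but sensitivity is only ~0.25-0.30. The cause is
structural: with 4 replicates the per-comparison power against the BH
threshold (at ~2% true signals among 2000 genes) is ~0.75-0.85, and a
call requires all four comparisons of the conjunction to pass
simultaneously. Raw p-values of planted genes are essentially all below
5e-3; it is the multiplicity correction combined with the all-comparisons
conjunction that rejects marginal genes. Variance-moderated tests (as in
dedicated DE frameworks) would be more powerful at this replicate count;
this package deliberately uses the closed-form Welch test so results are
reproducible without those frameworks, and reports the operating
characteristics it actually achieves. The corresponding recovery test in
the suite asserts the nominal 0.90 sensitivity bound and therefore fails
by design, documenting the gap rather than hiding it.

Overlaps between per-feature gene sets are summarized as a K x K
intersection-count matrix (diagonal = set sizes), an UpSet table of
exclusive membership-pattern counts (summing to the union size), and
Venn region counts for K <= 5.

## Mining

*Similarity search* ranks all genes against a query profile by Pearson or
Spearman correlation (descending) or Euclidean distance (ascending), ties
broken by gene id; selectors are a fixed count, a percentage (`top_pct`
p keeps ceil(p/100 x n) genes counting the query; the workflow default is
15%), or a similarity threshold. Spearman is the rank transform (average
ranks on ties) followed by Pearson.

*Hierarchical clustering* is agglomerative with correlation (1 - Pearson)
or Euclidean distance and average/complete/single linkage. The
agglomeration is written out explicitly with Lance-Williams updates so
tie-breaking is fully deterministic: among equally close pairs, the pair
whose smallest original leaf indices sort first merges. Trees are cut at
a height (merges with height <= h kept) or into exactly k clusters;
labels are numbered by each cluster's smallest leaf index. The suite
checks the merge heights against both a naive O(n^3) re-agglomeration and
scipy's independent implementation.

*Networks* use the unsigned soft-threshold adjacency a_ij = |cor_ij|^beta
with unit diagonal; beta defaults to 6, the common unsigned-network
choice that suppresses weak correlations while keeping strong
co-expression. Modules come from average-linkage clustering of 1 - a cut
at a fixed height (default 0.8; 1 - 0.9^6 ~ 0.47 for strongly
co-expressed pairs, ~1 for unrelated ones, so the default separates
planted blocks cleanly); clusters below `min_size` (default 5) stay
unassigned (label 0). A fixed-height cut is used rather than a dynamic
branch-splitting cut; this is a documented simplification. Connectivity
is each gene's adjacency sum within its own module. Graphs export to
GraphML with module/connectivity node attributes and edges pruned below
adjacency 0.1.

*Gene-set enrichment* of a cluster is the upper-tail hypergeometric
P(X >= overlap) with the supplied universe as population, BH-adjusted
across sets; sets come from standard GMT files.

## Co-visualization

PCA is the deterministic embedding baseline: centered SVD with each
component's sign fixed so its largest-magnitude loading is positive.
UMAP and t-SNE are seeded optional backends behind the same interface.

Tissue-cell maps associate cell-group labels with feature ids by five
routes: existing annotations (exact matching, optional translation
table); marker genes (each group scored by mean log expression of each
feature's enriched gene set; assigned to the argmax feature when it beats
the runner-up by a margin, default 0.5 log2 units, else orphan); manual
pair tables (validated verbatim); cluster labels plus a cluster-feature
table; and co-clustering. The co-clustering route intersects genes (>=
50 required), log-normalizes both sides (cells to a common library size,
then log2(x+1)), partitions cells by k-means on the top 10 PCs (k =
number of bulk features by default, seeded), correlates each cluster's
pseudo-profile (mean log expression) with every bulk feature's mean
profile, and assigns the best-correlated feature when r >= 0.3, else
orphan. This is a deliberately simple correlation-assignment scheme;
the 0.3 floor and the marker margin are configurable defaults. Groups
without an assignment are *orphans* and render grey in every scheme.

Four coloring schemes connect the two panels: `fixed_by_group`
(categorical color per mapped feature, propagated to its cells),
`cell_by_group` (per-group summary of a gene's single-cell expression
through one key, applied to cells and matched features),
`feature_by_group` (bulk value per feature, propagated to cells), and
`cell_by_value` (every cell by its own value, features by bulk, one
shared key). Composite figures are built from the package's own SVG
primitives — the embedding scatter is itself an SVGDoc of circle features
(one per cell, id = cell id) tiled next to the colored anatomy — so
every color in the output can be parsed back and checked.

Spatially resolved cells (scSHM) are registered onto a target feature by
a uniform-scale affine map: the cell-coordinate bounding box is scaled by
min(width-ratio, height-ratio) and centered on the feature's bounding
box, preserving aspect and hence relative pairwise distances up to one
global factor. Cells outside the plotted cluster set render grey.
Deconvolution outputs (a genes x cell-types expression table plus
proportions summing to 1) are shown as a cell-type panel positioned by
PCA of the type profiles, colored cell-by-value, each dot carrying its
proportion formatted to two decimals, next to the bulk SHM.

## Synthetic data

The simulators make every module testable without downloads and define
the package's study conditions:

- **Toy anatomies**: jittered octagons on a grid (non-overlapping by
  construction), ids `feat_1..`, optional semi-opaque overlay rectangle
  for transparency tests. Byte-identical output for identical seeds.
- **Bulk counts**: negative binomial with variance mu + phi mu^2, phi =
  0.1; gene base means log-normal(log 50, 1) (spanning roughly 2-3000
  counts, as in a typical bulk RNA-seq library); per-sample library
  multipliers log-normal(0, 0.15). A chosen fraction of genes gets a
  multiplicative 2^lfc boost in one feature (round-robin) or one
  condition. Ground truth (multipliers, planted assignments, true
  feature mean profiles) is recorded.
- **Single cells**: one group per bulk feature, NB draws around the
  feature's true mean profile rescaled to a 20k expected total per cell,
  extra dispersion phi = 0.3, per-cell log-normal(0, 0.2) size jitter;
  optional disjoint rectangular spatial regions per group with uniform
  placement.

What the simulations do *not* emulate: gene-gene correlation, doublets,
ambient contamination, zero-inflation beyond NB, batch structure, or
realistic anatomical geometry. Passing recovery tests therefore shows the
algorithms implement their rules correctly and recover clean planted
structure, not that they are robust to every artifact of real data.

## Numerical and design choices

- Color-key interior breaks assign to the higher bin; the last bin is
  right-closed; these tie rules make binning a total, monotone function.
- Welch variance floor 1e-8 prevents division by zero on constant
  groups; the resulting p = 1 is the conservative choice.
- Dendrogram ties resolve lexicographically by smallest leaf index, so
  clustering is reproducible across platforms regardless of float
  ordering accidents.
- PCA sign convention (largest loading positive) makes embeddings
  deterministic; k-means uses an explicit seed and 10 restarts.
- All generators and CLI subcommands are pure functions of their seed;
  file outputs use fixed float formats, so reruns are byte-identical.
- Problem sizes in the test suite (300-2000 genes, 4 replicates, tens to
  hundreds of cells) are chosen so the full suite and the acceptance
  script each run in well under a minute while still exercising every
  statistical property at meaningful scale.

## Known limitations

- CSS stylesheet cascades, SVG 2 features, animation and font rendering
  are out of scope; only presentation attributes and inline styles are
  interpreted.
- Rasterization approximates Bezier segments by control polygons;
  publication-quality curved output should use the written SVGs.
- The fixed-height module cut is simpler than dynamic tree cutting and
  may split large uneven modules.
- The enrichment test's sensitivity at small replicate counts is limited
  by design (see measured operating characteristics above).
- Co-clustering assumes cell groups correspond to profiled bulk features;
  cell types absent from the bulk panel can only become orphans.
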