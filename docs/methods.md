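# Methods

This note documents the models and procedures implemented in `goclust`, the
choices made where the design was genuinely open, and what the simulation
benchmark does and does not show.

## Annotation encoding

Associations between genes and biological functions (GO "Biological
Process" terms in the intended use) are encoded as a binary matrix
`T ∈ {0,1}^(K×J)` with explicit margins `T_k.`, `T_.j`, `T_..`.  Optional
ancestor propagation follows the term hierarchy: a gene annotated to a term
is annotated to all of the term's transitive ancestors.  By default only
`is_a` edges of an OBO ontology are followed; `part_of` can be enabled.
GAF evidence codes are ignored unless the caller excludes some (e.g. IEA).

Functions annotated to fewer than `min_genes = 2` genes are filtered out: a
single-gene function contributes nothing to between-gene similarity and
cannot be decomposed.  Genes left with an all-zero row are retained in the
matrix (dropping them silently would desynchronise gene indices with the
expression matrix) but flagged, and the pipeline excludes them from the
distance computation, whose per-gene profile divides by `T_k.`.

## Coexpressed biological functions

Each function *j* with gene set `K^j` is processed as follows.

* **Step 0 (filter).**  The coexpression indicator of `K^j` is compared
  with `B = 500` size-matched gene sets drawn without replacement from all
  genes; if the permutation p-value is below `alpha0 = 0.10`, the function
  counts as coexpressed and is kept as a single column.  The null draws
  from all genes of the expression matrix, not only annotated ones.
* **Steps 1–3 (split).**  Otherwise the genes of `K^j` are clustered by
  Ward linkage on the correlation distance `1 − r` (computed in a unit-norm
  embedding of the standardised profiles, so the distance is realised as
  squared Euclidean geometry, which is Ward's natural criterion — the
  linkage is a design choice; the intra-cluster-inertia reasoning behind
  the cut rule points to Ward).  The tree is cut at the number of clusters
  `L* = argmax_{L ∈ {2..L_max}} (W(L−1) − W(L)) / W(L−1)`, where `W(L)` is
  the sum of intra-cluster inertias of the L-cluster partition — the finer
  side of the largest relative inertia drop; ties break toward smaller L;
  two genes force `L = 2`.  `L_max = min(card(K^j) − 1, 10)`: an unbounded
  range degenerates toward all-singleton splits.

Sub-clusters are ordered by decreasing size (ties by first gene position)
and indexed `l = 1..L_j` after ordering, so output is reproducible.  The
expanded matrix `T_coexp` satisfies, by construction and by runtime
assertion: `Σ_l card(K_l^j) = T_.j` per function, row margins and total
equal to those of `T`.  Setting `alpha0 ≥ 1` short-circuits step 0 and
makes `T_coexp = T` exactly.

## Chi-square distance and clustering

The squared distance between genes is the chi-square distance between rows
of `T_coexp` with column weights `T_.. / card(K_l^j)`.  It is stored
squared (`is_squared=True`) because the defining sum of squares is the CA
convention; the square root is the metric satisfying the triangle
inequality and is what Ward linkage consumes.  The implementation is
vectorised through weighted profiles; its equality with a term-by-term
double sum and with squared Euclidean distances between full-rank
Correspondence Analysis row coordinates is enforced by tests (tolerances
1e-10 and 1e-8).

`cluster_genes` offers Ward HAC on the square-rooted distances (default)
and K-means with 20 seeded restarts.  K-means needs a vector space: the
package reconstructs coordinates from the squared distance matrix by
classical (Torgerson) MDS, which for this Euclidean-embeddable metric
agrees with the CA row coordinates up to rotation and translation —
transformations K-means is invariant to.  The number of clusters is a
required user input; no automatic selection is attempted.  Rare, heavily
weighted columns (small `card(K_l^j)`) can place single genes far from
everything else, so singleton clusters are common and permitted; K-means is
noticeably more sensitive to these outliers than Ward.

## Cluster evaluation

* **CI**: mean pairwise Pearson correlation (population 1/I normalisation;
  the normalisation cancels in the correlation).  Its mean over
  `n(n−1)/2` pairs mechanically shrinks with cluster size.  The mean
  off-diagonal of a correlation matrix is bounded below by `−1/(n−1)`
  (positive semi-definiteness); the two-anti-correlated-sub-groups
  construction attains `−1/(n−1)` for even n and `−1/n` for odd n.
* **BHI**: `1 − χ²/(N(n−1))` where `χ²` is the independence chi-square of
  the cluster × functions subtable (functions absent from the cluster drop
  out) and `N` its total — one minus the squared Cramér's V of that table.
  Margins are those of the cluster subtable: this is the reading under
  which the indicator genuinely measures within-cluster similarity of
  functional profiles, the extremal derivations (identical profiles → 1,
  fully gene-private functions → 0) hold, and the bound
  `χ² ≤ N·(min(rows, cols) − 1)` keeps BHI in [0, 1] for every cluster.
  BHI is always computed on the original `T`, never on `T_coexp`.

Both indicators carry a permutation p-value: `B` clusters of the same size
are drawn without replacement from the full gene universe, and the p-value
is the proportion of null values *strictly* greater than the observed one
(ties count as non-exceeding; the plain proportion can be exactly 0 — a
`(b+1)/(B+1)` correction is available but off by default).  Because the
null distribution depends only on the data and the cluster size, nulls are
drawn once per size and cached; within a benchmark replicate the cache is
shared across methods, so all methods face identical nulls.  This is
statistically identical to drawing per cluster and keeps the benchmark fast.
Singletons are not tested, are never significant, and stay in the
denominator of the partition-level percentages.  Defaults: `B = 1000`
(500 in the benchmark), `alpha = 0.05`; the "both" flag requires each
p-value below `alpha` separately.  No multiple-testing correction is
applied across clusters: the per-cluster p-values are reported raw.

## Simulation design

`simulate_expression` draws K genes × I samples from a multivariate
Gaussian with block-diagonal correlation: `rho_within` inside each planted
block, `rho_between` (default 0) elsewhere, via a shared-factor
construction.  Defaults — I = 10, K = 300, 20 equal blocks,
`rho_within = 0.85` — follow the small benchmark configuration, with the
block count matching the 20-cluster partitions evaluated.  The
equicorrelated block structure is the minimal one producing underlying
clusters of coexpressed genes; nothing finer is claimed about real
microarray noise.

`simulate_structured_annotations` builds a Ward tree on the correlation
distances of the simulated expression and makes every internal node except
the root a function annotated to the node's leaves (K − 2 columns for a
binary tree over K genes).  The nesting of node columns mimics GO's
hierarchy, and genes with similar expression mechanically receive similar
functional profiles.  The root is excluded: an all-ones column is
uninformative and its chi-square weight `T_../K` would be meaningless.
Leaves are not counted as nodes (a leaf column would be a single-gene
function, which the encoder filters anyway).

`simulate_random_annotations` juxtaposes r copies of the structured matrix
and independently permutes rows within each column: column margins — the
degree of specificity of each function — are conserved *exactly*, while
any association with the expression blocks is destroyed.  The intensity of
randomness r is the ratio of random to structured columns.

**What passing benchmarks show.**  The generator produces clean, equally
sized, strongly correlated blocks whose annotation structure derives from
the very tree of the simulated expression.  Under these conditions any
reasonable expression-only clustering recovers the planted blocks almost
perfectly, so the heatmap and network comparators score near-ceiling
percentages on all indicators and the cross-method gaps on biological
homogeneity are compressed relative to what messier, more realistic
expression structure would show; the integration method's own percentages
and their decline with r are the informative quantities.  Conclusions about
real data — where expression clusters and GO structure diverge much more —
rest on the method, not on these simulations.

## Comparators

* Heatmap: Ward linkage on the correlation distance, flat cut at the target
  cluster count (the gene-side tree of a heatmap; the sample-side tree does
  not affect gene partitions).
* WGCNA-style: unsigned adjacency `|cor|^β` with β = 6 (the classical
  soft-threshold default, fixed rather than fitted for determinism),
  topological-overlap similarity
  `TOM_kk' = (Σ_u a_ku a_uk' + a_kk') / (min(k_k, k_k') + 1 − a_kk')`,
  average-linkage clustering of `1 − TOM`, flat cut.  Module eigengenes,
  dynamic tree cut and scale-free fitting are out of scope: the comparator
  reproduces the dissimilarity, not the full WGCNA toolchain.

Both comparators use a flat cut at the configured cluster count so that all
methods produce partitions of identical size.

## Numerical and reproducibility choices

Correlations are computed once per dataset through a unit-norm embedding
and clipped to [−1, 1]; constant-expression genes are rejected at load
(their correlation is undefined).  Distances are symmetrised and clipped at
0 to absorb floating-point noise.  `fcluster(..., criterion="maxclust")`
may return fewer clusters than requested on degenerate ties; inertia is
then computed for the partition actually returned.  All randomness flows
from one top-level seed: the pipeline fans it out into named sub-streams
(step-0 permutations, clustering restarts, evaluation nulls) via hashed
seed sequences, and the benchmark derives one child generator per
(configuration, replicate), so every run is bit-reproducible and any
replicate can be recomputed in isolation.

Benchmark problem sizes: 20 replicates for the main (I=10, K=300, r=1)
configuration and 10 replicates per r for the randomness-intensity trend,
with B = 500 permutation draws — sizes at which the replicate means are
stable to within a few percentage points.

## Known limitations

* The chi-square weights inflate the influence of very small coexpressed
  sub-clusters; downstream K-means is sensitive to the resulting outlier
  genes, and the method produces a non-negligible share of singleton
  clusters, which are automatically bad candidates.
* BHI compares functional profiles wholesale; it knows nothing of the
  semantic distance between GO terms (two genes annotated to sibling terms
  count as dissimilar).
* The simulation does not model microarray/RNA-seq noise, missing values,
  unbalanced block sizes, or DAG-shaped (non-tree) annotation structure.
* Evidence-code quality, obsolete-term remapping and term-name resolution
  are outside the encoder's scope.
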