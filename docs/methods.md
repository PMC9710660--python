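# Methods

## The model of a dot plot

The engine treats a dot plot as a function from a long-format table to a
scene graph. A table row is a record `(x_level, y_level, f_1 … f_k)` with
`1 ≤ k ≤ 4` display factors, each **quantitative** (finite reals, missing
allowed) or **qualitative** (unordered labels). The cap of four factors is
structural: there are exactly four visual channels (size, color, text,
shape), a factor may drive at most one channel, and size only accepts
quantitative factors — a qualitative "size" has no honest geometric reading.
Each (x, y) combination may appear at most once; duplicates are an error
rather than being silently aggregated, because the format means "one summary
record per combination". Before composition the grid is completed: absent
combinations get missing values everywhere, and a missing size value omits
the dot entirely (absence and zero are visually distinct).

## Summarization of expression data

For gene *g*, cluster *k*, threshold *t* (default 0, "strictly greater"):

* `Pct.exp = 100 · #{cells in k with x > t} / #{cells in k}`.
* `Scaled.expr`: z-score the gene across **all** cells with the sample
  standard deviation (n − 1), then average z within each cluster. Scaling
  before averaging (rather than z-scoring cluster means) keeps cluster sizes
  in the weighting and guarantees the size-weighted cluster mean is exactly 0
  per gene — a property the test suite asserts at 1e-10. A zero-variance gene
  cannot be z-scored; it reports 0 for every cluster with a warning rather
  than failing, since constant genes are routine in subsetted matrices.

No normalization is applied: the adaptor summarizes what it is given, so
log-normalized input yields log-space summaries. A second modality (e.g.
antibody-derived tags alongside RNA) is handled by running the same formulas
on a second matrix over the same cells and attaching its `Pct.exp` as an
extra column; each modality is scaled independently. Matrices are densified
on load — the adaptor targets marker-panel-scale inputs (tens of genes ×
up to a few thousand cells), not atlas-scale matrices.

The built table puts clusters on x and genes on y, the usual marker-panel
orientation.

## Factor analysis and axis ordering

To order an axis, each chosen factor is pivoted wide along it (levels ×
other-axis levels) and the concatenated profiles are embedded:

* **PCA** (all columns quantitative): center, optionally divide by the
  population standard deviation, SVD; eigenvalues σ²/(n−1), row coordinates
  U·Σ. Zero-variance columns are dropped with a warning (with a tolerance
  relative to column magnitude, so mean-imputed columns that are constant up
  to rounding are also dropped).
* **MCA** (all qualitative): correspondence analysis of the indicator matrix
  Z. With P = Z/(nQ), row masses 1/n and column masses c, the SVD of
  `Dr^(−1/2)(P − rcᵀ)Dc^(−1/2)` gives eigenvalues σ² summing to (J−Q)/Q;
  the centering term removes the trivial dimension (it appears as a zero
  singular value rather than a leading 1). Row coordinates are
  mass-standardized principal coordinates √n·U·Σ. Single-category columns
  carry no inertia and are dropped with a warning.
* **FAMD** (mixed): quantitative columns standardized (population sd);
  each indicator divided by √(category proportion), then centered; unscaled
  PCA of the concatenation with population-convention eigenvalues σ²/n.
  Under these weights a standardized quantitative column contributes inertia
  1 and a qualitative column with J_q categories contributes J_q − 1, so the
  all-quantitative case reduces exactly to scaled PCA (identical
  coordinates). With only qualitative columns the eigenvalues are Q times
  the MCA eigenvalues — the inertia proportions, and hence the ordering,
  coincide; the two conventions differ only by that scalar.

Component signs follow the largest-|loading|-positive convention so
coordinates are reproducible across runs and platforms.

Default factor choice for ordering: all quantitative display factors if any
exist, else all factors — percentages and expression summaries are usually
the quantities users mean to cluster on. Missing values (typically created
by grid completion) are mean-imputed (quantitative) or given their own
"missing" category (qualitative), with a warning: the factor analyses need
complete matrices, and imputation at the column mean is inertia-neutral.

Clustering is agglomerative on Euclidean distances over the embedding
coordinates (all components by default; `n_components` can truncate), with
ward (default), complete, average or single linkage, delegated to
`scipy.cluster.hierarchy.linkage`; the test suite checks it exactly (heights
to 1e-10, identical merge topology) against an independent O(n³)
Lance–Williams implementation for every n ≤ 8 and all four linkages. Ties in
merge candidates are broken toward the smallest node indices. The leaf order
places the earlier-created subtree first at every merge — deterministic, with
no optimal-leaf-ordering rotation. If every profile column is constant the
levels are equidistant at 0; the axis keeps its input order with a warning.
Dendrograms export to Newick for inspection.

## Glyph encoding

* **Size** maps value → **area** linearly (not radius: perceived magnitude
  should track the value), clamped to `size_range` (default 10–220 pt²) over
  `size_domain` (default: observed range). A degenerate domain puts all dots
  mid-range with a warning.
* **Color**: quantitative values interpolate piecewise-linearly in RGB
  between gradient anchors. If the factor contains negatives (z-scores), the
  default is blue–white–red over a domain symmetric around 0, so 0 hits the
  middle anchor exactly; otherwise white→blue over the observed range.
  Qualitative levels cycle a discrete palette (tab10) in level order, with a
  warning when the palette wraps. Missing → neutral grey.
* **Text**: quantitative values default to round-half-away-from-zero
  integers (percentage-label style; a printf format overrides); qualitative
  values verbatim; missing → empty. Text is centered in the dot with
  black/white chosen by fill luminance.
* **Shape**: qualitative levels map injectively onto an ordered symbol list
  (circle, square, triangle, diamond, star; error when levels outnumber
  symbols). For quantitative factors the *fraction pie* glyph fills a
  circular sector of angle 2π·fraction (clockwise from 12 o'clock) over a
  light full-circle outline — the fraction is the value rescaled to the
  shape domain, clamped to [0, 1]; the alternative `symbol_series` bins the
  value into ≤5 equal-width bins mapped onto the symbol list. The pie
  geometry is this package's concretization of a quantitative shape channel;
  it is chosen because a filled circle fraction reads directly as a
  percentage. Symbols are drawn at equal area to the equivalent circle.

## Rendering

Scenes render through matplotlib onto a plain `Figure` (column dendrogram
above, row dendrogram left, each in a band of 15% of the grid extent;
legends stacked in a right-hand margin in channel order size, color, shape,
text; cell size 30 pt and 8 pt fonts by default). SVG output is
byte-deterministic: a fixed `svg.hashsalt` replaces random element ids, the
creation date is stripped, and elements are emitted in a fixed order. Each
dot's primary patch carries the group id `glyph-<x>-<y>`, so the number of
drawn dots can be audited from the SVG text. PNG rasterizes the same figure
at the requested dpi. `as_plot_object` returns an independently built
`Figure` per call; saved unmodified it is identical to `render`'s output.

## Synthetic data

`synthetic_expression` draws counts from a negative binomial with baseline
mean 1 and dispersion 0.5 (variance μ + 0.5μ², i.e. NB size r = 2) — enough
sparsity that percent-expressing is informative but not degenerate. A
fraction `marker_rate` (default 0.2) of genes are markers; each is assigned a
cluster (round-robin) and its mean is multiplied by `effect` (default 5)
there. Defaults of 30 genes × 300 cells × 4 clusters keep every pipeline
stage exercised at interactive problem sizes. The generator emulates the
block structure that makes marker dot plots legible; it does **not** emulate
library-size variation, dropout beyond NB sparsity, ADT noise models, real
dataset marginals, doublets or batch effects — so passing tests demonstrate
correctness of the summarization and display machinery, not robustness to
real-data artefacts. `synthetic_dot_table` draws quantitative factors uniform
on [0, 100] (the scale of percentages) and qualitative factors from 2–4
labeled levels, on a complete grid. Everything is reproducible from the seed.

## Numerical choices and limitations

* Standardization uses the population sd (ddof = 0); PCA eigenvalues use the
  sample convention σ²/(n−1), FAMD the population convention σ²/n (the pair
  that makes the inertia identities above exact).
* Eigenvalues are clamped at 0 below 1e-12; constant columns are dropped at
  a 1e-12 relative tolerance.
* Missing tokens on read: empty string, `NA`, `NaN` (case-insensitive);
  written back as `NA`.
* The split-column layout requires each x level to contain the pair
  separator exactly once; shared per-interaction factors are carried on both
  sides by default (configurable to one side).
* No significance testing of clusters, no bootstrap support, no optimal leaf
  ordering, no interactive viewer; huge-table streaming and xlsx input are
  out of scope.
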