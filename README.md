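# flexdot

A universal, multifaceted dot-plot engine for transcriptomics (and any other
two-factor summary data).

Dot plots generalize heatmaps: each cell of an x × y category grid becomes a
dot, and up to four variables are displayed at once through the dot's
**size**, **color**, **text** and **shape**. The layout is ubiquitous in
single-cell RNA-seq, where a dot shows, for one gene in one cell cluster, the
percentage of expressing cells (Pct.exp, size and/or text) and the average
scaled expression (color) — and shape can carry a fourth variable such as a
canonical-marker flag, a CNV state, or a second modality's percentage.

flexdot takes any long-format delimited table — column 1 the x factor,
column 2 the y factor, columns 3–6 the display factors, each quantitative or
qualitative — and:

* validates and types the table (kinds inferred or declared; size accepts
  only quantitative factors);
* optionally re-orders each axis by hierarchical clustering, preceded by a
  type-matched factor analysis of the levels' wide profiles: PCA for
  quantitative columns, multiple correspondence analysis (MCA) for
  qualitative ones, factor analysis of mixed data (FAMD) for a mixture;
* renders a byte-deterministic SVG (or PNG) with dendrograms and per-channel
  legends, or returns a matplotlib `Figure` you can extend with custom layers;
* summarizes an expression matrix + cluster labels into the canonical
  (gene, cluster) dot table, for one or two modalities (e.g. RNA and ADT);
* includes a quantitative *shape* encoding: a value mapped to a pie-sector
  glyph (fraction of a circle), a natural reading for percentages, or a
  binned ordered symbol series.

## The statistics underneath

For gene *g* and cluster *k* with cells *C_k*:

* `Pct.exp(g,k) = 100 · #{c ∈ C_k : x_gc > t} / |C_k|` (threshold *t* = 0 by
  default);
* `Scaled.expr(g,k) = mean_{c∈C_k} z_gc` where `z_g = (x_g − mean(x_g)) / sd(x_g)`
  is the gene's z-score across **all** cells (sample sd). The cluster-size
  weighted mean of `Scaled.expr(g,·)` is therefore exactly 0 for every gene.

Axis ordering embeds each level's profile and clusters on Euclidean
distances (ward/complete/average/single linkage). PCA eigenvalues are
σ²/(n−1) of the centered (optionally unit-scaled) profile matrix; MCA is the
correspondence analysis of the one-hot indicator matrix (total inertia
(J−Q)/Q for J categories over Q variables); FAMD standardizes quantitative
columns and weights each indicator by 1/√(category proportion), so total
inertia is (#quantitative) + (J−Q) and the all-quantitative case reduces
exactly to scaled PCA.

## Worked example

```sh
flexdot fixtures --out-dir fx  --n-genes 15 --n-cells 150 --n-clusters 3 --seed 21
flexdot fixtures --out-dir fx2 --n-genes 15 --n-cells 150 --n-clusters 3 --seed 22
flexdot summarize --mtx fx/matrix.mtx --genes fx/genes.txt --cells fx/cells.txt \
    --clusters fx/clusters.csv --markers fx/markers.csv \
    --mtx2 fx2/matrix.mtx --out table.csv
flexdot plot --input table.csv --size-col Pct.exp --color-col Scaled.expr \
    --text-col Pct.exp.RNA --shape-col Marker --row-dend --col-dend --out fig.svg
```

`summarize` prints `table.csv`; its first rows look like

```
Cluster,Gene,Pct.exp,Scaled.expr,Pct.exp.RNA,Marker
cl0,g000,86.0,0.8740829217669841,44.0,marker
cl1,g000,58.0,-0.45550800148420295,54.0,marker
```

— one row per (gene, cluster): `g000` is a marker gene whose high-expression
cluster is `cl0` (86% of cells expressing, average scaled expression 0.87
standard deviations above the gene's overall mean, versus 58% and −0.46 in
`cl1`), alongside the second modality's percentage and the marker flag.
`plot` prints `fig.svg`: a 3-cluster × 15-gene grid with one dot per
combination (45 glyph groups in the SVG), dot size/text giving the two
percentages, color the scaled expression (blue–white–red, centered at 0),
shape distinguishing marker genes, and dendrograms re-ordering both axes.

The same pipeline is available as library calls (`parse_table`,
`build_dot_table`, `order_axis`, `compose`, `render`, `as_plot_object`);
`as_plot_object` returns a matplotlib `Figure` for further annotation.

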