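"""Per-cluster marker summarization for scRNA-seq dot plots.

Builds the classic marker-panel dot-table from a genes × cells expression
matrix and a cell → cluster assignment:

* ``Pct.exp`` — the percentage of cells in a cluster whose expression of a
  gene exceeds a threshold (default: strictly greater than 0);
* ``Scaled.expr`` — the gene's expression z-scored across *all* cells
  ((x − mean)/sd, sample sd), then averaged within each cluster. By
  construction the cluster-size-weighted mean of these averages is 0 for
  every gene.

Extra per-gene or per-(gene, cluster) annotations (a second modality's
Pct.exp, canonical-marker flags, CNV status, ...) are attached as additional
display factors. No normalization happens here: values are summarized as
given, so callers pre-normalize if they want log-space summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .errors import FactorLookupError, ValidationError
from .table import DotTable, FactorKind, infer_factor_kind

PCT_COL = "Pct.exp"
EXPR_COL = "Scaled.expr"


@dataclass
class ExpressionMatrix:
    """Dense genes × cells matrix of non-negative finite expression values."""

    values: np.ndarray
    gene_names: list[str]
    cell_names: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("expression matrix must be 2-dimensional")
        n_genes, n_cells = self.values.shape
        if n_genes != len(self.gene_names) or n_cells != len(self.cell_names):
            raise ValidationError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_names)} gene names / {len(self.cell_names)} cell names"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if (self.values < 0).any():
            raise ValidationError("expression values must be non-negative")
        self._gene_index = {g: i for i, g in enumerate(self.gene_names)}

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise FactorLookupError(f"unknown gene {gene!r}") from None


@dataclass
class ClusterAssignment:
    """One cluster label per cell; ``cluster_levels`` fixes display order."""

    labels: Mapping[str, str]
    cluster_levels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = dict(self.labels)
        if not self.cluster_levels:
            seen: dict[str, None] = {}
            for lab in self.labels.values():
                seen.setdefault(lab, None)
            self.cluster_levels = list(seen)
        extra = set(self.labels.values()) - set(self.cluster_levels)
        if extra:
            raise ValidationError(f"labels not in cluster_levels: {sorted(extra)}")

    def mask_for(self, cluster: str, cell_names: Sequence[str]) -> np.ndarray:
        if cluster not in self.cluster_levels:
            raise FactorLookupError(f"unknown cluster {cluster!r}")
        missing = [c for c in cell_names if c not in self.labels]
        if missing:
            raise ValidationError(
                f"{len(missing)} cells lack a cluster label (first: {missing[0]!r})"
            )
        return np.array([self.labels[c] == cluster for c in cell_names], dtype=bool)


def pct_expressed(
    m: ExpressionMatrix,
    gene: str,
    cluster: str,
    a: ClusterAssignment,
    threshold: float = 0.0,
) -> float:
    """Percentage (0-100) of the cluster's cells with expression > threshold."""
    row = m.gene_row(gene)
    mask = a.mask_for(cluster, m.cell_names)
    n = int(mask.sum())
    if n == 0:
        raise ValidationError(f"cluster {cluster!r} contains no cells")
    return 100.0 * float((row[mask] > threshold).sum()) / n


def mean_scaled_expression(
    m: ExpressionMatrix, gene: str, a: ClusterAssignment
) -> dict[str, float]:
    """Average per-gene z-score within each cluster.

    The gene is z-scored across all cells ((x − mean)/sd, sd with the n−1
    denominator) and the z-scores are averaged per cluster. A zero-variance
    gene yields 0 for every cluster, with a warning.
    """
    row = m.gene_row(gene)
    if row.size < 2:
        raise ValidationError("mean_scaled_expression needs at least 2 cells")
    sd = float(np.std(row, ddof=1))
    if sd == 0.0:
        warnings.warn(
            f"gene {gene!r} has zero variance; scaled expression set to 0",
            UserWarning,
            stacklevel=2,
        )
        return {c: 0.0 for c in a.cluster_levels}
    z = (row - row.mean()) / sd
    out: dict[str, float] = {}
    for cluster in a.cluster_levels:
        mask = a.mask_for(cluster, m.cell_names)
        if not mask.any():
            raise ValidationError(f"cluster {cluster!r} contains no cells")
        out[cluster] = float(z[mask].mean())
    return out


def build_dot_table(
    m: ExpressionMatrix,
    a: ClusterAssignment,
    genes: Sequence[str],
    extra: Mapping[str, Mapping] | None = None,
    extra_kinds: Mapping[str, FactorKind] | None = None,
    threshold: float = 0.0,
) -> DotTable:
    """Assemble the marker dot-table: one row per (gene, cluster).

    Clusters go on the x axis, genes on the y axis (the usual marker-panel
    layout). ``extra`` maps a factor name to either a per-gene mapping
    (broadcast across that gene's rows) or a per-(gene, cluster) mapping keyed
    by tuples. Kinds of extra factors are inferred unless given in
    ``extra_kinds``.
    """
    unknown = [g for g in genes if g not in m._gene_index]
    if unknown:
        raise FactorLookupError(f"unknown genes: {unknown}")
    extra = dict(extra or {})
    if len(extra) + 2 > 4:
        raise ValidationError(
            f"{len(extra)} extra factors plus {PCT_COL}/{EXPR_COL} exceed 4 channels"
        )
    rows: list[dict] = []
    for gene in genes:
        scaled = mean_scaled_expression(m, gene, a)
        for cluster in a.cluster_levels:
            rec = {
                "Cluster": cluster,
                "Gene": gene,
                PCT_COL: pct_expressed(m, gene, cluster, a, threshold=threshold),
                EXPR_COL: scaled[cluster],
            }
            for name, mapping in extra.items():
                if (gene, cluster) in mapping:
                    rec[name] = mapping[(gene, cluster)]
                else:
                    rec[name] = mapping.get(gene, np.nan)
            rows.append(rec)
    data = pd.DataFrame(rows)
    kinds: dict[str, FactorKind] = {
        PCT_COL: FactorKind.QUANTITATIVE,
        EXPR_COL: FactorKind.QUANTITATIVE,
    }
    declared = dict(extra_kinds or {})
    for name in extra:
        if name in declared:
            kinds[name] = FactorKind(declared[name])
        else:
            raw = ["" if pd.isna(v) else str(v) for v in data[name]]
            kinds[name] = infer_factor_kind(raw)
        if kinds[name] is FactorKind.QUANTITATIVE:
            data[name] = pd.to_numeric(data[name], errors="raise").astype(float)
        else:
            data[name] = data[name].astype(object)
    return DotTable(
        x_name="Cluster",
        y_name="Gene",
        data=data,
        factor_kinds=kinds,
        x_levels=list(a.cluster_levels),
        y_levels=list(genes),
    )


# -- file readers ----------------------------------------------------------


def load_mtx(
    matrix_path: str | Path, genes_path: str | Path, cells_path: str | Path
) -> ExpressionMatrix:
    """Load a MatrixMarket triplet plus one-column gene / cell name files."""
    mat = scipy.io.mmread(str(matrix_path))
    if scipy.sparse.issparse(mat):
        mat = mat.toarray()
    genes = Path(genes_path).read_text(encoding="utf-8").split()
    cells = Path(cells_path).read_text(encoding="utf-8").split()
    return ExpressionMatrix(np.asarray(mat, dtype=float), genes, cells)


def load_dense_csv(path: str | Path) -> ExpressionMatrix:
    """Load a dense CSV with gene rows × cell columns (first column = gene)."""
    df = pd.read_csv(path, index_col=0)
    return ExpressionMatrix(
        df.to_numpy(dtype=float), [str(g) for g in df.index], [str(c) for c in df.columns]
    )


def load_clusters(path: str | Path) -> ClusterAssignment:
    """Load a two-column (cell, cluster) CSV; cluster order is first appearance."""
    df = pd.read_csv(path, dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: cluster file needs columns (cell, cluster)")
    cells, labels = df.iloc[:, 0], df.iloc[:, 1]
    return ClusterAssignment(labels=dict(zip(cells, labels)))
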