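"""Synthetic inputs with the structure the dot-plot engine assumes.

Two generators cover both entry points of the pipeline:

* :func:`synthetic_expression` — a genes × cells count matrix with
  cluster-specific marker blocks: counts are negative-binomial around a
  baseline mean of 1 (dispersion 0.5, i.e. NB size r = 2), and each marker
  gene's mean is multiplied by ``effect`` inside its assigned cluster. This
  emulates the marker-panel block structure of per-cluster scRNA-seq
  summaries at test scale; it makes no attempt to match real dataset
  marginals, ADT noise, or doublet/ambient artefacts.
* :func:`synthetic_dot_table` — a complete-grid long-format table with 1-4
  quantitative (uniform on [0, 100], the scale of percentages) and/or
  qualitative (2-4 labeled levels) display factors.

Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .scrna import ClusterAssignment, ExpressionMatrix
from .table import DotTable, FactorKind


@dataclass
class FixtureParams:
    """Parameters of the synthetic expression generator."""

    n_genes: int = 30
    n_cells: int = 300
    n_clusters: int = 4
    marker_rate: float = 0.2
    effect: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_genes, self.n_cells, self.n_clusters) < 1:
            raise ValidationError("n_genes, n_cells, n_clusters must be positive")
        if self.n_clusters > self.n_cells:
            raise ValidationError("n_clusters cannot exceed n_cells")
        if not (0.0 <= self.marker_rate <= 1.0):
            raise ValidationError("marker_rate must be in [0, 1]")
        if not self.effect > 1.0:
            raise ValidationError("effect must be > 1")


#: Baseline NB mean and dispersion (size r = 1/dispersion).
_BASE_MEAN = 1.0
_DISPERSION = 0.5


def synthetic_expression(
    p: FixtureParams,
) -> tuple[ExpressionMatrix, ClusterAssignment, pd.DataFrame]:
    """Generate (matrix, clusters, truth) with marker-gene block structure.

    ``truth`` has columns (gene, cluster) listing each marker gene and the
    cluster in which its mean is inflated by ``p.effect``.
    """
    rng = np.random.default_rng(p.seed)
    genes = [f"g{i:03d}" for i in range(p.n_genes)]
    cells = [f"c{i:04d}" for i in range(p.n_cells)]
    clusters = [f"cl{k}" for k in range(p.n_clusters)]

    # balanced-ish random assignment; every cluster gets at least one cell
    assign = np.array([clusters[i % p.n_clusters] for i in range(p.n_cells)])
    rng.shuffle(assign)

    n_markers = int(round(p.marker_rate * p.n_genes))
    marker_idx = rng.choice(p.n_genes, size=n_markers, replace=False)
    marker_cluster = {
        int(g): clusters[i % p.n_clusters] for i, g in enumerate(sorted(marker_idx))
    }

    means = np.full((p.n_genes, p.n_cells), _BASE_MEAN)
    for g, cl in marker_cluster.items():
        means[g, assign == cl] *= p.effect

    r = 1.0 / _DISPERSION  # NB size; var = mu + dispersion * mu^2
    prob = r / (r + means)
    values = rng.negative_binomial(r, prob).astype(float)

    matrix = ExpressionMatrix(values, genes, cells)
    assignment = ClusterAssignment(
        labels=dict(zip(cells, assign)), cluster_levels=clusters
    )
    truth = pd.DataFrame(
        [(genes[g], cl) for g, cl in sorted(marker_cluster.items())],
        columns=["gene", "cluster"],
    )
    return matrix, assignment, truth


def synthetic_dot_table(
    n_x: int, n_y: int, n_quant: int, n_qual: int, seed: int = 0
) -> DotTable:
    """Generate a complete-grid dot table with mixed-type display factors."""
    if min(n_x, n_y) < 1:
        raise ValidationError("n_x and n_y must be positive")
    total = n_quant + n_qual
    if not (1 <= total <= 4):
        raise ValidationError(
            f"need between 1 and 4 display factors, got {total}"
        )
    rng = np.random.default_rng(seed)
    x_levels = [f"x{i}" for i in range(n_x)]
    y_levels = [f"y{j}" for j in range(n_y)]
    n_rows = n_x * n_y
    data = pd.DataFrame(
        {
            "xfac": [x for x in x_levels for _ in y_levels],
            "yfac": y_levels * n_x,
        }
    )
    kinds: dict[str, FactorKind] = {}
    for q in range(n_quant):
        name = f"quant{q + 1}"
        data[name] = rng.uniform(0.0, 100.0, size=n_rows)
        kinds[name] = FactorKind.QUANTITATIVE
    for q in range(n_qual):
        name = f"qual{q + 1}"
        n_levels = 2 + q % 3  # 2..4 labeled levels per factor
        labels = [f"{name}_lv{k}" for k in range(n_levels)]
        data[name] = rng.choice(labels, size=n_rows)
        kinds[name] = FactorKind.QUALITATIVE
    return DotTable(
        x_name="xfac",
        y_name="yfac",
        data=data,
        factor_kinds=kinds,
        x_levels=x_levels,
        y_levels=y_levels,
    )
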