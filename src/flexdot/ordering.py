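"""Type-dispatched factor analysis and hierarchical axis ordering.

Before clustering the levels of a plot axis, the wide profile matrix of the
chosen display factors is reduced by the factor analysis matching the column
types: principal component analysis for all-quantitative columns, multiple
correspondence analysis (MCA) for all-qualitative columns, and factor analysis
of mixed data (FAMD) when both are present. Euclidean distances on the
resulting row coordinates feed agglomerative clustering, whose tree supplies
the dendrogram drawn next to the plot and the leaf order that re-orders the
axis.

Conventions
-----------
* PCA: columns centered (and divided by their population sd when ``scale``);
  eigenvalues are squared singular values / (n − 1); coordinates are row
  principal coordinates U·Σ.
* MCA: correspondence analysis of the one-hot indicator matrix Z.  With
  P = Z/(nQ), row masses r = 1/n and column masses c, the SVD of
  S = Dr^(−1/2) (P − r cᵀ) Dc^(−1/2) yields eigenvalues σ² (the centering
  removes the trivial dimension, which appears as a zero singular value) and
  mass-standardized row principal coordinates √n·U·Σ.  The eigenvalue sum is
  (J − Q)/Q for J categories over Q columns.
* FAMD: quantitative columns standardized to mean 0, population sd 1; each
  qualitative column one-hot expanded, each indicator divided by the square
  root of its category proportion and centered; unscaled PCA of the
  concatenation with population-convention eigenvalues σ²/n, so total inertia
  is (#quantitative columns) + (J − Q).  With only quantitative columns the
  coordinates coincide with scaled PCA; with only qualitative columns the
  eigenvalues are Q times the MCA eigenvalues (identical inertia proportions).
* Component signs follow the largest-|loading|-positive convention so
  coordinates are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .errors import ValidationError
from .table import DotTable, FactorKind, complete_grid, pivot_wide

LINKAGES = ("ward", "complete", "average", "single")

_EPS = 1e-12


@dataclass
class Embedding:
    """Row coordinates and eigenvalues from PCA, MCA or FAMD."""

    row_labels: list[str]
    coordinates: np.ndarray  # rows × components
    eigenvalues: np.ndarray  # non-increasing, >= 0
    method: str  # "pca" | "mca" | "famd"

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        ev = np.asarray(self.eigenvalues, dtype=float)
        if (ev < -_EPS).any():
            raise ValidationError(f"negative eigenvalue {ev.min()} in {self.method}")
        self.eigenvalues = np.maximum(ev, 0.0)
        if np.any(np.diff(self.eigenvalues) > _EPS):
            raise ValidationError("eigenvalues must be non-increasing")
        if self.coordinates.shape != (len(self.row_labels), len(self.eigenvalues)):
            raise ValidationError(
                f"coordinate shape {self.coordinates.shape} inconsistent with "
                f"{len(self.row_labels)} rows × {len(self.eigenvalues)} eigenvalues"
            )


@dataclass
class Dendrogram:
    """Agglomerative merge tree for one plot axis.

    Nodes 0..n−1 are leaves (in ``labels`` order); merge i creates node n+i.
    ``merges`` lists (node_a, node_b, height) with node_a < node_b, heights
    non-decreasing. ``leaf_order`` is the axis permutation obtained by placing
    the earlier-created subtree first at every merge.
    """

    labels: list[str]
    merges: list[tuple[int, int, float]]
    leaf_order: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if len(self.merges) != max(n - 1, 0):
            raise ValidationError(f"{n} leaves require {n - 1} merges")
        heights = [h for _, _, h in self.merges]
        if any(b < a - 1e-9 for a, b in zip(heights, heights[1:])):
            raise ValidationError("merge heights must be non-decreasing")
        if sorted(self.leaf_order) != sorted(self.labels):
            raise ValidationError("leaf_order is not a permutation of labels")

    @property
    def heights(self) -> list[float]:
        return [h for _, _, h in self.merges]

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height − child height."""
        n = len(self.labels)
        node_h = {i: 0.0 for i in range(n)}
        for k, (_, _, h) in enumerate(self.merges):
            node_h[n + k] = h

        def fmt(node: int, parent_h: float) -> str:
            bl = max(parent_h - node_h[node], 0.0)
            if node < n:
                return f"{self.labels[node]}:{bl:.6g}"
            a, b, h = self.merges[node - n]
            return f"({fmt(a, h)},{fmt(b, h)}):{bl:.6g}"

        if n == 1:
            return f"{self.labels[0]};"
        root = n + len(self.merges) - 1
        a, b, h = self.merges[-1]
        return f"({fmt(a, h)},{fmt(b, h)});"


# -- sign convention -------------------------------------------------------


def _fix_signs(u: np.ndarray, v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each component so its largest-magnitude loading is positive."""
    u = u.copy()
    v = v.copy()
    for k in range(v.shape[1]):
        col = v[:, k]
        if col.size == 0:
            continue
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            v[:, k] = -col
            u[:, k] = -u[:, k]
    return u, v


def _drop_constant_columns(x: np.ndarray, context: str) -> np.ndarray:
    # tolerance relative to column magnitude: mean-imputed columns are
    # constant only up to floating-point rounding
    sd = x.std(axis=0, ddof=0)
    scale = np.maximum(np.abs(x).max(axis=0, initial=0.0), 1.0)
    keep = sd > 1e-12 * scale
    if not keep.all():
        warnings.warn(
            f"{context}: dropped {int((~keep).sum())} zero-variance column(s)",
            UserWarning,
            stacklevel=3,
        )
    return x[:, keep]


# -- the three factor analyses --------------------------------------------


def pca(
    x: np.ndarray | pd.DataFrame,
    scale: bool = True,
    row_labels: Sequence[str] | None = None,
) -> Embedding:
    """Principal component analysis of a quantitative matrix.

    Zero-variance columns are dropped with a warning; with ``scale`` the
    remaining columns are divided by their population sd after centering.
    """
    if isinstance(x, pd.DataFrame):
        if row_labels is None:
            row_labels = [str(i) for i in x.index]
        x = x.to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValidationError("pca needs a 2-D matrix with at least 2 rows")
    if np.isnan(x).any():
        raise ValidationError("pca input contains missing values; impute first")
    labels = list(row_labels) if row_labels is not None else [
        str(i) for i in range(x.shape[0])
    ]
    n = x.shape[0]
    proc = _drop_constant_columns(x, "pca")
    if proc.shape[1] == 0:
        raise ValidationError("pca: every column has zero variance")
    proc = proc - proc.mean(axis=0)
    if scale:
        proc = proc / proc.std(axis=0, ddof=0)
    u, s, vt = np.linalg.svd(proc, full_matrices=False)
    u, v = _fix_signs(u, vt.T)
    return Embedding(
        row_labels=labels,
        coordinates=u * s,
        eigenvalues=s**2 / (n - 1),
        method="pca",
    )


def _indicator(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, int]:
    """One-hot expand qualitative columns; returns (Z, proportions, Q_retained)."""
    blocks: list[np.ndarray] = []
    retained = 0
    for col in df.columns:
        vals = df[col].astype(str)
        cats = pd.unique(vals)
        if len(cats) < 2:
            warnings.warn(
                f"qualitative column {col!r} has a single category and "
                f"contributes no inertia; dropped",
                UserWarning,
                stacklevel=3,
            )
            continue
        retained += 1
        blocks.append((vals.to_numpy()[:, None] == np.array(cats)[None, :]).astype(float))
    if retained == 0:
        raise ValidationError("every qualitative column has a single category")
    z = np.hstack(blocks)
    return z, z.mean(axis=0), retained


def mca(
    x: pd.DataFrame, row_labels: Sequence[str] | None = None
) -> Embedding:
    """Multiple correspondence analysis of qualitative columns."""
    df = pd.DataFrame(x)
    if df.shape[0] < 2:
        raise ValidationError("mca needs at least 2 rows")
    labels = list(row_labels) if row_labels is not None else [
        str(i) for i in df.index
    ]
    n = df.shape[0]
    z, p, q = _indicator(df)
    # S = Dr^{-1/2} (P - r c^T) Dc^{-1/2} with P = Z/(nQ), r = 1/n, c = p/Q
    s_mat = (z - p[None, :]) / np.sqrt(p)[None, :] / np.sqrt(n * q)
    u, s, vt = np.linalg.svd(s_mat, full_matrices=False)
    u, v = _fix_signs(u, vt.T)
    return Embedding(
        row_labels=labels,
        coordinates=np.sqrt(n) * u * s,
        eigenvalues=s**2,
        method="mca",
    )


def famd(
    x: pd.DataFrame,
    kinds: Mapping[str, FactorKind],
    row_labels: Sequence[str] | None = None,
) -> Embedding:
    """Factor analysis of mixed quantitative and qualitative columns."""
    df = pd.DataFrame(x)
    if df.shape[0] < 2 or df.shape[1] < 1:
        raise ValidationError("famd needs at least 2 rows and 1 column")
    labels = list(row_labels) if row_labels is not None else [
        str(i) for i in df.index
    ]
    n = df.shape[0]
    quant_cols = [c for c in df.columns if FactorKind(kinds[c]) is FactorKind.QUANTITATIVE]
    qual_cols = [c for c in df.columns if c not in quant_cols]
    blocks: list[np.ndarray] = []
    if quant_cols:
        qx = df[quant_cols].to_numpy(dtype=float)
        if np.isnan(qx).any():
            raise ValidationError("famd input contains missing values; impute first")
        qx = _drop_constant_columns(qx, "famd")
        if qx.shape[1]:
            qx = qx - qx.mean(axis=0)
            blocks.append(qx / qx.std(axis=0, ddof=0))
    if qual_cols:
        z, p, _ = _indicator(df[qual_cols])
        w = z / np.sqrt(p)[None, :]
        blocks.append(w - w.mean(axis=0))
    if not blocks:
        raise ValidationError("famd: no informative columns remain")
    proc = np.hstack(blocks)
    u, s, vt = np.linalg.svd(proc, full_matrices=False)
    u, v = _fix_signs(u, vt.T)
    return Embedding(
        row_labels=labels,
        coordinates=u * s,
        eigenvalues=s**2 / n,
        method="famd",
    )


# -- agglomerative ordering ------------------------------------------------


def _leaf_order(n: int, merges: list[tuple[int, int, float]]) -> list[int]:
    """Depth-first order placing the earlier-created (smaller-id) child first."""

    def leaves(node: int) -> list[int]:
        if node < n:
            return [node]
        a, b, _ = merges[node - n]
        return leaves(a) + leaves(b)

    if n == 1:
        return [0]
    return leaves(n + len(merges) - 1)


def dendrogram_from_coordinates(
    coords: np.ndarray, labels: Sequence[str], linkage: str = "ward"
) -> Dendrogram:
    """Agglomerate rows on Euclidean distances; tie-break by smallest node ids."""
    if linkage not in LINKAGES:
        raise ValidationError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    labels = list(labels)
    n = len(labels)
    if n == 1:
        return Dendrogram(labels=labels, merges=[], leaf_order=labels)
    zmat = sch.linkage(np.asarray(coords, dtype=float), method=linkage)
    merges = [
        (int(min(a, b)), int(max(a, b)), float(h)) for a, b, h, _ in zmat
    ]
    order = _leaf_order(n, merges)
    return Dendrogram(labels=labels, merges=merges, leaf_order=[labels[i] for i in order])


def embed_axis_profiles(
    table: DotTable, axis: str = "x", factors: Sequence[str] | None = None
) -> Embedding:
    """Pivot the chosen factors wide along one axis and embed the profiles.

    Dispatch: all-quantitative → PCA (scaled), all-qualitative → MCA, mixed →
    FAMD. Default factor choice: all quantitative display factors if any
    exist, else all factors. Missing values (from grid completion) are
    mean-imputed (quantitative) or given their own "missing" category
    (qualitative), with a warning.
    """
    table = complete_grid(table)
    if factors is None or len(factors) == 0:
        quant = [
            f
            for f in table.factor_names
            if table.factor_kinds[f] is FactorKind.QUANTITATIVE
        ]
        factors = quant if quant else table.factor_names
    for f in factors:
        table.kind_of(f)
    levels = table.x_levels if axis == "x" else table.y_levels
    kinds_present = {table.factor_kinds[f] for f in factors}

    quant_blocks: list[np.ndarray] = []
    qual_frames: list[pd.DataFrame] = []
    col_kinds: dict[str, FactorKind] = {}
    mixed = pd.DataFrame(index=levels)
    for f in factors:
        wide = pivot_wide(table, f, axis=axis)
        if table.factor_kinds[f] is FactorKind.QUANTITATIVE:
            mat = wide.to_numpy(dtype=float)
            if np.isnan(mat).any():
                warnings.warn(
                    f"factor {f!r}: mean-imputed missing values before embedding",
                    UserWarning,
                    stacklevel=2,
                )
                col_mean = np.nanmean(mat, axis=0)
                col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
                mat = np.where(np.isnan(mat), col_mean[None, :], mat)
            for j, other in enumerate(wide.columns):
                name = f"{f}|{other}"
                mixed[name] = mat[:, j]
                col_kinds[name] = FactorKind.QUANTITATIVE
        else:
            filled = wide.astype(object)
            if filled.isna().any().any():
                warnings.warn(
                    f"factor {f!r}: missing labels mapped to a 'missing' category",
                    UserWarning,
                    stacklevel=2,
                )
                filled = filled.fillna("missing")
            for other in filled.columns:
                name = f"{f}|{other}"
                mixed[name] = filled[other].astype(str).to_numpy()
                col_kinds[name] = FactorKind.QUALITATIVE
    if kinds_present == {FactorKind.QUANTITATIVE}:
        return pca(mixed.to_numpy(dtype=float), scale=True, row_labels=levels)
    if kinds_present == {FactorKind.QUALITATIVE}:
        return mca(mixed, row_labels=levels)
    return famd(mixed, kinds=col_kinds, row_labels=levels)


def order_axis(
    table: DotTable,
    axis: str = "x",
    factors: Sequence[str] | None = None,
    linkage: str = "ward",
    n_components: int | None = None,
) -> Dendrogram:
    """Cluster one axis's levels and return the dendrogram that re-orders it.

    The levels' wide factor profiles are embedded (:func:`embed_axis_profiles`),
    Euclidean distances are taken on the first ``n_components`` coordinates
    (default: all), and the chosen linkage agglomerates them. A single-level
    axis yields a degenerate dendrogram with no merges, with a warning.
    """
    table = complete_grid(table)
    levels = table.x_levels if axis == "x" else table.y_levels
    if len(levels) == 1:
        warnings.warn(
            f"axis {axis!r} has a single level; degenerate dendrogram",
            UserWarning,
            stacklevel=2,
        )
        return Dendrogram(labels=list(levels), merges=[], leaf_order=list(levels))
    try:
        emb = embed_axis_profiles(table, axis=axis, factors=factors)
        coords = emb.coordinates
        if n_components is not None:
            coords = coords[:, : max(1, n_components)]
    except ValidationError:
        # all profiles identical (every column zero-variance): any order works
        warnings.warn(
            f"axis {axis!r}: level profiles carry no variance; arbitrary order",
            UserWarning,
            stacklevel=2,
        )
        coords = np.zeros((len(levels), 1))
    return dendrogram_from_coordinates(coords, levels, linkage=linkage)
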