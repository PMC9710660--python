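"""Independent brute-force oracles used to check the implementation.

These deliberately use naive explicit-loop algorithms (O(n^3) agglomeration,
per-cell z-scoring loops, elementwise correspondence-analysis setup) so they
share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np


def naive_agglomerate(points: np.ndarray, method: str):
    """O(n^3) Lance-Williams agglomerative clustering on Euclidean distances.

    Returns merges [(node_a, node_b, height)] with scipy node numbering
    (leaves 0..n-1, merge k creates node n+k), node_a < node_b, ties broken
    by the smallest (node_a, node_b).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    dist: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = math.dist(pts[i], pts[j])
    size = {i: 1 for i in range(n)}
    active = set(range(n))
    merges = []
    for k in range(n - 1):
        best = min(
            ((d, a, b) for (a, b), d in dist.items()),
            key=lambda t: (t[0], t[1], t[2]),
        )
        h, a, b = best
        new = n + k
        merges.append((a, b, h))
        active -= {a, b}
        d_ab = dist.pop((a, b))
        for c in sorted(active):
            d_ac = dist.pop((min(a, c), max(a, c)))
            d_bc = dist.pop((min(b, c), max(b, c)))
            na, nb, nc = size[a], size[b], size[c]
            if method == "single":
                d_new = min(d_ac, d_bc)
            elif method == "complete":
                d_new = max(d_ac, d_bc)
            elif method == "average":
                d_new = (na * d_ac + nb * d_bc) / (na + nb)
            elif method == "ward":
                d_new = math.sqrt(
                    ((na + nc) * d_ac**2 + (nb + nc) * d_bc**2 - nc * d_ab**2)
                    / (na + nb + nc)
                )
            else:
                raise ValueError(method)
            dist[(c, new)] = d_new
        size[new] = size[a] + size[b]
        active.add(new)
    return merges


def merge_leafsets(n: int, merges) -> list[frozenset]:
    """Leaf set created by each merge, for topology comparison."""
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, _) in enumerate(merges):
        members[n + k] = members[a] | members[b]
        out.append(members[n + k])
    return out


def brute_pct_expressed(values, cell_clusters, gene_idx, cluster, threshold=0.0):
    """Loop-based percent-expressing for one gene in one cluster."""
    hits = total = 0
    for j, cl in enumerate(cell_clusters):
        if cl == cluster:
            total += 1
            if values[gene_idx][j] > threshold:
                hits += 1
    return 100.0 * hits / total


def brute_mean_scaled(values, cell_clusters, gene_idx, clusters):
    """Loop-based z-then-average per cluster (sample sd)."""
    row = [float(v) for v in values[gene_idx]]
    n = len(row)
    mean = sum(row) / n
    var = sum((x - mean) ** 2 for x in row) / (n - 1)
    sd = math.sqrt(var)
    if sd == 0:
        return {c: 0.0 for c in clusters}
    out = {}
    for c in clusters:
        zs = [(row[j] - mean) / sd for j in range(n) if cell_clusters[j] == c]
        out[c] = sum(zs) / len(zs)
    return out


def brute_mca_eigenvalues(columns: list[list[str]]) -> np.ndarray:
    """Correspondence analysis of the indicator matrix, built with loops."""
    n = len(columns[0])
    q = len(columns)
    cats = []
    for col in columns:
        seen = []
        for v in col:
            if v not in seen:
                seen.append(v)
        cats.append(seen)
    j_total = sum(len(c) for c in cats)
    z = np.zeros((n, j_total))
    offset = 0
    for col, cset in zip(columns, cats):
        for i, v in enumerate(col):
            z[i, offset + cset.index(v)] = 1.0
        offset += len(cset)
    p = z / (n * q)
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = np.zeros_like(p)
    for i in range(n):
        for j in range(j_total):
            s[i, j] = (p[i, j] - r[i] * c[j]) / math.sqrt(r[i] * c[j])
    sv = np.linalg.svd(s, compute_uv=False)
    return sv**2
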