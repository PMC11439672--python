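"""Independent brute-force reference implementations used only by tests.

These deliberately mirror the mathematical definitions with literal loops and
stay independent of the package's vectorized code paths.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import rankdata


def ssgsea_es_loop(expression: np.ndarray, gene_names, gene_set, alpha: float) -> float:
    """Literal double-loop ssGSEA enrichment score for one sample.

    Walks positions i = 1..N; at each position accumulates the weighted
    fraction of gene-set genes with rank <= i minus the unweighted fraction
    of out-of-set genes with rank <= i.
    """
    expression = np.asarray(expression, dtype=float)
    n = expression.size
    ranks = rankdata(-expression)  # rank 1 = highest, average ties
    in_set = np.array([g in set(gene_set) for g in gene_names])
    s = int(in_set.sum())
    weights = (n - ranks + 1.0) ** alpha
    denom_hit = sum(weights[j] for j in range(n) if in_set[j])
    es = 0.0
    for i in range(1, n + 1):
        p_hit = sum(weights[j] for j in range(n) if in_set[j] and ranks[j] <= i) / denom_hit
        p_miss = sum(1 for j in range(n) if not in_set[j] and ranks[j] <= i) / (n - s)
        es += p_hit - p_miss
    return es


def ssgsea_es_unweighted_loop(expression, gene_names, gene_set) -> float:
    """Separate alpha = 0 oracle: plain hit/miss ECDF difference walk."""
    expression = np.asarray(expression, dtype=float)
    n = expression.size
    ranks = rankdata(-expression)
    in_set = np.array([g in set(gene_set) for g in gene_names])
    s = int(in_set.sum())
    es = 0.0
    for i in range(1, n + 1):
        hits = sum(1 for j in range(n) if in_set[j] and ranks[j] <= i)
        misses = sum(1 for j in range(n) if not in_set[j] and ranks[j] <= i)
        es += hits / s - misses / (n - s)
    return es


def filter_survivors_loop(counts: np.ndarray, min_cells: int, min_genes: int):
    """Exhaustive per-row/per-column QC filter oracle (cells x genes counts)."""
    n_cells, n_genes = counts.shape
    gene_keep = []
    for j in range(n_genes):
        detected = sum(1 for i in range(n_cells) if counts[i, j] > 0)
        gene_keep.append(detected > min_cells)
    cell_keep = []
    for i in range(n_cells):
        detected = sum(
            1 for j in range(n_genes) if gene_keep[j] and counts[i, j] > 0
        )
        cell_keep.append(detected >= min_genes)
    return np.array(gene_keep), np.array(cell_keep)


def crosstab_loop(cell_types, is_ht):
    """Literal counting-loop cross-tabulation oracle."""
    table: dict[str, list[int]] = {}
    for ct, ht in zip(cell_types, is_ht):
        row = table.setdefault(str(ct), [0, 0])
        row[0 if ht else 1] += 1
    return table


def min_wcss_two_clusters(points: np.ndarray) -> float:
    """Exhaustive best within-cluster sum of squares over all 2-partitions."""
    n = len(points)
    best = np.inf
    for mask_bits in range(1, 2**n - 1):
        mask = np.array([(mask_bits >> i) & 1 for i in range(n)], dtype=bool)
        wcss = 0.0
        for side in (mask, ~mask):
            c = points[side].mean(axis=0)
            wcss += ((points[side] - c) ** 2).sum()
        best = min(best, wcss)
    return best
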