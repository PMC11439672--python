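"""Quality-control filters and log-normalization for raw scRNA-seq counts.

Filtering keeps genes detected (raw count > 0) in strictly more than
``min_cells_per_gene`` cells, then cells detecting at least
``min_genes_per_cell`` genes — the gene filter runs first. Normalization is
the global-scaling Log-Normalize transform

    normalized = ln(raw / cell_total * scale_factor + 1)

with cell totals taken from the (already filtered) raw counts; natural log,
so a raw zero maps to exactly zero and the transform is invariant to scaling
all counts of a cell.
"""

from __future__ import annotations

import anndata as ad
import numpy as np
import scanpy as sc
import scipy.sparse as sp

__all__ = ["EmptyResultError", "filter_counts", "lognormalize"]


class EmptyResultError(ValueError):
    """Raised when QC filtering removes every gene or every cell."""


def _detection(X) -> tuple[np.ndarray, np.ndarray]:
    """(cells detecting each gene, genes detected in each cell)."""
    if sp.issparse(X):
        pos = X > 0
        return np.asarray(pos.sum(axis=0)).ravel(), np.asarray(pos.sum(axis=1)).ravel()
    pos = X > 0
    return pos.sum(axis=0), pos.sum(axis=1)


def filter_counts(
    adata: ad.AnnData,
    min_cells_per_gene: int = 3,
    min_genes_per_cell: int = 200,
    per_sample: bool = False,
    sample_key: str = "sample",
) -> ad.AnnData:
    """Apply the QC filters, returning a new AnnData.

    ``per_sample=True`` applies the gene-detection rule within each sample and
    keeps a gene if it passes in at least one sample (the behaviour of
    per-sample QC followed by merging); the cell filter always runs on the
    merged matrix afterwards.
    """
    X = adata.X
    if sp.issparse(X):
        if (X.data < 0).any() or not np.allclose(X.data, np.round(X.data)):
            raise ValueError("counts must be non-negative integers")
    elif (np.asarray(X) < 0).any() or not np.allclose(X, np.round(X)):
        raise ValueError("counts must be non-negative integers")

    n_genes0, n_cells0 = adata.n_vars, adata.n_obs
    if per_sample:
        if sample_key not in adata.obs:
            raise KeyError(f"per-sample filtering needs obs[{sample_key!r}]")
        keep_gene = np.zeros(adata.n_vars, dtype=bool)
        for _, idx in adata.obs.groupby(sample_key, observed=True).indices.items():
            per_gene, _ = _detection(adata[idx].X)
            keep_gene |= per_gene > min_cells_per_gene
        out = adata[:, keep_gene].copy()
    else:
        out = adata.copy()
        # scanpy's min_cells is ">=", the rule here is strict ">"
        sc.pp.filter_genes(out, min_cells=min_cells_per_gene + 1)
    if out.n_vars == 0:
        raise EmptyResultError(
            f"gene filter (> {min_cells_per_gene} cells) removed all {n_genes0} genes"
        )
    sc.pp.filter_cells(out, min_genes=min_genes_per_cell)
    if out.n_obs == 0:
        raise EmptyResultError(
            f"cell filter (>= {min_genes_per_cell} genes) removed all {n_cells0} cells "
            f"({out.n_vars} genes had survived the gene filter)"
        )
    out.var.drop(columns=["n_cells"], errors="ignore", inplace=True)
    out.obs.drop(columns=["n_genes"], errors="ignore", inplace=True)
    return out


def lognormalize(adata: ad.AnnData, scale_factor: float = 1e4) -> ad.AnnData:
    """Log-Normalize counts; raw counts are preserved in ``layers['counts']``."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = np.asarray(adata.X.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = adata.obs_names[np.flatnonzero(totals <= 0)[:5]].tolist()
        raise ValueError(f"cells with zero total counts cannot be normalized: {bad}")
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    if sp.issparse(out.X):
        X = out.X.astype(np.float64).tocsr()
        scale = scale_factor / totals
        X = sp.diags(scale) @ X
        X.data = np.log1p(X.data)  # zeros stay exactly zero
        out.X = X
    else:
        X = np.asarray(out.X, dtype=np.float64)
        out.X = np.log1p(X / totals[:, None] * scale_factor)
    out.uns["scale_factor"] = float(scale_factor)
    return out
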