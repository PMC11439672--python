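"""Expression-based copy-number profiles relative to reference cells.

The profiler is a simplified expression-intensity CNV caller of the inferCNV
family: log-normalized expression is compared to the per-gene mean over a set
of reference (paratumor) cells, residuals are bounded and smoothed along each
chromosome with a pyramidal (triangular) moving average, each cell is centered
at its median smoothed residual, and the cell x chromosome means of the
centered residuals form the CNA feature matrix used for clustering. No hidden
Markov discretization is applied: the per-chromosome scores stay continuous.

Sex chromosomes and the mitochondrial contig are excluded by default so the
feature matrix covers the 22 autosomes.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.ndimage import convolve1d
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["CNVProfile", "CNVProfiler", "order_genes", "infer_cnv", "cnv_burden"]

DEFAULT_EXCLUDE = ("chrX", "chrY", "chrM", "chrMT", "X", "Y", "M", "MT")


def _chrom_key(chrom: str) -> tuple[int, float, str]:
    name = re.sub(r"^chr", "", str(chrom), flags=re.IGNORECASE)
    if name.isdigit():
        return (0, int(name), "")
    order = {"X": 100, "Y": 101, "M": 102, "MT": 102}
    if name.upper() in order:
        return (0, order[name.upper()], "")
    return (1, 0.0, name)


def order_genes(adata: ad.AnnData, positions: pd.DataFrame) -> ad.AnnData:
    """Restrict to genes with known positions, sorted by (chromosome, start).

    Chromosomes sort naturally (chr1..chr22, chrX, chrY, chrM). Genes absent
    from the table are dropped with a warning carrying the count.
    """
    pos = positions.drop_duplicates("gene_id").set_index("gene_id")
    shared = adata.var_names.intersection(pos.index)
    if len(shared) == 0:
        raise ValueError("no genes shared between the matrix and the position table")
    n_dropped = adata.n_vars - len(shared)
    if n_dropped:
        warnings.warn(f"dropping {n_dropped} genes without genomic positions")
    pos = pos.loc[shared]
    order = sorted(
        shared, key=lambda g: (_chrom_key(pos.at[g, "chromosome"]), pos.at[g, "start"])
    )
    out = adata[:, order].copy()
    for col in ("chromosome", "start", "end"):
        out.var[col] = pos.loc[order, col].to_numpy()
    return out


def _triangular_smooth(values: np.ndarray, chroms: np.ndarray, window: int) -> np.ndarray:
    """Pyramidal moving average along gene order, per chromosome.

    Weights are renormalized where the window is truncated at chromosome
    edges, so a constant signal is preserved exactly everywhere.
    """
    half = (window - 1) // 2
    weights = (half + 1 - np.abs(np.arange(-half, half + 1))).astype(float)
    out = np.empty_like(values, dtype=float)
    for chrom in pd.unique(chroms):
        cols = np.flatnonzero(chroms == chrom)
        block = values[:, cols]
        num = convolve1d(block, weights, axis=1, mode="constant", cval=0.0)
        den = convolve1d(np.ones(block.shape[1]), weights, mode="constant", cval=0.0)
        out[:, cols] = num / den
    return out


@dataclass
class CNVProfile:
    """Smoothed, centered residuals plus the per-chromosome CNA features."""

    residuals: pd.DataFrame  # cells x ordered genes
    chrom_features: pd.DataFrame  # cells x chromosomes
    gene_order: list[str]
    params: dict


class CNVProfiler(BaseEstimator, TransformerMixin):
    """Smoothed-residual CNV profiler (sklearn-style transformer).

    Parameters
    ----------
    cutoff : minimum mean normalized expression (over all cells seen in
        ``fit``) for a gene to be retained; inferCNV's ``cutoff`` analogue.
    window : odd width of the triangular smoothing window, in genes.
    clamp : residuals are bounded to ``[-clamp, clamp]`` before smoothing.
    exclude_chromosomes : contig names removed before profiling (default: sex
        chromosomes and mitochondria, leaving the autosomes).

    Fitted attributes: ``kept_genes_`` (mask over input genes), ``ref_mean_``
    (per-gene reference means), ``chromosomes_`` (per-kept-gene contig) and
    ``feature_names_`` (chromosome order of the feature columns).
    """

    def __init__(
        self,
        cutoff: float = 0.1,
        window: int = 101,
        clamp: float = 3.0,
        exclude_chromosomes: tuple = DEFAULT_EXCLUDE,
    ):
        self.cutoff = cutoff
        self.window = window
        self.clamp = clamp
        self.exclude_chromosomes = exclude_chromosomes

    def fit(self, X, y=None, *, chromosomes, reference_mask):
        X = np.asarray(X, dtype=float)
        chromosomes = np.asarray(chromosomes, dtype=object)
        reference_mask = np.asarray(reference_mask, dtype=bool)
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be a positive odd integer, got {self.window}")
        if self.clamp <= 0:
            raise ValueError("clamp must be positive")
        if reference_mask.sum() < 2:
            raise ValueError(
                f"need at least 2 reference cells, got {int(reference_mask.sum())}"
            )
        excl = {str(c) for c in self.exclude_chromosomes}
        keep = ~np.isin(chromosomes.astype(str), list(excl))
        keep &= X.mean(axis=0) >= self.cutoff
        if keep.sum() == 0:
            raise ValueError("cutoff removed every gene")
        self.kept_genes_ = keep
        self.chromosomes_ = chromosomes[keep]
        self.ref_mean_ = X[reference_mask][:, keep].mean(axis=0)
        self.feature_names_ = list(pd.unique(self.chromosomes_))
        low = pd.Series(self.chromosomes_).value_counts()
        thin = low[low < 2].index.tolist()
        if thin:
            warnings.warn(f"chromosomes with fewer than 2 retained genes: {thin}")
        return self

    def transform(self, X) -> np.ndarray:
        """Centered smoothed residuals, cells x kept genes."""
        X = np.asarray(X, dtype=float)
        resid = X[:, self.kept_genes_] - self.ref_mean_[None, :]
        np.clip(resid, -self.clamp, self.clamp, out=resid)
        smooth = _triangular_smooth(resid, self.chromosomes_, self.window)
        return smooth - np.median(smooth, axis=1, keepdims=True)

    def chromosome_features(self, residuals: np.ndarray) -> np.ndarray:
        """Per-cell mean centered residual within each chromosome."""
        feats = np.empty((residuals.shape[0], len(self.feature_names_)))
        for j, chrom in enumerate(self.feature_names_):
            feats[:, j] = residuals[:, self.chromosomes_ == chrom].mean(axis=1)
        return feats


def infer_cnv(
    ordered: ad.AnnData,
    reference_cell_ids=None,
    cutoff: float = 0.1,
    window: int = 101,
    clamp: float = 3.0,
    exclude_chromosomes: tuple = DEFAULT_EXCLUDE,
) -> CNVProfile:
    """Run the profiler on a chromosome-ordered normalized AnnData.

    ``reference_cell_ids`` defaults to cells flagged in ``obs['is_reference']``.
    """
    if "chromosome" not in ordered.var:
        raise ValueError("run order_genes first: var['chromosome'] missing")
    if reference_cell_ids is None:
        if "is_reference" not in ordered.obs:
            raise ValueError("no reference_cell_ids given and obs['is_reference'] missing")
        ref_mask = ordered.obs["is_reference"].to_numpy(dtype=bool)
    else:
        ref_ids = set(reference_cell_ids)
        missing = ref_ids - set(ordered.obs_names)
        if missing:
            raise ValueError(f"reference cells absent from the matrix: {sorted(missing)[:5]}")
        ref_mask = ordered.obs_names.isin(ref_ids)
    X = ordered.X.toarray() if sp.issparse(ordered.X) else np.asarray(ordered.X)
    profiler = CNVProfiler(
        cutoff=cutoff, window=window, clamp=clamp, exclude_chromosomes=exclude_chromosomes
    ).fit(X, chromosomes=ordered.var["chromosome"].to_numpy(), reference_mask=ref_mask)
    resid = profiler.transform(X)
    genes = list(np.asarray(ordered.var_names)[profiler.kept_genes_])
    residuals = pd.DataFrame(resid, index=ordered.obs_names, columns=genes)
    feats = pd.DataFrame(
        profiler.chromosome_features(resid),
        index=ordered.obs_names,
        columns=profiler.feature_names_,
    )
    return CNVProfile(
        residuals=residuals,
        chrom_features=feats,
        gene_order=genes,
        params={"cutoff": cutoff, "window": window, "clamp": clamp},
    )


def cnv_burden(profile: CNVProfile) -> pd.Series:
    """Per-cell mean squared centered residual (overall CNV load)."""
    return (profile.residuals**2).mean(axis=1).rename("cnv_burden")
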