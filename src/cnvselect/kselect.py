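"""Objective selection of the K-means cluster number for CNV profiles.

For each candidate K, cells are clustered on their per-chromosome CNA
features; clusters depleted of reference (paratumor) cells are called
malignant; the top differentially expressed genes (up in malignant cells)
form a signature; the signature is scored by ssGSEA in an independent bulk
cohort; and the two-sided rank-sum P-value comparing tumor vs normal bulk
enrichment scores grades the K. The selected K minimizes that P-value, with
ties broken toward the smaller K. A K whose malignant/non-malignant
partition degenerates (all clusters on one side, a side with fewer than
three cells, or no significant up-regulated genes) stays in the result table
with P = 1 so every candidate remains auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import mannwhitneyu
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .simulate import BulkCohort
from .ssgsea import GeneSet, SSGSEA, separation_pvalue

__all__ = [
    "NoCandidateGenesError",
    "KResult",
    "KSelectionResult",
    "KSelector",
    "kmeans_over_range",
    "assign_malignancy",
    "de_top_genes",
    "select_k",
]


class NoCandidateGenesError(ValueError):
    """No gene is significantly up-regulated in the malignant group."""


def kmeans_over_range(
    features,
    k_min: int = 6,
    k_max: int = 15,
    seed: int = 0,
    n_init: int = 10,
) -> dict[int, np.ndarray]:
    """Best-of-``n_init`` Lloyd's K-means (k-means++ seeding) for each K.

    Deterministic given ``seed``: K value ``k`` uses ``random_state =
    seed + k`` so labelings are independent of which other K are requested.
    """
    X = np.asarray(features, dtype=float)
    if k_min < 2:
        raise ValueError(f"k_min must be >= 2, got {k_min}")
    if k_max < k_min:
        raise ValueError(f"empty K range [{k_min}, {k_max}]")
    if k_max >= X.shape[0]:
        raise ValueError(f"k_max={k_max} must be below the number of cells ({X.shape[0]})")
    n_distinct = np.unique(X, axis=0).shape[0]
    out: dict[int, np.ndarray] = {}
    for k in range(k_min, k_max + 1):
        if k > n_distinct:
            raise ValueError(
                f"K={k} exceeds the number of distinct feature rows ({n_distinct})"
            )
        km = KMeans(n_clusters=k, n_init=n_init, init="k-means++", random_state=seed + k)
        out[k] = km.fit_predict(X)
    return out


def assign_malignancy(labels, is_reference) -> tuple[set[int], bool]:
    """Call clusters malignant by reference-cell depletion.

    A cluster is non-malignant iff its fraction of reference cells is at
    least the global reference fraction; all other clusters are malignant.
    Returns ``(malignant_clusters, degenerate)`` — degenerate when every
    cluster lands on one side.
    """
    labels = np.asarray(labels)
    is_reference = np.asarray(is_reference, dtype=bool)
    if is_reference.sum() == 0:
        raise ValueError("no reference cells: malignancy cannot be anchored")
    global_frac = is_reference.mean()
    clusters = np.unique(labels)
    malignant = {
        int(c) for c in clusters if is_reference[labels == c].mean() < global_frac
    }
    degenerate = len(malignant) in (0, len(clusters))
    return malignant, degenerate


def _dense(X) -> np.ndarray:
    return X.toarray() if sp.issparse(X) else np.asarray(X)


def de_top_genes(
    normalized: ad.AnnData,
    malignant_cells,
    nonmalignant_cells,
    n_top: int = 50,
    sig_alpha: float = 0.05,
) -> GeneSet:
    """Top up-regulated genes in malignant vs non-malignant cells.

    Per gene: two-sided Wilcoxon rank-sum on normalized expression with
    Benjamini-Hochberg adjustment; candidates have adjusted P < ``sig_alpha``
    and a higher malignant-group mean; ranking is by descending log2 fold
    change of de-logged group means (pseudocount 1), gene id breaking ties.
    """
    mal = normalized[list(malignant_cells)] if not isinstance(malignant_cells, np.ndarray) else normalized[malignant_cells]
    non = normalized[list(nonmalignant_cells)] if not isinstance(nonmalignant_cells, np.ndarray) else normalized[nonmalignant_cells]
    if mal.n_obs < 3 or non.n_obs < 3:
        raise ValueError(
            f"need >= 3 cells per group, got {mal.n_obs} malignant / {non.n_obs} non-malignant"
        )
    Xm, Xn = _dense(mal.X), _dense(non.X)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant genes yield all-tied warnings
        res = mannwhitneyu(Xm, Xn, axis=0, alternative="two-sided", method="asymptotic")
    pvals = np.nan_to_num(np.asarray(res.pvalue, dtype=float), nan=1.0)
    padj = multipletests(pvals, method="fdr_bh")[1]
    up = Xm.mean(axis=0) > Xn.mean(axis=0)
    cand = np.flatnonzero((padj < sig_alpha) & up)
    if cand.size == 0:
        raise NoCandidateGenesError(
            "no gene is significantly up-regulated in the malignant group"
        )
    lfc = np.log2((np.expm1(Xm[:, cand]).mean(axis=0) + 1.0) /
                  (np.expm1(Xn[:, cand]).mean(axis=0) + 1.0))
    gene_ids = np.asarray(normalized.var_names)[cand]
    order = np.lexsort((gene_ids, -lfc))
    top = cand[order[:n_top]]
    if cand.size < n_top:
        warnings.warn(f"only {cand.size} candidate genes for a top-{n_top} set")
    return GeneSet(
        name=f"malignant_up_top{len(top)}",
        genes=list(np.asarray(normalized.var_names)[top]),
        description="up in malignant vs non-malignant cells",
    )


@dataclass
class KResult:
    k: int
    labels: np.ndarray
    malignant_clusters: set[int]
    gene_set: GeneSet | None
    es_scores: pd.Series | None
    statistic: float | None
    p_value: float
    degenerate: bool
    note: str = ""


@dataclass
class KSelectionResult:
    per_k: dict[int, KResult]
    selected_k: int
    seed: int

    def summary(self) -> pd.DataFrame:
        rows = []
        for k, r in sorted(self.per_k.items()):
            rows.append(
                {
                    "K": k,
                    "n_malignant_cells": int(np.isin(r.labels, list(r.malignant_clusters)).sum()),
                    "n_malignant_clusters": len(r.malignant_clusters),
                    "gene_set_size": 0 if r.gene_set is None else len(r.gene_set.genes),
                    "p_value": r.p_value,
                    "degenerate": r.degenerate,
                    "selected": k == self.selected_k,
                    "note": r.note,
                }
            )
        return pd.DataFrame(rows)

    @property
    def selected(self) -> KResult:
        return self.per_k[self.selected_k]

    def malignant_mask(self, k: int | None = None) -> np.ndarray:
        r = self.per_k[self.selected_k if k is None else k]
        return np.isin(r.labels, list(r.malignant_clusters))


class KSelector(BaseEstimator):
    """Grid of K-means clusterings graded by bulk ssGSEA separation.

    Parameters mirror the stages: the K range, K-means restarts, signature
    size, the ssGSEA exponent and the DE significance level. ``fit`` needs
    the CNA feature matrix, the matching log-normalized expression, the
    per-cell reference flags and a labelled bulk cohort; it exposes
    ``selected_k_``, ``results_`` (a :class:`KSelectionResult`), ``labels_``
    and ``malignant_mask_`` for the selected K.
    """

    def __init__(
        self,
        k_min: int = 6,
        k_max: int = 15,
        n_init: int = 10,
        n_top_genes: int = 50,
        alpha: float = 0.25,
        sig_alpha: float = 0.05,
        random_state: int = 0,
    ):
        self.k_min = k_min
        self.k_max = k_max
        self.n_init = n_init
        self.n_top_genes = n_top_genes
        self.alpha = alpha
        self.sig_alpha = sig_alpha
        self.random_state = random_state

    def fit(self, X, y=None, *, normalized: ad.AnnData, is_reference, cohort: BulkCohort):
        is_reference = np.asarray(is_reference, dtype=bool)
        labelings = kmeans_over_range(
            X, self.k_min, self.k_max, seed=self.random_state, n_init=self.n_init
        )
        per_k: dict[int, KResult] = {}
        cells = np.asarray(normalized.obs_names)
        for k, labels in labelings.items():
            malignant, degenerate = assign_malignancy(labels, is_reference)
            result = KResult(
                k=k,
                labels=labels,
                malignant_clusters=malignant,
                gene_set=None,
                es_scores=None,
                statistic=None,
                p_value=1.0,
                degenerate=degenerate,
                note="",
            )
            if degenerate:
                result.note = "all clusters on one side of the malignancy rule"
                per_k[k] = result
                continue
            mal_mask = np.isin(labels, list(malignant))
            if mal_mask.sum() < 3 or (~mal_mask).sum() < 3:
                result.degenerate = True
                result.note = "fewer than 3 cells on one side"
                per_k[k] = result
                continue
            try:
                gene_set = de_top_genes(
                    normalized,
                    cells[mal_mask],
                    cells[~mal_mask],
                    n_top=self.n_top_genes,
                    sig_alpha=self.sig_alpha,
                )
                scorer = SSGSEA(gene_sets=[gene_set], alpha=self.alpha).fit(cohort)
            except (NoCandidateGenesError, ValueError) as err:
                result.degenerate = True
                result.note = str(err)
                per_k[k] = result
                continue
            es = scorer.transform(cohort)[gene_set.name]
            stat, p = separation_pvalue(es.to_numpy(), cohort.labels.to_numpy())
            result.gene_set = gene_set
            result.es_scores = es
            result.statistic = stat
            result.p_value = p
            per_k[k] = result
        if all(r.degenerate for r in per_k.values()):
            raise ValueError("no informative K in range: every candidate degenerated")
        selected = min(per_k, key=lambda k: (per_k[k].p_value, k))
        self.results_ = KSelectionResult(per_k=per_k, selected_k=selected, seed=self.random_state)
        self.selected_k_ = selected
        self.labels_ = per_k[selected].labels
        self.malignant_mask_ = self.results_.malignant_mask()
        return self


def select_k(
    normalized: ad.AnnData,
    features,
    cohort: BulkCohort,
    k_min: int = 6,
    k_max: int = 15,
    seed: int = 0,
    n_init: int = 10,
    n_top_genes: int = 50,
    alpha: float = 0.25,
) -> KSelectionResult:
    """Run the full K-selection loop; see :class:`KSelector`."""
    if "is_reference" not in normalized.obs:
        raise ValueError("obs['is_reference'] required")
    sel = KSelector(
        k_min=k_min,
        k_max=k_max,
        n_init=n_init,
        n_top_genes=n_top_genes,
        alpha=alpha,
        random_state=seed,
    ).fit(
        features,
        normalized=normalized,
        is_reference=normalized.obs["is_reference"].to_numpy(dtype=bool),
        cohort=cohort,
    )
    return sel.results_
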