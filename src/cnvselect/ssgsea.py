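"""Single-sample gene set enrichment (ssGSEA) and class-separation testing.

Per sample, genes are ranked by expression in descending order (average ranks
on ties). With rank weight ``w(g) = N - rank(g) + 1`` and exponent ``alpha``,
the enrichment score is the sum over the N positions of the walk down the
ranked list of the difference between the weighted in-set ECDF and the
unweighted out-of-set ECDF:

    ES = sum_i [ P_hit(i) - P_miss(i) ]
    P_hit(i)  = sum_{g in S, rank(g) <= i} w(g)^alpha / sum_{g in S} w(g)^alpha
    P_miss(i) = |{g not in S : rank(g) <= i}| / (N - |S|)

The score depends only on within-sample ranks, so any strictly increasing
per-sample transform of expression leaves it unchanged. No cross-sample
normalization is applied: the downstream rank-sum comparison is invariant to
monotone per-cohort rescaling, which is why the min-max step some
implementations add is omitted here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, rankdata
from sklearn.base import BaseEstimator, TransformerMixin

from .simulate import BulkCohort

__all__ = [
    "GeneSet",
    "SSGSEA",
    "ssgsea_score",
    "separation_pvalue",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSet:
    name: str
    genes: list[str] = field(default_factory=list)
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            self.genes = list(dict.fromkeys(self.genes))


class SSGSEA(BaseEstimator, TransformerMixin):
    """ssGSEA scorer over one or more gene sets (sklearn-style transformer).

    ``fit`` captures the cohort's gene universe (a samples x genes DataFrame
    or a ``BulkCohort``); ``transform`` returns a samples x sets score frame.
    """

    def __init__(self, gene_sets=None, alpha: float = 0.25):
        self.gene_sets = gene_sets
        self.alpha = alpha

    @staticmethod
    def _frame(X) -> pd.DataFrame:
        return X.values if isinstance(X, BulkCohort) else X

    def fit(self, X, y=None):
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")
        frame = self._frame(X)
        self.gene_ids_ = pd.Index(frame.columns)
        sets = self.gene_sets if self.gene_sets is not None else []
        self.effective_sets_ = []
        for gs in sets if isinstance(sets, (list, tuple)) else [sets]:
            inter = [g for g in gs.genes if g in self.gene_ids_]
            n_miss = len(gs.genes) - len(inter)
            if n_miss:
                warnings.warn(f"gene set {gs.name!r}: {n_miss} genes absent from cohort")
            if len(inter) < 2:
                raise ValueError(
                    f"gene set {gs.name!r}: effective size {len(inter)} < 2 after intersection"
                )
            if len(inter) == len(self.gene_ids_):
                raise ValueError(f"gene set {gs.name!r} covers every cohort gene")
            self.effective_sets_.append((gs.name, inter))
        return self

    def transform(self, X) -> pd.DataFrame:
        frame = self._frame(X)
        expr = frame[self.gene_ids_].to_numpy(dtype=float)
        n_samples, n_genes = expr.shape
        # rank 1 = highest expression, average ranks on ties
        ranks = rankdata(-expr, axis=1)
        # a gene with rank r contributes to every step i >= r of the walk,
        # i.e. to N - ceil(r) + 1 positions; summing contributions per gene
        # collapses the double loop over steps and genes
        steps = n_genes - np.ceil(ranks) + 1.0
        weights = (n_genes - ranks + 1.0) ** self.alpha
        out = {}
        col_index = {g: j for j, g in enumerate(self.gene_ids_)}
        for name, genes in self.effective_sets_:
            hit = np.zeros(n_genes, dtype=bool)
            hit[[col_index[g] for g in genes]] = True
            s = hit.sum()
            hit_w = weights[:, hit]
            p_hit = (hit_w * steps[:, hit]).sum(axis=1) / hit_w.sum(axis=1)
            p_miss = steps[:, ~hit].sum(axis=1) / (n_genes - s)
            out[name] = p_hit - p_miss
        return pd.DataFrame(out, index=frame.index)


def ssgsea_score(cohort: BulkCohort, gene_set: GeneSet, alpha: float = 0.25) -> pd.Series:
    """Per-sample enrichment score of one gene set."""
    scorer = SSGSEA(gene_sets=[gene_set], alpha=alpha).fit(cohort)
    return scorer.transform(cohort)[gene_set.name]


def separation_pvalue(scores, labels) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum of tumor vs normal enrichment scores.

    The exact null distribution is used when the combined sample size is at
    most 20 and there are no ties; otherwise the normal approximation with
    tie correction (no continuity correction). Returns ``(statistic, p)``
    where the statistic is the tumor-side Mann-Whitney U.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    tumor = scores[labels == "tumor"]
    normal = scores[labels == "normal"]
    if len(tumor) < 2 or len(normal) < 2:
        raise ValueError(
            f"need >= 2 samples per class, got {len(tumor)} tumor / {len(normal)} normal"
        )
    n = len(tumor) + len(normal)
    if len(np.unique(scores)) == 1:  # all tied: no separation at all
        return float(len(tumor) * len(normal) / 2.0), 1.0
    has_ties = len(np.unique(scores)) < n
    method = "exact" if (n <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(
        tumor, normal, alternative="two-sided", method=method, use_continuity=False
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def read_gmt(path) -> list[GeneSet]:
    sets = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line (need name, description, >=1 gene): {line!r}")
        sets.append(GeneSet(name=fields[0], description=fields[1], genes=fields[2:]))
    return sets


def write_gmt(sets, path) -> None:
    lines = [
        "\t".join([gs.name, gs.description or "na", *gs.genes]) for gs in sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
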