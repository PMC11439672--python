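"""HT-associated specific cells: cell-type composition tests between groups.

A cell type is an HT-associated specific cell (HASC) when its proportion is
significantly higher in Hashimoto's-thyroiditis (HT) samples than in non-HT
samples. The global comparison is a Pearson chi-square on the full
types x {HT, nonHT} table; the post-hoc step tests each type against all
others in a collapsed 2x2 table (no Yates continuity correction), adjusts
the raw P-values across types, and flags types with adjusted P below alpha
and a higher HT proportion.

Cells are pooled across samples within each group by default, matching
figure-level composition comparisons; pooling ignores within-sample
correlation, so a per-sample mode (rank-sum on per-sample type fractions) is
provided for a more conservative reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = ["HASCTable", "proportion_table", "hasc_test", "per_sample_proportion_test"]

_CORRECTIONS = {"bonferroni": "bonferroni", "BH": "fdr_bh", "none": None}


def proportion_table(cell_types, is_HT) -> pd.DataFrame:
    """Cross-tabulate cell types against HT status (columns HT, nonHT)."""
    cell_types = pd.Series(np.asarray(cell_types, dtype=object), name="cell_type")
    is_HT = np.asarray(is_HT, dtype=bool)
    if len(cell_types) != len(is_HT):
        raise ValueError("cell_types and is_HT lengths differ")
    if is_HT.all() or (~is_HT).all():
        raise ValueError("both HT and non-HT groups must be non-empty")
    group = pd.Series(np.where(is_HT, "HT", "nonHT"))
    table = pd.crosstab(cell_types, group).reindex(columns=["HT", "nonHT"], fill_value=0)
    if table.shape[0] < 2:
        raise ValueError("need at least 2 cell types")
    table.columns.name = None
    return table.sort_index()


@dataclass
class HASCTable:
    """Per-type composition statistics plus the global chi-square test."""

    table: pd.DataFrame  # per type: counts, proportions, chi2, p_raw, p_adj, is_hasc
    global_chi2: float
    global_p: float
    correction: str
    alpha: float

    @property
    def hascs(self) -> list[str]:
        return self.table.index[self.table["is_hasc"]].tolist()


def _pearson_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Chi-square (no continuity correction) on [[a, b], [c, d]]."""
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ValueError("zero marginal")
    chi2, p, _, expected = chi2_contingency(obs, correction=False)
    if (expected == 0).any():
        raise ValueError("zero expected count")
    return float(chi2), float(p)


def hasc_test(
    table: pd.DataFrame, alpha: float = 0.05, correction: str = "bonferroni"
) -> HASCTable:
    """Global + post-hoc composition testing on a types x {HT, nonHT} table."""
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    if table.shape[0] < 2:
        raise ValueError("need at least 2 cell types")
    if (table.sum(axis=0) <= 0).any():
        raise ValueError("each group needs at least one cell")
    counts = table[["HT", "nonHT"]].to_numpy(dtype=float)
    # all-zero types carry no information for the global test
    informative = counts.sum(axis=1) > 0
    if informative.sum() < 2:
        raise ValueError("need at least 2 non-empty cell types")
    g_chi2, g_p, _, _ = chi2_contingency(counts[informative], correction=False)
    tot = counts.sum(axis=0)
    props = counts / tot[None, :]

    p_raw = np.ones(len(table))
    chi2s = np.zeros(len(table))
    for i in range(len(table)):
        a, b = counts[i]
        c, d = tot[0] - a, tot[1] - b
        try:
            chi2s[i], p_raw[i] = _pearson_2x2(a, b, c, d)
        except ValueError:
            warnings.warn(
                f"type {table.index[i]!r}: degenerate 2x2 table, P set to 1"
            )
            chi2s[i], p_raw[i] = 0.0, 1.0
    method = _CORRECTIONS[correction]
    p_adj = p_raw if method is None else multipletests(p_raw, method=method)[1]
    p_adj = np.minimum(p_adj, 1.0)
    is_hasc = (p_adj < alpha) & (props[:, 0] > props[:, 1])
    out = pd.DataFrame(
        {
            "count_HT": counts[:, 0].astype(int),
            "count_nonHT": counts[:, 1].astype(int),
            "prop_HT": props[:, 0],
            "prop_nonHT": props[:, 1],
            "chi2": chi2s,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "is_hasc": is_hasc,
        },
        index=table.index,
    )
    return HASCTable(
        table=out,
        global_chi2=float(g_chi2),
        global_p=float(g_p),
        correction=correction,
        alpha=alpha,
    )


def per_sample_proportion_test(
    cell_types, is_HT, samples, alpha: float = 0.05, correction: str = "bonferroni"
) -> pd.DataFrame:
    """Conservative alternative: rank-sum on per-sample type fractions.

    Each sample contributes one fraction per cell type; HT vs non-HT samples
    are compared per type with a two-sided Wilcoxon rank-sum test.
    """
    if correction not in _CORRECTIONS:
        raise ValueError(f"correction must be one of {sorted(_CORRECTIONS)}")
    df = pd.DataFrame(
        {
            "cell_type": np.asarray(cell_types, dtype=object),
            "sample": np.asarray(samples, dtype=object),
            "is_HT": np.asarray(is_HT, dtype=bool),
        }
    )
    ht_of_sample = df.groupby("sample")["is_HT"].first()
    frac = (
        df.groupby(["sample", "cell_type"]).size().unstack(fill_value=0).pipe(
            lambda t: t.div(t.sum(axis=1), axis=0)
        )
    )
    ht_frac = frac.loc[ht_of_sample[ht_of_sample].index.intersection(frac.index)]
    nht_frac = frac.loc[ht_of_sample[~ht_of_sample].index.intersection(frac.index)]
    if len(ht_frac) < 2 or len(nht_frac) < 2:
        raise ValueError("need >= 2 samples per group for the per-sample mode")
    rows = []
    for ct in frac.columns:
        res = mannwhitneyu(ht_frac[ct], nht_frac[ct], alternative="two-sided")
        rows.append(
            {
                "cell_type": ct,
                "mean_frac_HT": float(ht_frac[ct].mean()),
                "mean_frac_nonHT": float(nht_frac[ct].mean()),
                "p_raw": float(res.pvalue),
            }
        )
    out = pd.DataFrame(rows).set_index("cell_type")
    method = _CORRECTIONS[correction]
    out["p_adj"] = out["p_raw"] if method is None else multipletests(out["p_raw"], method=method)[1]
    out["is_hasc"] = (out["p_adj"] < alpha) & (out["mean_frac_HT"] > out["mean_frac_nonHT"])
    return out
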