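"""Synthetic single-cell and bulk RNA-seq cohorts with planted copy-number clones.

The generator emulates the statistical structure the downstream method assumes:

* an over-dispersed (negative-binomial) gene x cell count matrix in which a
  subset of "observation" cells belongs to malignant clones carrying clonal
  copy-number segments, modelled as multiplicative shifts of the NB mean over
  contiguous gene blocks along a pseudo-genome;
* reference cells (paratumor tissue) with no copy-number signal;
* a bulk cohort in which tumor samples over-express a chosen set of malignant
  marker genes while normal (paratumor) samples sit at baseline.

Gene positions form a pseudo-genome: genes are evenly partitioned over
``n_chromosomes`` in index order with contiguous, non-overlapping spans, which
is all the chromosome-ordered smoothing downstream requires.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import anndata as ad
import numpy as np
import pandas as pd

__all__ = [
    "SimulationConfig",
    "BulkCohort",
    "chromosome_spans",
    "default_segments",
    "generate_sc",
    "generate_bulk",
]

# A CNV segment: (clone index, chromosome index, start gene, end gene, fold change).
# Gene indices are global, half-open [start, end), and must lie inside the
# chromosome's span. Fold change 1.0 is a no-op segment.
Segment = tuple[int, int, int, int, float]

DEFAULT_CELL_TYPES = (
    "thyrocyte",
    "T_NK",
    "B_cell",
    "myeloid",
    "fibroblast",
    "endothelial",
)
DEFAULT_TYPE_PROBS = (0.35, 0.25, 0.10, 0.12, 0.10, 0.08)


@dataclass
class SimulationConfig:
    """Parameters of the paired single-cell / bulk simulation.

    ``nb_dispersion`` is the negative-binomial size parameter (theta), so the
    count variance is ``mu + mu**2 / theta``; smaller values mean more
    over-dispersion. ``nb_mean`` is the mean of the gamma-distributed per-gene
    baseline means (shape ``gene_mean_shape``), giving the usual long-tailed
    scRNA-seq expression-level distribution.
    """

    n_genes: int = 2000
    n_chromosomes: int = 22
    n_reference_cells: int = 200
    n_normal_obs_cells: int = 200
    clone_sizes: Sequence[int] = (100, 100)
    cnv_segments: Sequence[Segment] | None = None
    nb_mean: float = 2.5
    nb_dispersion: float = 5.0
    gene_mean_shape: float = 2.0
    libsize_sigma: float = 0.2
    n_bulk_tumor: int = 20
    n_bulk_normal: int = 20
    bulk_marker_fraction: float = 1.0
    bulk_marker_shift: float = 2.0
    purity_range: tuple[float, float] = (0.4, 0.9)
    n_paratumor_samples: int = 3
    n_tumor_samples: int = 4
    ht_fraction: float = 0.5
    cell_type_names: Sequence[str] = DEFAULT_CELL_TYPES
    cell_type_probs: Sequence[float] = DEFAULT_TYPE_PROBS
    ht_enriched_type: str = "T_NK"
    ht_enrichment: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cnv_segments is None:
            self.cnv_segments = default_segments(self)
        self.validate()

    def validate(self) -> None:
        for name in (
            "n_genes",
            "n_chromosomes",
            "n_reference_cells",
            "n_normal_obs_cells",
            "n_paratumor_samples",
            "n_tumor_samples",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer, got {getattr(self, name)}")
        if any(s < 1 for s in self.clone_sizes):
            raise ValueError("clone_sizes must all be positive")
        for name in ("nb_mean", "nb_dispersion", "gene_mean_shape"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 < self.bulk_marker_fraction <= 1.0:
            raise ValueError("bulk_marker_fraction must lie in (0, 1]")
        lo, hi = self.purity_range
        if not 0.0 < lo <= hi <= 1.0:
            raise ValueError("purity_range must satisfy 0 < low <= high <= 1")
        if len(self.cell_type_names) != len(self.cell_type_probs):
            raise ValueError("cell_type_names and cell_type_probs lengths differ")
        if self.ht_enriched_type not in self.cell_type_names:
            raise ValueError(f"unknown ht_enriched_type {self.ht_enriched_type!r}")
        spans = chromosome_spans(self.n_genes, self.n_chromosomes)
        n_clones = len(self.clone_sizes)
        for seg in self.cnv_segments:
            clone, chrom, start, end, fold = seg
            if not 0 <= clone < n_clones:
                raise ValueError(f"segment {seg}: clone index out of range (have {n_clones} clones)")
            if not 0 <= chrom < self.n_chromosomes:
                raise ValueError(f"segment {seg}: chromosome index out of range")
            lo, hi = spans[chrom]
            if not (lo <= start < end <= hi):
                raise ValueError(
                    f"segment {seg}: gene range [{start}, {end}) outside chromosome span [{lo}, {hi})"
                )
            if fold <= 0:
                raise ValueError(f"segment {seg}: fold change must be > 0")


def chromosome_spans(n_genes: int, n_chromosomes: int) -> list[tuple[int, int]]:
    """Half-open global gene-index spans of an even pseudo-genome partition."""
    base, rem = divmod(n_genes, n_chromosomes)
    spans, lo = [], 0
    for c in range(n_chromosomes):
        hi = lo + base + (1 if c < rem else 0)
        spans.append((lo, hi))
        lo = hi
    return spans


def default_segments(config: SimulationConfig) -> list[Segment]:
    """Truncal plus private copy-number events for two malignant clones.

    Subclones of one tumor share truncal alterations: both clones carry the
    chr2 gain (fold 2.0), clone 0 additionally gains chr7 (fold 2.0) and
    clone 1 loses chr10 (fold 0.5). Each segment covers the middle ~40% of
    its chromosome (1-based chromosome naming; indices below are 0-based).
    The shared gain gives malignant cells the common dosage-driven expression
    program the bulk-validation step presumes.
    """
    spans = chromosome_spans(config.n_genes, config.n_chromosomes)
    n_clones = len(config.clone_sizes)
    plan = [(0, 1, 2.0), (0, 6, 2.0), (1, 1, 2.0), (1, 9, 0.5)]
    segments: list[Segment] = []
    for clone, chrom, fold in plan:
        if clone >= n_clones or chrom >= config.n_chromosomes:
            continue
        lo, hi = spans[chrom]
        size = hi - lo
        start = lo + int(0.3 * size)
        end = lo + max(int(0.7 * size), int(0.3 * size) + 1)
        segments.append((clone, chrom, start, end, fold))
    return segments


def _gene_position_table(config: SimulationConfig) -> pd.DataFrame:
    spans = chromosome_spans(config.n_genes, config.n_chromosomes)
    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes)]
    chroms = np.empty(config.n_genes, dtype=object)
    starts = np.empty(config.n_genes, dtype=int)
    for c, (lo, hi) in enumerate(spans):
        chroms[lo:hi] = f"chr{c + 1}"
        starts[lo:hi] = (np.arange(hi - lo)) * 1000 + 1
    return pd.DataFrame(
        {"gene_id": gene_ids, "chromosome": chroms, "start": starts, "end": starts + 999}
    )


def generate_sc(config: SimulationConfig) -> tuple[ad.AnnData, pd.DataFrame, pd.DataFrame]:
    """Simulate the single-cell cohort.

    Returns ``(adata, positions, truth)`` where ``adata`` holds integer counts
    (cells x genes) with per-cell metadata columns ``sample``, ``group``,
    ``is_reference``, ``is_HT`` and ``cell_type``; ``positions`` is the
    4-column gene-position table; ``truth`` records the planted clone of every
    cell (``clone`` = "normal" or "clone<k>") and a boolean ``is_malignant``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_clones = len(config.clone_sizes)
    n_cells = config.n_reference_cells + config.n_normal_obs_cells + int(np.sum(config.clone_sizes))

    base_mean = rng.gamma(
        config.gene_mean_shape, config.nb_mean / config.gene_mean_shape, size=config.n_genes
    )
    base_mean = np.maximum(base_mean, 1e-8)

    # per-group fold-change vectors: group 0 = normal, group k+1 = clone k
    fold = np.ones((n_clones + 1, config.n_genes))
    for clone, _chrom, start, end, fc in config.cnv_segments:
        fold[clone + 1, start:end] *= fc

    group = np.concatenate(
        [
            np.zeros(config.n_reference_cells + config.n_normal_obs_cells, dtype=int),
            np.repeat(np.arange(1, n_clones + 1), config.clone_sizes),
        ]
    )
    size_factor = np.exp(rng.normal(0.0, config.libsize_sigma, size=n_cells))
    mu = base_mean[None, :] * fold[group] * size_factor[:, None]
    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu)).astype(np.int64)

    # library sizes must stay positive even in tiny test configs
    empty = counts.sum(axis=1) == 0
    if empty.any():
        counts[empty, int(np.argmax(base_mean))] = 1

    # sample layout: reference cells over paratumor samples, observation cells
    # over tumor samples (alternating primary / metastasis tissue labels)
    n_ref = config.n_reference_cells
    para_samples = [f"P{i + 1}" for i in range(config.n_paratumor_samples)]
    tumor_samples = [f"T{i + 1}" for i in range(config.n_tumor_samples)]
    tumor_groups = {
        s: ("primary" if i % 2 == 0 else "metastasis") for i, s in enumerate(tumor_samples)
    }
    sample = np.empty(n_cells, dtype=object)
    sample[:n_ref] = np.array(para_samples)[np.arange(n_ref) % len(para_samples)]
    n_obs = n_cells - n_ref
    sample[n_ref:] = np.array(tumor_samples)[np.arange(n_obs) % len(tumor_samples)]

    tissue = np.empty(n_cells, dtype=object)
    tissue[:n_ref] = "paratumor"
    if n_obs:
        tissue[n_ref:] = pd.Series(sample[n_ref:]).map(tumor_groups).to_numpy()

    all_samples = para_samples + tumor_samples
    n_ht = int(round(config.ht_fraction * len(all_samples)))
    ht_samples = set(rng.permutation(all_samples)[:n_ht])
    is_ht = np.array([s in ht_samples for s in sample])

    # cell-type labels: multinomial, HT samples enrich one type (composition
    # shift exercised by the hasc module); labels are independent of clones
    probs = np.asarray(config.cell_type_probs, dtype=float)
    probs = probs / probs.sum()
    probs_ht = probs.copy()
    probs_ht[list(config.cell_type_names).index(config.ht_enriched_type)] *= config.ht_enrichment
    probs_ht = probs_ht / probs_ht.sum()
    types = np.asarray(config.cell_type_names, dtype=object)
    draw = rng.random(n_cells)
    cell_type = np.where(
        is_ht,
        types[np.searchsorted(np.cumsum(probs_ht), draw)],
        types[np.searchsorted(np.cumsum(probs), draw)],
    )

    cell_ids = [f"CELL{i:05d}" for i in range(n_cells)]
    positions = _gene_position_table(config)
    obs = pd.DataFrame(
        {
            "sample": sample,
            "group": tissue,
            "is_reference": np.arange(n_cells) < n_ref,
            "is_HT": is_ht,
            "cell_type": cell_type,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    var = positions.set_index("gene_id")
    adata = ad.AnnData(X=counts, obs=obs, var=var.loc[positions["gene_id"]])

    clone_name = np.where(group == 0, "normal", np.array([f"clone{g - 1}" for g in group]))
    truth = pd.DataFrame(
        {"cell_id": cell_ids, "clone": clone_name, "is_malignant": group > 0}
    )
    return adata, positions, truth


@dataclass
class BulkCohort:
    """Bulk expression cohort: ``values`` is samples x genes, labels per sample."""

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.labels.index):
            self.labels = self.labels.reindex(self.values.index)
        if self.labels.isna().any():
            raise ValueError("every bulk sample needs a label")
        bad = set(self.labels.unique()) - {"tumor", "normal"}
        if bad:
            raise ValueError(f"labels must be 'tumor' or 'normal', got {sorted(bad)}")
        if self.values.isna().any().any():
            raise ValueError("bulk cohort contains missing values")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.columns


def generate_bulk(config: SimulationConfig, marker_genes: Sequence[str]) -> BulkCohort:
    """Simulate the bulk cohort with tumor over-expression of marker genes.

    Tumor samples multiply the NB mean of a ``bulk_marker_fraction`` of
    ``marker_genes`` by ``bulk_marker_shift``, attenuated per sample by a
    tumor-purity factor drawn from ``Uniform(purity_range)`` (the effective
    per-sample shift is ``1 + (shift - 1) * purity``, emulating the variable
    malignant-cell content of real bulk tumors); normal samples are baseline.
    ``bulk_marker_shift`` of 1.0 plants nothing (a null cohort).
    """
    config.validate()
    if config.n_bulk_tumor < 1 or config.n_bulk_normal < 1:
        raise ValueError(
            f"need at least one sample per class, got {config.n_bulk_tumor} tumor / "
            f"{config.n_bulk_normal} normal"
        )
    marker_genes = list(marker_genes)
    if not marker_genes:
        raise ValueError("marker_genes must be non-empty")
    gene_ids = [f"GENE{i:05d}" for i in range(config.n_genes)]
    universe = set(gene_ids)
    unknown = [g for g in marker_genes if g not in universe]
    if unknown:
        raise ValueError(f"unknown marker gene ids: {unknown[:5]}")

    # independent stream so single-cell and bulk draws do not interleave
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(2)[1])
    base_mean = np.maximum(
        rng.gamma(config.gene_mean_shape, config.nb_mean / config.gene_mean_shape, config.n_genes),
        1e-8,
    )
    n_shift = max(1, int(round(config.bulk_marker_fraction * len(marker_genes))))
    shifted = rng.permutation(marker_genes)[:n_shift]
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    marker_mask = np.zeros(config.n_genes, dtype=bool)
    marker_mask[[gene_index[g] for g in shifted]] = True

    n_t, n_n = config.n_bulk_tumor, config.n_bulk_normal
    purity = rng.uniform(*config.purity_range, size=n_t)
    shift = np.ones((n_t + n_n, config.n_genes))
    shift[:n_t, marker_mask] = 1.0 + (config.bulk_marker_shift - 1.0) * purity[:, None]
    mu = base_mean[None, :] * shift * np.exp(
        rng.normal(0.0, config.libsize_sigma, size=(n_t + n_n, 1))
    )
    theta = config.nb_dispersion
    values = rng.negative_binomial(theta, theta / (theta + mu)).astype(float)

    ids = [f"TUMOR{i:03d}" for i in range(n_t)] + [f"NORMAL{i:03d}" for i in range(n_n)]
    labels = pd.Series(["tumor"] * n_t + ["normal"] * n_n, index=ids, name="label")
    return BulkCohort(pd.DataFrame(values, index=ids, columns=gene_ids), labels)


def config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["clone_sizes"] = list(config.clone_sizes)
    d["cnv_segments"] = [list(s) for s in config.cnv_segments]
    d["purity_range"] = list(config.purity_range)
    d["cell_type_names"] = list(config.cell_type_names)
    d["cell_type_probs"] = list(config.cell_type_probs)
    return d
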