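# Methods

`cnvselect` implements an objective criterion for choosing the number of
clusters K when K-means is used to split single thyroid epithelial cells into
malignant (mTE) and non-malignant (nTE) groups on the basis of inferred
copy-number profiles. This note describes each stage, its assumptions, the
tunable parameters, and the design choices that were genuinely open.

## Quality control and normalization

Raw counts pass two filters, gene filter first: a gene is kept when it is
detected (raw count > 0) in **strictly more than** `min_cells_per_gene`
(default 3) cells; a cell is kept when it detects **at least**
`min_genes_per_cell` (default 200) genes. The defaults mirror common scRNA-seq
QC practice for 10x data. A `per_sample` mode applies the gene rule within
each sample and keeps the union of survivors, the behaviour of per-sample QC
followed by merging; merged-matrix filtering is the default for single-matrix
input.

Normalization is the global-scaling log transform

    normalized = ln(raw / cell_total x scale_factor + 1),    scale_factor = 10 000

computed in float64 with cell totals taken after filtering. The natural
logarithm is used (the convention of the Log-Normalize method this transform
follows); the base is a documented choice, and any fixed base would rescale
all downstream rank statistics without changing them. Zeros map to exactly
zero and the transform is invariant to rescaling a cell's counts.

## Copy-number profiles from expression

The profiler is a simplified expression-intensity member of the inferCNV
family. Given normalized expression ordered along the genome:

1. genes with mean normalized expression over all cells below `cutoff`
   (default 0.1, the inferCNV `cutoff` analogue, applied to all cells by the
   inferCNV convention) are dropped, as are sex chromosomes and mitochondrial
   contigs (leaving the 22 autosomes);
2. the per-gene mean over **reference cells** (paratumor cells) is subtracted
   from every cell;
3. residuals are bounded to ±`clamp` (default 3.0 log-units), inferCNV-style
   outlier bounding;
4. residuals are smoothed along each chromosome with a pyramidal (triangular)
   weighted moving average of width `window` (default 101 genes, inferCNV's
   documented smoothing default; the window is truncated and the weights
   renormalized at chromosome edges, so a constant signal is preserved
   exactly);
5. each cell is centered at its median smoothed residual, removing
   cell-specific baseline shifts.

The per-cell, per-chromosome means of the centered smoothed residuals form
the cells x 22 CNA feature matrix used for clustering. **No hidden-Markov
discretization is applied**: tools in this family often post-process
residuals with an HMM into discrete dosage states, but K-means over
continuous per-chromosome scores is well-defined without it, and the
continuous scores avoid a discretization layer with many latent conventions.
This is the package's most consequential design choice and is deliberate.

`cnv_burden` (mean squared centered residual per cell) summarizes overall
aneuploidy and is reported for audit; it plays no role in K selection.

## Single-sample GSEA

For one sample, genes are ranked by expression descending (average ranks on
ties). With rank weight `w(g) = N - rank(g) + 1` raised to `alpha`
(default 0.25), the enrichment score is the sum over the N positions of the
ranked-list walk of `P_hit(i) - P_miss(i)`, where `P_hit` is the weighted
in-set ECDF and `P_miss` the unweighted out-of-set ECDF. The implementation
collapses the double loop: a gene of rank r contributes to `N - ceil(r) + 1`
walk positions, so the score is a weighted sum over genes; a literal
double-loop oracle in the test suite verifies the equivalence to < 1e-10.

Two variant decisions are fixed and documented rather than inferred: the ES
is the *sum* of the running difference (the canonical single-sample variant),
not the maximum deviation; and no min–max cross-sample normalization is
applied, because a monotone per-cohort rescaling cannot change the rank-sum
P-value that consumes the scores.

Separation between tumor and normal bulk samples is tested with the
two-sided Wilcoxon rank-sum test: exact null distribution when the combined
sample size is at most 20 and there are no ties, otherwise the normal
approximation with tie correction and no continuity correction. When every
score is tied the test reports P = 1 (no separation).

## The K-selection loop

For each K in `[k_min, k_max]` (defaults 6..15; the desk-scale studies below
use 2..8):

1. **Cluster** the CNA features with Lloyd's K-means, k-means++ seeding, best
   of `n_init = 10` restarts; K value k uses `random_state = seed + k` so a
   labeling never depends on which other K are in the range.
2. **Call malignancy**: a cluster is non-malignant iff its fraction of
   reference cells is at least the global reference fraction; the remaining
   clusters are malignant. The rule is this package's choice — the source
   convention labels reference-rich clusters non-malignant without stating a
   rule — and its threshold form allows paratumor cells to land in malignant
   clusters and vice versa, as observed in real data. If every cluster falls
   on one side, the K is degenerate.
3. **Signature**: per gene, two-sided Wilcoxon rank-sum between malignant and
   non-malignant cells with Benjamini–Hochberg adjustment; candidates need
   adjusted P < 0.05 and a higher malignant mean; the top `n_top_genes = 50`
   by log2 fold change of de-logged group means (pseudocount 1, gene id as
   deterministic tie-break) form the gene set. The test family and
   up-in-malignant direction are package choices.
4. **Validate in bulk**: ssGSEA of the signature across the labelled bulk
   cohort, then the rank-sum separation P-value.

The selected K minimizes the P-value; ties break toward smaller K
(parsimony). Degenerate K values (one-sided partition, a side smaller than
3 cells, or no significant up-regulated gene) stay in the result table with
P = 1 for auditability; if every K degenerates the loop raises. The stored
P-value for any K is exactly reproducible from its stored gene set and the
cohort.

## HT-associated specific cells

Cell types over-represented in Hashimoto's-thyroiditis (HT) samples are
found by composition testing: a global Pearson chi-square on the full
types x {HT, nonHT} contingency table, then per type a 2x2 chi-square of the
type against all others (no Yates continuity correction), Bonferroni
adjustment across types by default (configurable to BH or none — the source
convention states only P < 0.05), and a HASC flag when the adjusted P is
below alpha = 0.05 *and* the HT proportion is higher. Cells are pooled
across samples within each group, matching figure-level composition
comparisons; pooling ignores within-sample correlation and inflates
significance, so `per_sample_proportion_test` offers the conservative
alternative (rank-sum on per-sample type fractions).

## The synthetic cohorts

The generator produces the statistical structure the method assumes, not a
portrait of any particular dataset.

*Single cell.* Counts are negative binomial with gamma-distributed per-gene
baseline means (shape 2.0, mean `nb_mean = 2.5` counts/gene — about 5 000
UMIs per cell over the 2 000 simulated genes, representative of 10x data),
NB size `nb_dispersion = 5.0` (mild over-dispersion typical of UMI counts),
and log-normal cell size factors (sigma 0.2). Copy-number events are
multiplicative shifts of the NB mean over contiguous gene blocks of an even
pseudo-genome (genes partitioned over 22 chromosomes in index order — the
smoothing needs only ordering, not real coordinates). The default clonal
structure is truncal-plus-private: both clones share a chr2 gain (fold 2.0),
clone 0 privately gains chr7, clone 1 privately loses chr10 (fold 0.5), each
event spanning the middle ~40% of its chromosome. Subclones of one tumor
share truncal events, and the shared gain gives malignant cells the common
dosage-driven expression program that the bulk-validation step presumes; a
configuration with fully disjoint clone segments makes the criterion prefer
the partition isolating the amplified clone alone, which is a property of
that configuration, not a defect of the criterion. Reference cells
(paratumor) carry no events. Cell-type labels are drawn from a multinomial
whose probabilities differ between HT and non-HT samples (default: T/NK
doubled in HT) and are independent of clone structure — they are
exchangeable labels that exercise the composition tests only.

*Bulk.* Tumor samples over-express a configurable fraction of the supplied
marker genes by `bulk_marker_shift` (default 2.0), attenuated per sample by
a tumor-purity draw from Uniform(0.4, 0.9) (effective shift
`1 + (shift-1) x purity`), emulating the variable malignant content of real
bulk tumors and keeping the separation statistic away from its saturation
floor; normal samples are baseline. Shift 1.0 produces a null cohort.

What the generator does **not** emulate: batch effects and integration,
doublets, ambient RNA, allele-specific dosage, realistic gene-gene
correlation, and real genomic coordinates. Passing tests therefore
demonstrate the internal correctness and calibration of the method under its
own assumptions, not performance on any real accession.

## Problem sizes and numerical choices

The simulation studies run at desk scale, chosen so the whole suite
completes in minutes on one CPU: the K-recovery study uses 600 cells (200
reference, 200 normal observation, two clones of 100), 2 000 genes, 22
chromosomes, a 20+20 bulk cohort and the K range 2..8 over 10 replicate
seeds; the null-calibration study uses 200 replicate 20+20 cohorts with no
planted shift. Smoothing renormalizes truncated windows exactly, so constant
signals pass through unchanged; residual clamping happens before smoothing;
DE ranking breaks fold-change ties by gene id so results are deterministic;
all randomness flows through explicitly passed integer seeds (NumPy PCG64),
making every artifact bit-reproducible.

## Known limitations

- The malignancy rule is proportion-based; it cannot separate two clones
  that K-means merges, and it labels a cluster, not a cell.
- The reported per-K P-values are selection criteria, not calibrated
  significance statements: the minimum over K is biased low.
- Pooled composition testing overstates significance under within-sample
  correlation; use the per-sample mode when samples are few and large.
- At strong planted signal the rank-sum P saturates at its combinatorial
  floor and several K tie; selection then rests on the parsimony tie-break.
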