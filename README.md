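# cnvselect

Identifying malignant cells in tumor scRNA-seq data usually starts from
inferred copy-number profiles: each cell's expression is compared to
reference (paratumor) cells, smoothed along the genome, and the resulting
per-chromosome CNA scores are clustered with K-means into malignant (mTE)
and non-malignant (nTE) epithelial groups. The weak point of that recipe is
the cluster number K, which is conventionally picked by eye. `cnvselect`
implements an **objective K-selection criterion**: every candidate K is
scored by how well its own malignant-vs-non-malignant signature separates
tumor from paratumor samples in an independent bulk cohort, and the K with
the strongest separation wins. The package was built around the papillary
thyroid carcinoma setting (paratumor reference cells, a TCGA-THCA-like bulk
cohort, Hashimoto's thyroiditis as the clinical contrast) but the machinery
is tissue-agnostic.

For each K in a range (conventionally 6..15):

1. K-means (k-means++, best of 10 restarts) clusters cells on their 22
   per-chromosome CNA features;
2. clusters depleted of reference cells (reference fraction below the global
   fraction) are called **malignant**;
3. the top 50 genes up-regulated in malignant cells (per-gene Wilcoxon
   rank-sum, Benjamini–Hochberg adjusted P < 0.05, ranked by log2 fold
   change) form the signature;
4. single-sample GSEA (ssGSEA, sum-of-running-differences ES with rank
   weights `(N − rank + 1)^0.25`) scores the signature in every bulk sample;
5. the two-sided Wilcoxon rank-sum P-value comparing tumor vs paratumor
   enrichment scores grades the K.

`selected_k = argmin_K P(K)`, ties broken toward smaller K. The package also
implements the companion composition test that flags **HT-associated
specific cells (HASCs)** — cell types with significantly higher proportion
in Hashimoto's-thyroiditis samples (global chi-square plus per-type 2×2
post-hoc tests) — and a synthetic-data module that generates negative-
binomial single-cell cohorts with planted copy-number clones and matched
bulk cohorts, so the whole method is testable without any download.

## Worked example

```python
from cnvselect import (SimulationConfig, generate_sc, generate_bulk, filter_counts,
                       lognormalize, order_genes, infer_cnv, select_k,
                       proportion_table, hasc_test)

config = SimulationConfig(seed=7)                      # 600 cells, 2000 genes, 2 clones
adata, positions, truth = generate_sc(config)
markers = sorted({positions["gene_id"].iloc[g]
                  for _cl, _c, s, e, f in config.cnv_segments if f > 1
                  for g in range(s, e)})
bulk = generate_bulk(config, markers)                  # 20 tumor + 20 paratumor samples

normalized = lognormalize(filter_counts(adata, 3, 200))
ordered = order_genes(normalized, positions)
profile = infer_cnv(ordered)                           # cutoff 0.1, window 101, clamp 3
result = select_k(ordered, profile.chrom_features.to_numpy(), bulk,
                  k_min=2, k_max=8, seed=7)
print(result.summary()[["K", "n_malignant_cells", "gene_set_size", "p_value", "selected"]]
      .to_string(index=False))
print(f"selected K = {result.selected_k}, "
      f"{result.malignant_mask().sum()} cells called malignant")

ht = hasc_test(proportion_table(adata.obs["cell_type"], adata.obs["is_HT"]))
print(f"global chi2 = {ht.global_chi2:.2f} (p = {ht.global_p:.2e}); HASCs: {ht.hascs}")
```

prints

```
 K  n_malignant_cells  gene_set_size      p_value  selected
 2                204             50 6.301848e-08      True
 3                217             50 6.301848e-08     False
 4                210             50 6.301848e-08     False
 5                207             50 6.301848e-08     False
 6                196             50 6.301848e-08     False
 7                192             50 6.301848e-08     False
 8                198             50 6.301848e-08     False
selected K = 2, 204 cells called malignant
global chi2 = 20.00 (p = 1.25e-03); HASCs: ['T_NK']
```

Every K here recovers the 200 planted malignant cells almost exactly (the
planted signal is strong, so the separation P-value saturates at its
combinatorial floor for all K and the parsimony tie-break picks K = 2), and
the composition test recovers the one cell type planted at doubled abundance
in HT samples. `truth` carries the planted clone of every cell for
verification.

The same pipeline runs from the shell:

```bash
cnvselect simulate --outdir data --seed 7
cnvselect kselect --mtx data/mtx --meta data/meta.tsv \
    --positions data/positions.tsv --bulk data/bulk.tsv \
    --kmin 2 --kmax 8 --seed 7 --out results
cnvselect hasc --meta data/meta.tsv --out results/hasc.tsv
```

(`cnvselect run --config config.yaml` executes preprocess → CNV → K
selection → HASC in one go and writes a JSON manifest with parameters, input
hashes and headline results.)

sklearn-style estimator classes (`CNVProfiler`, `SSGSEA`, `KSelector`) back
these functions for use inside sklearn pipelines; see `docs/methods.md` for
the full model description, parameter semantics, and design rationale.

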