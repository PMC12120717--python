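# epidriver

Discovery of **epigenetically activated driver genes** from paired
tumor/normal multi-omics data, built around the observation that some
oncogenic transcription-factor genes (notably homeobox genes in
esophageal squamous cell carcinoma) are switched **on** when the
normally unmethylated regulatory regions inside their gene bodies gain
DNA methylation.

The package is aimed at computational biologists who have per-CpG
bisulfite methylation counts, RNA-seq counts, variant summaries, a
protein-interaction network and survival follow-up for a paired
tumor/normal cohort, and who want a transparent, fully tested
implementation of the whole discovery chain — plus a seeded synthetic
data generator with planted ground truth so every stage can be
validated without any external download.

## What it computes

**Methylome.** After a per-sample coverage filter (≥ 4 reads per CpG),
under-methylated regions (UMRs) are called as maximal runs of ≥ 10
CpGs with mean methylation β ≤ 10%. Differentially methylated regions
(DMRs) merge consecutive sign-consistent differential CpGs and are
tested with a paired Wilcoxon signed-rank on per-sample region means;
reported DMRs satisfy |Δβ| ≥ 0.1 over ≥ 10 CpGs at
Benjamini–Hochberg FDR < 0.05, split into hyper-/hypomethylated.

**Transcriptome.** Genes are kept when their count exceeds 10 in at
least 5% of samples; outlier samples are removed when their
standardized network-connectivity Z score falls below −2. Paired
differential expression (median-of-ratios normalisation, paired
Wilcoxon, BH) labels genes up/down at |log2FC| ≥ 1 and FDR ≤ 0.05,
which partitions a homeobox list into activated (aHBG) and
unactivated (uHBG) sets.

**Integration.** Per-gene methylation change (promoter, gene body, or
normal-tissue gene-body UMRs) versus expression change by Spearman
correlation; set overlaps by upper-tail hypergeometric tests; SNV
density per kb and the pyrimidine-collapsed substitution spectrum with
CpG-context flags.

**Gene Risk Score.** Each gene *i* is scored as

```
GRS_i = Σ_j ρ_j · Z(X_ij)
```

over features X = (log2 fold change, |Δ methylation|, minor allele
frequency, network degree at STRING-style combined score ≥ 700), where
the weight ρ_j is the Spearman correlation of feature *j* with the
gene's missense-Z constraint score and Z(·) standardises each column.
Genes with missense Z ≥ 3.09 are flagged as intolerant to missense
variation; genes are ranked and the top *k* selected.

**Survival axis.** A per-sample pathway activity score for a gene set
(PLAGE: leading right singular vector of the per-gene z-scored
log-expression submatrix), a maximally selected log-rank cutpoint,
Kaplan–Meier curves and the two-group log-rank test.

**Synthetic data.** `epidriver.simulate` plants gene-body UMRs whose
tumor hypermethylation co-occurs with overexpression of known driver
genes, alongside consistent variant, network, constraint and survival
structure, all from a single seed with independent substreams per data
type.

## Worked example

```python
from epidriver.simulate import SyntheticConfig, generate_bundle
from epidriver import methylome as em, transcriptome as etx, \
    integration as eint, grs as egrs, survival as esurv

cfg = SyntheticConfig(n_genes=300, n_pairs=15, n_drivers=12,
                      n_homeobox=30, seed=7)
b = generate_bundle(cfg)

m = em.filter_by_coverage(b.methylome, min_cov=4)
umrs = em.call_umrs(m, m.samples_for("normal"))
dmrs = em.call_dmrs(m)
s = em.summarize_dmrs(dmrs)
print(f"UMRs called on normals: {len(umrs)}")
print(f"DMRs: {s.n_hyper} hyper / {s.n_hypo} hypo")

de = etx.differential_expression(etx.filter_low_expression(b.expression))
sets = etx.classify_homeobox(de, b.truth.homeobox)
table = eint.build_gene_delta_table(m, b.gene_models, de,
                                    "gene_body_umr", normal_umrs=umrs)
rho, p, n = eint.methylation_expression_correlation(table, sets.ahbg)
print(f"aHBG gene-body-UMR meth/expr Spearman rho = {rho:.2f} "
      f"(p = {p:.2e}, n = {n})")

act = esurv.stratify_by_activity(
    b.expression.counts[list(b.survival.data.index)],
    b.truth.axis_genes, b.survival)
print(f"log-rank chi2 = {act.logrank_chi2:.2f}, p = {act.logrank_p:.3f}")
```

prints

```
UMRs called on normals: 30
DMRs: 12 hyper / 0 hypo
aHBG gene-body-UMR meth/expr Spearman rho = 0.75 (p = 8.45e-03, n = 11)
log-rank chi2 = 5.80, p = 0.016
```

All 30 planted homeobox UMRs are recovered; the 12 hypermethylated
DMRs are exactly the planted driver UMRs; methylation gain inside
gene-body UMRs correlates positively with overexpression among
activated genes; and the high-activity patient group has significantly
worse survival.

The same chain runs from the shell:

```bash
epidriver generate --seed 7 --out bundle/
epidriver run-all --config run.yaml --out results/
```

`run-all` writes every intermediate table (UMRs/DMRs as BED6+, the DE
table, GRS ranking, activity groups, Kaplan–Meier curves) plus a
`report.json`, each stamped with the tool version, seed and parameter
hash.

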