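# Methods

This note documents the statistical procedures implemented in
`epidriver`, the defaults they ship with, the design decisions that were
genuinely open, and what the synthetic benchmark does and does not
demonstrate.

## Coordinates and data model

Intervals are 0-based half-open (BED convention); CpG positions are
1-based points (CpG-report convention). A CpG at position *p* belongs to
interval [s, e) iff s ≤ p−1 < e. CpGs are assumed to be reported on one
strand only (pre-merged input); a missing per-sample observation is
encoded as total count 0 and excluded from every mean — never imputed.
The TSS is strand-aware: the interval start on the + strand, the last
base on the − strand.

## Methylome

**Coverage filter.** Per-sample observations with fewer than `min_cov`
reads (default 4) are masked; sites with no remaining observation are
dropped. The threshold reflects the usual reliability floor for
single-CpG methylation estimates from bisulfite sequencing.

**Region means.** The mean methylation of a region is the unweighted
mean of per-site β values, each site first averaged across the requested
samples. Coverage-weighted means would bias toward deeply covered CpGs;
the unweighted form matches the "average methylation level" notion the
UMR definition is built on.

**UMR calling.** An under-methylated region is a maximal run of
consecutive CpGs with across-sample mean β ≤ `umr_max_meth` (default
0.10 — the defining property of these regions), at least `umr_min_cpgs`
CpGs (default 10, mirroring the DMR rule) and inter-CpG gaps ≤
`max_gap_bp` (default 1000, preventing runs from spanning CpG deserts).
This is deliberately a thresholded segmentation, not an HMM: the
definition itself is the property of interest, and a direct
implementation of it is exactly testable against planted segments.
For integration analyses UMRs are called on the **normal** samples and
held fixed, so that tumor hypermethylation cannot shift the region being
measured.

**DMR calling.** Candidates merge consecutive CpGs whose tumor − normal
mean difference shares sign and exceeds `min_diff`/2 in magnitude
(half the reporting threshold, so region boundaries are not clipped by
site-level noise), with the same 1-kb gap rule. Candidates with ≥
`min_cpgs` (10) CpGs are tested by a two-sided paired Wilcoxon
signed-rank on per-sample region means (≥ 3 complete pairs required),
corrected by Benjamini–Hochberg across candidates; reported regions need
q < `fdr` (0.05) and |region mean difference| ≥ `min_diff` (0.1). The
region statistic is nonparametric and paired by design: per-patient
region means are exchangeable under the null within a pair, and no
distributional model of β values is assumed. One published description
of this analysis mentions a 0.2 difference threshold in a figure legend
while the methods text states 0.1; the default here is 0.1 and the
threshold is configurable rather than silently reconciled.

**Context annotation.** Promoter windows default to −1500/+500 bp around
the TSS (strand-aware). Labels follow the precedence promoter >
gene body > intergenic with ≥ 1 bp overlap; ties across genes break by
nearest TSS, then lexicographic gene id, making annotation fully
deterministic.

**Metagene profile.** Gene bodies are scaled to [0, 1) strand-aware
(bin 0 at the TSS, default 100 bins); CpGs are averaged within
gene × bin, then across genes, so long genes do not dominate. Empty
bins are reported as missing, not zero.

## Transcriptome

Low-expression filtering keeps genes with count strictly > 10 in at
least ⌈5% of samples⌉ (minimum one sample). Sample QC computes each
sample's connectivity — the sum of its Pearson correlations with all
other samples on log2(count+1) profiles — and removes samples whose
standardized connectivity Z falls below −2 (single pass by default;
iterative mode available). When the connectivity spread is exactly
zero, Z is defined as 0 for all samples and nothing is removed.

Differential expression uses median-of-ratios size factors (computed
over genes expressed in every sample), a per-gene paired two-sided
Wilcoxon signed-rank on log2(normalised count + 1), and BH correction.
The fold change is the mean over pairs of log2((t + 0.5)/(n + 0.5)) on
normalised counts; the 0.5 pseudocount avoids log of zero and is
configurable. A gene is **up** iff LFC ≥ 1 and q ≤ 0.05, **down** iff
LFC ≤ −1 and q ≤ 0.05, else **unchanged** — the effect-size gate makes
the caller conservative by construction. Note the resolution floor of
the exact signed-rank test: with *n* pairs the smallest two-sided p is
2/2ⁿ, so cohorts below ~12 pairs cannot clear a 5% FDR over thousands
of genes regardless of effect size. A reader for externally produced DE
tables (gene, lfc, q) lets the downstream stages run on output of
model-based callers instead.

Homeobox classification splits a supplied gene list into activated
(status up) and unactivated (down **or** unchanged) sets; ids absent
from the DE table are ignored with a warning, and the two sets always
partition the known ids.

## Integration

Methylation/expression coupling is measured by Spearman correlation
between per-gene methylation change (tumor − normal over a chosen
region class) and expression log2 fold change, per gene set. Ties get
average ranks; the two-sided p uses the t-approximation for n > 9 and
exhaustive permutation enumeration for n ≤ 9. Genes lacking the region
class (e.g. no normal-tissue gene-body UMR) are absent from the table,
never zero-filled. Set-overlap enrichment is the upper-tail
hypergeometric probability P(X ≥ overlap). SNV density divides the
variant count inside a region by its length in kb (full interval
length — coding length is not modelled). The substitution spectrum
strand-collapses purine-reference SNVs to the six pyrimidine classes
with reverse-complemented trinucleotide context; the CpG flag requires
G immediately 3′ of the collapsed C. Indels are excluded and counted
separately, so class counts always sum to the number of retained SNVs.

## Gene Risk Score

Features per gene: expression log2 fold change; absolute methylation
change (default region class: the gene body, which exists for every
gene — the gene-body-UMR class is only defined where a normal-tissue
UMR was called); mean minor allele frequency over the gene's SNVs (0
without variants — no aggregation rule is canonical, the mean is the
simplest symmetric choice); and network degree counting distinct
partners over edges with combined score ≥ 700 (deduplicated,
self-edges ignored). Weights are the Spearman correlations of each
feature with the per-gene missense-Z constraint score, computed over
**all** genes in the assembled table; constant columns get weight 0
with a warning.

Because the raw features live on incommensurate scales (MAF ~10⁻³,
degree ~10¹), each column is z-scored before the weighted sum by
default; a raw mode is available. Standardisation makes the score
equivariant to positive rescaling of any feature (Spearman weights are
already rank-based), which the tests assert. Ranking is descending by
score with lexicographic gene-id tie-breaks, so the top-k selection is
deterministic. Missense Z ≥ 3.09 flags genes as intolerant to missense
variation (the conventional constraint cutoff).

## Survival axis

**PLAGE activity.** Gene-set rows of log2(count+1) are z-scored per
gene (sample sd, ddof 1) and the activity is the leading right singular
vector of the resulting genes × samples matrix. The SVD sign is
arbitrary, so it is fixed to correlate non-negatively with the mean
z-scored expression of the set — "high activity" then means high axis
expression. Zero-variance genes raise an error naming the gene.
Whether to feed counts, TPM or normalised values is not canonical;
log2(count+1) is the default and any expression layer can be passed.

**Cutpoint.** Candidates are midpoints between consecutive sorted
unique scores leaving at least `min_prop` (default 0.1) of samples on
each side; the candidate maximising the absolute standardized log-rank
statistic wins, ties to the smaller cutpoint. No selection-adjusted
p-value is applied: the reported p is the plain log-rank p at the chosen
cutoff, which is optimistic under cutpoint optimisation — a documented
caveat, not a bug.

**Log-rank and Kaplan–Meier.** The two-group log-rank statistic sums
observed − expected events with hypergeometric variance at each distinct
event time (variance term zero when only one subject remains); χ² is
referred to one degree of freedom. The product-limit estimator counts
samples censored exactly at an event time as still at risk for that
time. Both implementations are cross-checked in the test suite against
lifelines as an independent oracle.

## Synthetic data generator

The generator emulates the discovery setting at desk scale: a single
synthetic chromosome with genes of 3 kb every 8 kb, CpGs every 50 bp in
genes and every 500 bp between them; every homeobox gene carries a
central 20-CpG gene-body UMR at β = 0.05 on a β = 0.8 background;
planted drivers gain tumor methylation inside that UMR and are
overexpressed, with a shared per-driver effect scale (uniform on
[0.5, 1.5]) multiplying both the methylation gain (base 0.3) and the
log2 fold change (base 2.0) — this co-variation is what makes the
methylation/expression correlation recoverable. Methylation counts are
beta-binomial (concentration 30) at Poisson(30) coverage with a 5%
low-coverage admixture that deliberately exercises the ≥ 4-read filter.
Expression is negative-binomial (dispersion 0.1) around log-normal
baselines with uniform library-size factors. Drivers carry 3× the
background SNV rate with 70% C>T-at-CpG substitutions and inflated
allele frequencies, denser high-score network edges, and missense Z
drawn around 3.5 versus a standard-normal background. Survival times
are exponential with hazard 0.02/month multiplied by 2 per unit of a
latent per-patient activity that also shifts axis-gene expression;
censoring is uniform administrative on 12–60 months. A single root
seed drives independent substreams per data type, so the bundle is
byte-reproducible and regenerating one block leaves the others
untouched.

The default benchmark — 2000 genes, 30 tumor/normal pairs, 40 drivers
among 100 homeobox genes, seed 1 — is the package's reference study
condition; null-calibration runs use 200 replicates of small matrices
(200 CpGs × 8 pairs; 300 genes × 10 pairs) and the survival power study
uses 100 cohorts of n = 200.

**What passing does not show.** The generator draws independent CpGs
and genes: no co-methylation beyond the planted blocks, no CpG islands,
no copy-number or purity effects, no batch structure, no
mutation-signature mixture, and a network with only degree (not
modular) structure. Recovery of planted effects under these conditions
validates the implementation logic and its calibration, not performance
on real tumor cohorts, where effect sizes are smaller and confounding
is real.

## Known limitations

- The DMR caller's sign-consistent merging can split a true region at a
  noisy interior CpG; at reference coverage and sample size this is
  negligible, at low coverage it shortens calls rather than inventing
  them.
- The signed-rank DE test is underpowered below ~12 pairs (exact-p
  floor) and ignores count overdispersion structure a model-based
  caller would exploit.
- The maximally selected cutpoint p-value is not adjusted for
  selection.
- MAF and connectivity aggregation per gene are simple summaries (mean
  AF, raw degree); alternatives (max AF, weighted degree) are easy to
  swap in but not implemented.
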