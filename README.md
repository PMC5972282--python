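# pleiorice

Why are agronomic traits correlated? In structured inbred panels — the
motivating case is a rice diversity panel of indica and japonica accessions
phenotyped for heading date (HD), grain number per panicle (GNP), panicle
number (PN) and kilo-grain weight (KGW) in a short-day and a long-day
environment — a trait correlation can arise from three distinct genetic
mechanisms:

1. **pleiotropy** — one SNP or gene moves both traits (pSNPs / pGenes);
2. **linkage** — distinct causal variants in LD, so one trait's QTL
   "hitch-hikes" association signal for the other;
3. **interaction** — two genes in a shared biological pathway jointly
   affecting a trait pair through a genotype × genotype term (iGene pairs).

`pleiorice` implements the full dissection as a reusable, tested pipeline,
plus a synthetic-panel generator so every stage can be exercised and
calibrated without any real data.

## Method core

Per trait/population/environment the association scan fits the mixed
linear model

```
y = μ + PCγ + xβ + u + e,    u ~ N(0, σg²K),  e ~ N(0, σe²I)
```

with VanRaden kinship K and genotype principal components; variance
components by REML on the spectral decomposition of K, with P3D (variance
ratio estimated once under the null) as default. Genome-wide significance
comes from a structure-preserving permutation test: Y is split into the PC
regression fit Ps and residual G, G is reshuffled to build pseudo-phenotypes
Ps + Gr, and the threshold is −log₁₀ of the smallest p-value observed in
`n_perm` re-scans. Significant SNPs are chained into QTL bins (≥ 3 SNPs,
adjacent gaps < 70 kb); overlapping bins of two traits in the same scan
context form a pleiotropic QTL. Inbred-haplotype r² (counted directly,
no phasing) quantifies linkage between the two traits' significant-SNP
sets; correlating that LD with per-bin differences of phenotypic variance
contributions (PVC, marginal single-SNP R²) yields the hitch-hiking
statistic r_X2Y. Allele and haplotype effects are classified
increased/decreased by one-way fits with Tukey HSD, combined into
same-direction (SD) vs opposite-direction (OD) classes, and tabulated over
indica/japonica × landrace/improved variety classes. Finally, pathways
shared by associated genes of ≥ 2 traits are scanned for cross-trait gene
pairs with a significant dosage-product interaction (BH-adjusted).

See `docs/methods.md` for model details, defaults, and what the synthetic
generator does and does not emulate.

## Worked example

A config drives everything; simulation is a first-class input:

```yaml
# panel.yaml
simulate:
  seed: 2
  n_snps: 6000        # 266 accessions (157 indica / 109 japonica) default
permutation:
  n_perm: 200
  seed: 3
```

```
pleiorice run-all panel.yaml -o run/
```

or equivalently `pipeline.run_pipeline({...}, "run/")` from Python. The run
directory contains one TSV per stage. A few of the numbers this exact
config prints:

`thresholds.tsv` — permutation thresholds per scan (here: the HD scan in
the full panel at SY rescanned 97 candidate SNPs in 200 permutations; the
lowest permutation p-value 2.14e-4 sets the significance line at
−log₁₀p = 3.67, above which 16 SNPs fall):

```
population  environment  trait  n_perm  p_perm      threshold_neg_log10  n_candidates  n_significant
full        SY           HD     200     0.00021384  3.6699               97            16
full        SY           GNP    200     0.00022148  3.6547               102           14
```

`qtl_bins.tsv` — 28 QTL bins are called, e.g. an HD bin on chr1 spanning
1,355,228–1,363,994 bp with 10 member SNPs and peak −log₁₀p = 9.58.

`pqtls.tsv` — one pleiotropic QTL: GNP and HD bins overlap on chr1 in
japonica at CS, sharing 3 pSNPs and 1 pGene, with mean cross-set r² = 0.67
— a locus where the planted HD/GNP pleiotropy was recovered and its local
LD measured:

```
chrom  start    end      trait_a  trait_b  population  environment  n_psnps  n_pgenes  mean_r2
chr1   1329300  1361305  GNP      HD       japonica    CS           3        1         0.671
```

`trait_correlations.tsv` — the planted correlation structure is visible
phenotypically: HD–GNP r = +0.21 (p = 4.5e-4) and GNP–PN r = −0.28
(p = 3.3e-6) in the full panel at SY, matching the configured
positive-HD/GNP, negative-GNP/PN architecture.

Ground truth for every planted causal element is written to `truth.tsv`,
so recovery can be checked mechanically.

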