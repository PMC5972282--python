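# Methods

`pleiorice` dissects why quantitative traits are correlated in a structured
inbred panel, separating three genetic mechanisms: true pleiotropy (one
variant or gene moving two traits), linkage (distinct causal variants in
LD, so one trait's QTL "hitch-hikes" signal for the other), and gene–gene
interaction within a shared biological pathway. The pipeline was designed
around a rice diversity panel — two diverged subspecies (indica/japonica),
landrace and improved varieties, four traits (heading date HD in days,
grain number per panicle GNP, panicle number PN, kilo-grain weight KGW in
grams) measured in a short-day (SY) and a long-day (CS) environment — but
every step is scale- and organism-agnostic.

## Association model

Per trait, population (full / indica / japonica) and environment, each SNP
is tested with the mixed linear model

    y = mu + PC gamma + x beta + u + e,   u ~ N(0, sg^2 K),  e ~ N(0, se^2 I)

where K is the VanRaden genomic relationship matrix, `K = ZZ' / (2 sum
p_j(1-p_j))` on centered dosages, and the principal components are those of
the centered, variance-scaled genotype matrix (defaults: 3 PCs for the full
panel, 2 within a subspecies; PC signs fixed by making the largest-magnitude
loading positive).

Variance components are estimated by REML on the profile likelihood of
`lambda = sg^2/se^2` using the spectral decomposition of K (one
eigendecomposition per population, reused everywhere): a 41-point grid on
log-lambda in [-10, 10] followed by bounded Brent refinement to 1e-6.
The default mode is P3D — lambda estimated once under the null model and
reused per SNP, each SNP test reducing to a weighted regression in the
rotated basis. `mode="exact"` re-estimates lambda per SNP. The per-SNP test
is a Wald t-test with the residual variance re-estimated from the SNP
model's weighted RSS (df = n − p), so with K = I and no covariates the
p-values coincide with OLS F-tests exactly — a tested limit. Compression of
accessions into kinship groups is deliberately not emulated: plain
MLM + P3D is the transparent, reproducible core, and no compression
settings exist to replicate.

PVC (phenotypic variance contribution) is operationalized as the marginal
single-SNP R² — the squared Pearson correlation between dosage and
phenotype over pairwise-complete accessions. It is simple, coding-invariant
and reproducible; a model-based increment was considered and rejected
because every downstream use (hitch-hiking differences) only needs a
comparable per-SNP effect-size scale.

## Permutation significance threshold

The observed phenotype is decomposed as Y = Ps + G, with Ps the
least-squares fit of Y on [1, PCs] and G the residual. Each permutation
reshuffles G uniformly across accessions (structure component Ps held
fixed), rescans with identical model settings, and the threshold is
`-log10(P_perm)` with P_perm the smallest p-value seen in any permutation
(n_perm default 1,000). A per-permutation-minimum quantile rule is
available (`threshold_rule="quantile"`) because the literal global minimum
grows stricter without bound in n_perm; the literal rule stays the default.

Candidate filtering — rescanning only SNPs with −log10(p) > 2 in the
observed scan — is supported and used by the pipeline as a compute
shortcut. It is only statistically neutral when `n_perm × |candidates|`
dwarfs the effective number of genome-wide tests: the candidates are the
observed scan's selected extremes, so a small permutation budget over them
yields milder minima than the observed genome-wide minimum and the
threshold becomes too lenient. At desk scale we measured family-wise error
≈ 0.6 with the filter (100 permutations, 2,000 SNPs) versus 0.02 without
it; `permutation_scan` therefore defaults to scanning all SNPs, and the
calibration test uses that exact form. At the scale the shortcut was
designed for (1,000 permutations, millions of SNPs, tens of thousands of
candidates) the distortion is negligible.

## QTL bins, pleiotropy, LD and hitch-hiking

Significant SNPs are chained per chromosome: adjacent significant SNPs
closer than 70 kb (strict) join one chain; chains with ≥ 3 members become
QTL bins (span = first to last member, peak = minimum p). Two bins from
different traits in the same population and environment form a pleiotropic
QTL (pQTL) when their intervals overlap by ≥ 1 bp (touching is not
overlapping under inclusive coordinates); pSNPs are the shared significant
SNPs, pGenes are genes whose span holds ≥ 1 significant SNP of each trait,
and the stricter class additionally requires a pSNP inside the gene.
Percentages are reported relative to each trait's total QTL count, rounded
half-up to two decimals.

LD is computed assuming inbred haplotypes: each accession homozygous at
both sites contributes one haplotype, so `r² = (p_AB − p_A p_B)² /
(p_A(1−p_A) p_B(1−p_B))` by direct counting, no phasing or EM (on such data
r² equals the squared Pearson dosage correlation — used as a cross-check
oracle). Heterozygous/missing calls are excluded pairwise; undefined values
propagate as NaN sentinels, never as zeros. A pQTL's LD is the mean r² over
the Cartesian product of the two traits' significant-SNP sets, and tier
counts use strict cutoffs 0.2/0.4/0.6/0.8.

The hitch-hiking statistic for direction X→Y correlates, across pQTLs of a
trait pair, the mean cross-set r² with ΔPVC = (mean PVC-to-Y of the Y bin's
SNPs) − (mean PVC-to-Y of the X bin's SNPs), both read from the Y scan.
Strong LD lets X's QTL proxy Y's causal variant, shrinking ΔPVC, so the
correlation is negative when linkage drives the shared signal. Mean (not
peak) PVC aggregation is the default; at least 3 usable pQTLs and
non-degenerate vectors are required, otherwise the NaN sentinel is
returned.

## Effect classes

Allele or haplotype effects are called by a one-way fixed-effects model
with all-pairs Tukey HSD at alpha = 0.05: a group significantly above at
least one other group and below none is "increased" (I), the mirror case
"decreased" (D), otherwise NS. Tukey HSD replaces Duncan's multiple range
test (which does not control family-wise error and has no canonical open
implementation); alpha and minimum group size (2) are configurable. A unit
with calls on two traits is SD when directions agree, OD when they oppose,
UNCLASSIFIED when either is NS — reported explicitly, with percentages
computable over classified units only or over all units. Gene haplotypes
are formed from homozygous calls over the SNPs in the gene span (carriers
with any het/missing member call excluded) and pooled into a "rare" class
below frequency 0.05.

## Pathways and interaction (iGene) scan

A pathway is shared when ≥ 2 distinct genes carry significant SNPs for ≥ 2
distinct traits. Within each shared pathway, every cross-trait gene pair is
tested on both traits of the pair with the two-locus model
`trait = mu + x1 + x2 + x1·x2` at the genes' representative SNPs (their
minimum-p significant SNP, ties to the smaller position), centered dosages.
The product term's Wald p is Benjamini–Hochberg adjusted across all pairs
per trait pair, and pairs with q < 0.05 on at least one trait are reported.
This is the single largest methodological gap being filled: no statistical
model, threshold or correction was specified for the original interaction
analysis, so the most standard two-locus operationalization with FDR
control was adopted. Nearly collinear representative SNPs (r² > 0.95) make
the interaction unidentifiable and the pair is skipped with a warning.

## Synthetic panel generator

The generator produces the study conditions every test runs under, so its
realism boundaries matter.

Genotypes: each inbred accession carries, per chromosome, a latent
standard-normal AR(1) process with correlation `exp(-gap/L)` between
adjacent SNPs (L = `block_length_bp`, default 150 kb — the rice LD scale);
the haplotype allele is the indicator that the latent value falls below the
normal quantile of the SNP's subpopulation frequency, and dosage = 2 ×
allele (fully homozygous). Ancestral frequencies are the probit transform
of another AR(1) walk (marginally uniform on (0.05, 0.95), locally
coherent), and subpopulation divergence follows Balding–Nichols (F default
0.2) drawn through an AR(1)-correlated probit so divergence is coherent
within haplotype blocks. The result: exact marginal frequencies, adjacent
r² ≈ 0.8 at the default 1 kb spacing decaying monotonically to ~0 beyond
two block lengths, independent chromosomes, and a first PC that separates
the subspecies. An earlier founder-block-copying design was discarded
because its LD did not decay with distance and its frequency spectrum
collapsed. The default spacing (1 kb) keeps the density-to-LD-length ratio
close to a deeply genotyped panel, so significant-SNP clusters span the ≥ 3
SNPs the binning rule expects; 2,000–20,000 SNPs on 4 chromosomes is the
desk-scale envelope used throughout.

Phenotypes: per environment, each trait is built on a unit-variance
baseline — polygenic background `~ N(0, h² K_norm)` (per-trait h² defaults
0.35–0.5) plus residual noise correlated across traits (defaults: HD–GNP
+0.3, GNP–PN −0.3, PN–KGW −0.1) — and causal effects are added on top in
baseline-SD units via standardized dosages. The architecture plants all
three mechanisms: pleiotropic SNPs (default one SD pair +HD+GNP, one OD
pair +GNP−PN), linked pairs < 70 kb apart affecting different traits, and
interacting SNP pairs with a product-term effect plus modest main effects
(so their genes are discoverable by association, as real candidate pathway
genes are). Background single-trait QTLs alternate between
environment-specific activity to emulate low QTL overlap between
environments; environments also differ by additive trait shifts. Traits are
reported in field units (days/grains/panicles/grams) by affine scaling.

What the generator does not emulate: real chromosome lengths and MAF
spectra, admixed or clinal structure beyond two clean subpopulations,
residual heterozygosity, genotyping error and missingness (off by default),
dominance, and G×E beyond effect rescaling. Passing tests therefore
demonstrate correctness and calibration of the machinery under idealized
inbred block-LD conditions, not performance on any real panel.

## Numerical and degenerate-input conventions

All coordinates are 1-based inclusive internally; BED I/O is 0-based
half-open through a single conversion routine. Dosage 1 (het) is allowed in
matrices, excluded from LD/haplotype analyses. Monomorphic SNPs get missing
statistics, never fabricated p-values. K gets a 1e-6 ridge before
eigendecomposition. Percentages round half-up (decimal arithmetic, not
binary float rounding). Every stochastic stage takes an explicit seed;
pipeline reruns with the same config are byte-identical, and per-scan
permutation seeds are derived from the config seed with a stable CRC of the
scan key.

## Problem sizes

Defaults were chosen so the full test suite runs in minutes on one CPU:
panels of 266–300 accessions with 1,000–6,000 SNPs for statistical
properties (50 null datasets × 100 permutations for calibration; 20 seeds
for recovery and direction checks; 10–25 seeds for rate estimates), and a
6,000-SNP default panel for the end-to-end demonstration run. The methods
contain nothing scale-dependent besides these fixture sizes.
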