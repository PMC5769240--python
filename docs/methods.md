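# Methods

## Study model

The package implements an ensemble integration of eQTLs with a
case-control GWAS for a tissue cohort of modest size (default 86 cases,
31 controls — severe-COPD-study proportions) plus a larger independent
GWAS cohort (default 5000). All statistics operate on standard in-memory
containers (pandas DataFrames) and plain-text formats (TSV matrices,
DS-field VCF, PLINK-style `.assoc` summaries). Genomic coordinates are
1-based inclusive throughout, including the BED-like annotation tables.

## eQTL scan

Association of expression on dosage is ordinary least squares with
covariates (age, sex, pack-years, ancestry PCs, and top-k expression PCs;
k defaults to 13 and is a plain config parameter — no iterative PC
selection is attempted). The full scan residualises expression and
dosage against the covariates once (Frisch–Waugh–Lovell) and obtains
every pair's t-test from cross-products with residual degrees of freedom
n − rank(C) − 1; the per-pair solver `fit_association` is retained as an
independent route and the two agree to 1e-8 relative tolerance.

Cis/trans assignment: a pair is cis iff same chromosome and the SNP
position lies in [gene start − w, gene end + w], w = 500 kb, boundaries
inclusive; the window anchors at the annotated interval, not the TSS.
BH-FDR is applied separately within the cis and the trans analysis (the
two are reported as separate analyses with separate counts), so a
"false-discovery proportion ≤ target" statement is evaluated per
analysis family. Monomorphic SNPs and zero-variance probes are dropped
with counts recorded in provenance, not raised. Dosages are accepted as
continuous values in [0, 2].

Numerical edge cases: a fit with numerically zero residual sum of
squares reports the smallest representable p (a perfect signal), unless
the slope is also zero, in which case the record is a null fit (t = 0,
p = 1). Features numerically constant after covariate adjustment are
treated the same way.

## GWAS integration

The intersection keeps GWAS SNPs below the suggestive threshold
(10⁻⁴) that are eSNPs at q < 0.05, reporting each SNP's best (minimum
eQTL p, ties by probe id) eGene. Enrichment uses the hypergeometric
upper tail with the universe defined explicitly as the SNPs present in
both the eQTL scan and the GWAS; the universe definition is written into
provenance because the fold depends on it. Permutation-null summaries
shuffle the case-control labels of the simulated cohort itself
(preserving class totals) and recompute the same allelic logistic score
test used for the observed synthetic GWAS, keeping observed and null
summaries exchangeable under the null.

## Gene scoring

The score is a Wakefield-style approximate Bayes factor evaluated at the
GWAS z-score of each qualifying eSNP, on the log₁₀ scale with the
sampling variance normalised to V = 1 and prior effect variance
W = 0.21 (default; configurable). z is recovered from the two-sided
GWAS p as Φ⁻¹(1 − p/2) because signed effects are not available from
p-only summaries. Qualification follows the ensemble thresholds (cis
p < 10⁻³, trans p < 10⁻⁶, SNP present in the observed GWAS and every
permutation); probes collapse to gene symbols keeping the best eQTL p
per (gene, SNP). Greedy distance pruning (1 Mb default; records visited
by ascending eQTL p, a record kept iff no kept record on the same
chromosome is strictly closer than the window) limits LD double
counting; r²-aware pruning is out of scope, and the unpruned mode is
available (`ScoreConfig(prune=False)`).

Empirical p-values use the add-one estimator
(1 + #{null ≥ obs}) / (1 + N). The default pools null scores across
genes and permutations: 50 permutations alone resolve only to 1/51,
while pooling reaches ~1/(50·n_genes), which is what makes small
empirical p-values attainable from 50 shuffles. Pooling assumes the
null score distribution is comparable across genes; it is exact for
single-eSNP genes (the common case at these thresholds) and
approximate otherwise — the per-gene mode is provided for the
conservative alternative.

## Network and communities

Edges are thresholded eQTLs between eSNP (rsID) and eGene (gene symbol)
nodes; eSNPs absent from the GWAS are excluded. "Single-edge" exclusion
is read as removing isolated SNP–gene pairs — edges whose two endpoints
both have degree 1 — since such edges create no additional connections;
for the pair rule one pass is already a fixed point, and the stricter
leaf rule (any degree-1 endpoint, iterated) is available behind a flag.
Multiple probes supporting one edge are recorded in provenance only; the
network is unweighted.

Barber's bipartite modularity is evaluated sparsely (edge sum minus
community degree products over m²). BRIM alternates exact one-side
updates: with gene labels fixed Q decomposes over SNP nodes, so the
simultaneous per-node argmax is optimal for that side, and Q is
non-decreasing; iteration stops when the improvement falls below 1e-10
or at 100 sweeps (best-so-far returned with a warning flag). Nodes are
swept in sorted order and ΔQ ties break toward the lowest community id,
making runs deterministic under a seed. Initial labels come from seeded
asynchronous label propagation on the gene one-mode projection (genes
linked by shared eSNPs, weight = shared count), with each SNP taking the
majority label of its gene neighbours. Because BRIM cannot create labels
beyond its initialisation, `detect_communities` restarts from the
label-propagation init, an all-singleton init (which realises the
maximum possible label count) and a few seeded random partitions,
keeping the highest-Q fit. Community ids are compacted to 1..C.

## Validation

Differential expression and methylation are covariate-adjusted linear
models on case-control status; the methylation table also retains the
raw (unadjusted) case-control mean beta difference, and the 5% effect
filter is strict (|difference| > 0.05) on that raw value. Fisher's
method combines each community's probe p-values (all probes of member
genes) and its effect-filtered CpG p-values; a side with no qualifying
features yields an absent meta-p. Fisher assumes independence and
community probes are correlated; the output is reported as a
meta-analysis p-value with that caveat, matching standard usage, and a
Brown-style correction (Kost–McDermott moment matching, requiring the
feature correlation matrix) is provided but off by default. Validation
status: both meta-p < 0.05 → `validated_both`; exactly one →
`validated_one`; otherwise `not_validated`.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not a real genome:

- **Genotypes** — two haplotypes per subject, fixed-size LD blocks
  (default 10 SNPs). Within a block each SNP's latent uniform is copied
  from the previous SNP with probability `ld_rho` (default 0.8),
  otherwise drawn fresh; the allele is the indicator u < maf. Copying on
  the uniform scale keeps every marginal frequency exactly at its maf
  (even with heterogeneous mafs) while giving r² → 1 between equal-maf
  neighbours as rho → 1. Dosages are hard calls in {0,1,2}; panel mafs
  are drawn in (0.05, 0.5], reflecting the common-variant filter.
- **Expression** — planted betas (expression-SD units per allele) times
  dosage, plus standardised-covariate terms with seeded coefficients,
  plus N(0, noise_sd) noise. Optional case-control shifts (`de_effects`)
  emulate disease differential expression on top of the genetic signal.
- **Phenotype** — logistic liability over the causal dosages; the
  intercept is tuned by root finding so the expected case count matches
  the quota, then repeated Bernoulli passes fill the case/control quotas
  exactly, preserving the genotype-risk gradient.
- **GWAS** — an independent cohort simulated from the same panel and
  disease model (balanced by intercept tuning), tested per SNP with the
  allelic logistic score test (Armitage trend test); monomorphic SNPs
  are flagged with p = 1.
- **Methylation** — beta values as the logistic transform of a Gaussian
  latent (sd 0.5). Latent means are calibrated by Gauss–Hermite
  quadrature and root finding so the *expected beta-scale* case-control
  difference equals the planted effect despite the nonlinear transform.

Default plan (the desk-scale study): 117 subjects (86/31), 2000 SNPs on
two chromosomes at 5 kb spacing, 200 genes (a few with two probes),
500 CpGs, 30 cis-eGenes (|beta| 0.8–1.2), 8 trans effects (0.8), five
"shared" genes whose eSNPs carry disease log-odds 0.5 per allele, DE
shifts of 0.5 SD and methylation shifts of 0.08–0.12 beta units on the
shared genes' features. No published effect-size distribution exists for
these loci; the defaults are chosen so a 117-subject scan has realistic
(incomplete) power for cis effects while the 5000-subject GWAS detects
the shared eSNPs reliably, and they live in the plan, not in code paths.
The recovery-experiment design (`shared_gene_design`) plants one strong
cis eSNP per gene (|beta| 1.2 at maf ≥ 0.25, one per LD block) because
that experiment probes the score's ranking behaviour rather than scan
power.

What the generator does not emulate: realistic genome-wide LD maps,
imputation dosage uncertainty, population structure (ancestry PCs are
injected as covariates, not simulated admixture), probe cross-
hybridisation, or cell-type composition effects on methylation. Passing
tests therefore demonstrate the statistical machinery under the model's
assumptions, not performance on real cohort data.

## Problem sizes and determinism

Simulation-based checks use desk-scale sizes: null-calibration runs use
117-subject cohorts of 200 SNPs × 50 genes with several hundred
replicates (the false-discovery proportion estimator needs a standard
error well under the margin it is tested against); recovery runs use 20
replicates of the 1000-SNP / 50-gene design with a 5000-subject GWAS and
50 permutations each. Every stochastic routine takes an explicit seed,
sub-seeds are derived through `numpy.random.SeedSequence`, and repeated
runs are bit-identical.

## Known limitations

- The LBF kernel is a reconstruction of signature matching on p-only
  summaries; hierarchical priors over cis/trans configurations are not
  implemented, and the kernel is a pluggable function.
- Fisher meta-p values inherit the independence assumption noted above.
- The enrichment fold depends on the universe; only the both-analyses
  universe is computed.
- BRIM finds local optima; restarts mitigate but do not guarantee the
  global maximum on large networks.
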