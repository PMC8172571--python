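# Methods

This note records the statistical model, estimators, generator scope, and
numerical conventions behind `circnet`.

## Design and data model

All analyses assume a two-group (Sham, ICH), two-timepoint (day 7, day 28)
bulk RNA-seq design with `n_reps` replicates per group x timepoint cell.
Counts for feature *i* in sample *j* are modelled negative-binomially,

    K_ij ~ NB(mean = s_j * q_i * f_ij,  dispersion = alpha_i)

with sample depth factor `s_j`, baseline abundance `q_i`, and condition
effect `f_ij` (2^lfc in ICH samples of differential features, 1 otherwise).

## circRNA catalog

- **Caller intersection.** Two callers' back-splice-junction (BSJ) calls are
  matched on (chromosome, start, end, strand). With `slack > 0`, candidates
  within that many nucleotides on both coordinates are paired nearest-first
  and one-to-one. Junction reads of a merged call are the per-sample maximum
  of the two callers (a conservative union of evidence).
- **Read-support filter.** A call is kept when at least one replicate set
  (group x timepoint) has `min_reads` (default 2) junction reads in *every*
  one of its samples; requiring a full set guards against single-library
  artifacts while not penalizing signals confined to one condition or time.
- **Classification.** Against a GTF: *exonic* if the circle span falls inside
  a gene and either boundary touches an annotated exon boundary or overlaps
  an exon, *intronic* if it lies inside a gene without exon contact,
  *intergenic* otherwise. Coordinates are 1-based inclusive at file
  boundaries and 0-based half-open internally. Class percentages are
  reported to two decimals with round-half-up.

## Normalization and differential expression

- **TPM** = count * 1e6 / library size, **FPKM** = count * 1e9 /
  (length * library size), with library size the per-sample sum over the
  species' features. TPM columns therefore sum to exactly 1e6.
- **DE test** (per species, per timepoint, ICH vs Sham): size factors by
  median-of-ratios; gene-wise method-of-moments dispersions (floored at
  1e-8) shrunk 50/50 toward a fitted `a0 + a1/mu` trend; Wald statistic on
  the difference of log means with delta-method variance
  `Var(ln mu_hat) ~ (1/n^2) * sum_j 1/(mu s_j) + alpha/n`, referred to the
  standard normal. Fold changes use a 0.5 pseudocount. P-values are
  Benjamini-Hochberg adjusted; features with adjusted p < 0.05 are called
  up/down by the sign of log2FC. Monte-Carlo calibration: the raw-p false
  positive rate at 0.05 is 0.052-0.060 for dispersions 0.02-0.2 at n = 4 vs 4.
- The normal reference (rather than a t with ad-hoc degrees of freedom) was
  chosen empirically: simulated null Wald statistics at n = 4 have sd ~ 1.02,
  and the normal reference keeps the size closest to nominal.

## miRNA targeting

Seed = miRNA positions 2-8. Target (DNA, sense strand) sites are the
canonical classes: **8mer** (perfect Watson-Crick match to positions 2-8
plus an A opposite position 1), **7mer-m8** (match to 2-8), **7mer-A1**
(match to 2-7 plus the A1 anchor), scored 3/2/1. Optionally G:U wobble
pairs are accepted within the seed match. Candidate pairs keep only
differentially expressed miRNAs and targets; multiple sites on one target
collapse into a `site_count`.

## ceRNA network

Triplets are all (circRNA, miRNA) x (miRNA, mRNA) pairs joined on the shared
miRNA. Pearson r is computed on log2(normalized + 1) values across the
samples of one timepoint (pooled Sham+ICH by default, or ICH-only), with the
exact two-sided p from `t = r * sqrt((n-2)/(1-r^2))` on n-2 df. Constant
expression vectors make r undefined; such triplets are flagged `degenerate`
and never selected. **Hub selection** requires both correlations strictly
below -0.5 and both p-values at most 0.05 (boundary semantics: r = -0.5
excluded, p = 0.05 included). Networks export to GraphML (typed node/edge
attributes) and SIF.

Note that in the pooled cohort, opposite-direction fold changes alone induce
negative correlations; the ICH-only cohort isolates the within-group
(latent-activity) component of the sponge signal.

## Group discrimination

Signatures stack the DE features of one or more species as rows of
log2(normalized + 1), z-scored per feature. Samples are clustered
hierarchically (Euclidean distance, average linkage, dendrogram cut at k),
and accuracy is the fraction correct under the optimal one-to-one
cluster-to-class (Hungarian) matching — defined for k equal to the number of
classes (k = 4 over all samples, k = 2 within a timepoint). PCA (SVD of the
centered sample x feature matrix) reports PC1/PC2 scores and percentages of
variance; numerically zero total variance (identical samples) is flagged
rather than divided through.

## Synthetic generator: scope and mechanics

The generator produces everything the pipeline consumes, with full ground
truth. Per `SimConfig` (defaults in parentheses):

- Baselines `q_i` are log-normal (sigma 1.5); library sizes vary uniformly
  +/-20% around `depth_mean` (1e6); NB dispersion `nb_dispersion` (0.05).
- A fraction `de_fraction` (0.1) of each species is differential with
  |log2FC| drawn from `log2fc_range` ((1, 3)) and random sign; triplet
  members are always differential with coherent directions (circRNA and mRNA
  together, miRNA opposite).
- `n_triplets` (5) sponge trios get a latent activity z ~ N(0,1) per sample
  (independent across timepoints) scaling means by 2^(+/- strength * z),
  strength in [0, 1].
- Sequences: random-background miRNAs (RNA, 22 nt), circRNA (500 nt) and
  3'UTR (1000 nt) DNA; for each triplet the reverse complement of the seed
  is embedded at a recorded offset, followed by a non-A base so the planted
  site is a clean 7mer-m8.
- Caller tables: both callers report every true locus (placed exonic /
  intronic / intergenic per the configured fractions on a generated GTF) and
  each adds private false positives (`fp_frac_a/b`); a `lowcount_frac`
  subset of true circRNAs is forced to fail the read-support rule.

Three independent RNG streams (counts, sequences, caller tables) are derived
from the single seed, so each emission is reproducible in isolation.

## Numerical conventions

- All stochastic code uses `numpy.random.default_rng` seeded from explicit
  integers; no global RNG state.
- Percentages use decimal round-half-up (not banker's rounding) to two
  decimals.
- BH adjustment delegates to `statsmodels.stats.multitest.multipletests`
  and is oracle-tested against a hand-written step-up implementation.
- Fisher exact tests and t/normal tail probabilities come from `scipy.stats`.

## Limitations

- The DE test is a simplified NB Wald test: no GLM offsets or covariates, no
  outlier handling, and a two-parameter dispersion trend; it is calibrated
  for the simulated regime (n >= 3 per group, moderate dispersion), not a
  general replacement for DESeq2/edgeR.
- Targeting covers canonical seed classes only - no 3' supplementary
  pairing, site accessibility, or conservation scoring.
- Correlation edges assume roughly log-linear co-variation and at least 3
  samples; p-values are not adjusted across triplets (matching the
  hub-threshold convention this mirrors).
- The generator plants independent features (no correlation structure beyond
  the sponge latent factor) and coordinate-exact caller agreement; caller
  slack handling is therefore exercised only by unit fixtures.
- Hierarchical-clustering accuracy is defined only for k equal to the number
  of classes; with k greater, the Hungarian matching leaves extra clusters
  unmatched.
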