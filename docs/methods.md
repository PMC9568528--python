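# Methods

This note documents the models and procedures implemented in `selmort`, the
conventions chosen where the design was genuinely open, and what the
synthetic cohorts do and do not establish about real data.

## The synthetic cohort generator

`simulate_cohort` draws, in order:

1. **Ancestral allele frequencies.** One frequency per SNP,
   `p ~ Uniform(ancestral_maf_range)` (default (0.05, 0.5)). RAD tags carry
   1–3 SNPs with probabilities `snps_per_tag` (default 0.6/0.3/0.1).
2. **Locality frequencies.** Balding–Nichols:
   `p_k ~ Beta(p(1−F)/F, (1−p)(1−F)/F)`. With the default hierarchical
   mode and three localities, locality 1 and a shared parent of localities
   2 and 3 each diverge from the ancestor at `fst_baseline` (default 0.05),
   and the two southern localities diverge from their parent at
   `fst_within` (default 0.01). This emulates a one-front geography (a
   northern site separated from two southern sites by an oceanographic
   break) without simulating demography. A flat, single-level mode is
   available (`hierarchical=False`).
3. **Genotypes.** Two Bernoulli haplotypes per individual per SNP
   (Hardy–Weinberg within locality), so within-tag phase is defined by
   construction and survives the VCF round trip (`GT` written with `|`).
4. **Phenotypes.** Nine otolith-style predictors (hatch date, hatch size,
   moon phase at hatch, PLD, GRPLD, SST, settlement date, settlement size,
   moon phase at settlement) drawn from a latent multivariate normal with
   `pheno_corr_matrix`. The default correlation target is the identity
   except r(hatch date, settlement date) = 0.9 — the pair the downstream
   collinearity filter must catch — and r(PLD, settlement date) = 0.3.
   Each selected tag is linked to one of the eight scan predictors
   (settlement date is excluded as a link target, since the scan drops it;
   its signal would be recovered only indirectly through hatch date) and
   every genotype copy shifts that predictor by
   `sign × effect_size_beta` latent-SD units (default 0.8). Moon phases
   are discretized to ordinal levels 0–9 through the normal CDF of the
   (possibly shifted) latent variable, each level covering ~10 % of its
   mass.
5. **Survival.** Survivors are an independent subsample of a larger
   virtual settler pool (`pool_multiplier × n_survivors`, default 4×),
   mirroring a field design in which settlers and survivors are different
   individuals sampled months apart. Each pool member survives with
   probability `logistic(selection_strength × score)`, where the score is
   the mean of the standardized linked predictors; the mortality fraction
   in the wild is unknown, so the pool multiplier is a free parameter.
   If fewer than `n_survivors` are accepted the generator raises an error
   naming the locality rather than silently relaxing selection.
6. **Depth and missingness.** Per-call depth is negative-binomial with
   mean 29.67 and dispersion 5.7 — chosen to reproduce a mean ± SD of
   roughly 29.7 ± 13.5, clearly overdispersed relative to Poisson — and
   calls are masked missing with probability `missing_rate` (default
   0.02).

Default cohort sizes are 200 settlers + 100 survivors per locality with
5 000 neutral and 50 selected loci; the parameter-recovery checks run these
defaults with single-SNP tags so locus and SNP counts coincide. The truth
table records each SNP's selected flag, linked predictor, effect sign and
realized per-group frequencies.

**What the simulation does not model:** linkage beyond within-tag
co-inheritance, genotyping error, batch effects, age-dependent sampling
bias, demographic history, or spatial autocorrelation of phenotypes.
Passing the recovery tests therefore shows that the statistics behave as
designed under their own assumptions — not that a field cohort of this
size would yield the same power.

## Filter cascade

Stages run in a fixed order (depth mask → missingness → MAF → tag mean
depth → HWE), and the report attributes every removal to its stage:

* calls with depth < 5× are masked (not the SNP removed);
* SNPs with missingness > 0.30, computed over all individuals after
  masking (globally, not per locality);
* SNPs with MAF < 0.05 over non-missing calls; **the boundary MAF = 0.05
  is kept** — the removal criterion is read as "below 0.05";
* the per-tag mean depth over non-missing calls is compared with the Tukey
  upper fence Q3 + 1.5 IQR of the per-tag distribution ("1.5 × IQR" alone
  is not a complete rule; a `median + 1.5 IQR` variant is selectable);
  all SNPs of an offending tag are removed, targeting collapsed paralogs;
* a mid-p exact Hardy–Weinberg test (settlers and survivors pooled per
  locality, α = 0.05) removes SNPs rejected in ≥ 2 localities; localities
  with < 5 genotyped individuals at a SNP are skipped with a warning. The
  mid-p variant keeps the realized type-I rate near nominal on discrete
  genotype-count supports (measured ≈ 0.048 at n = 200).

The tag-depth fence depends on the surviving tag set, so exact idempotence
of the cascade is a property of typical depth distributions rather than a
theorem; it is verified on simulated cohorts in the test suite.

Within-tag SNPs collapse into multi-allelic haplotype loci using read
phase. An individual with two or more *unphased* heterozygous sites on one
tag gets a missing haplotype (counted and reported): imputing phase would
fabricate alleles. A single heterozygous site is always phase-determined.

## Structure statistics

* **F_ST.** Weir & Cockerham (1984) variance components a (among
  populations), b (among individuals) and c (within individuals);
  per-locus θ = a/(a+b+c), multi-locus θ as the ratio of sums, loci with a
  zero or undefined denominator excluded. Haplotype loci are handled as
  multi-allelic loci by summing per-allele components. Significance: free
  permutation of individuals between the two groups preserving sizes,
  p = (1 + #{θ* ≥ θ})/(B+1), B = 999 by default. The permutation loop is
  fully vectorized (membership-matrix products), so a 999-permutation test
  on tens of loci costs milliseconds.
* **PERMANOVA.** Distances (Euclidean by default; Manhattan and a numeric
  Gower are selectable — Bray–Curtis is undefined for signed variables
  such as dates) are squared, Gower-centered, and partitioned by
  sequential (type-I) projectors built from an SVD orthonormal basis of
  the cumulative design (age, locality, age × locality). For a univariate
  Euclidean response the pseudo-F reproduces classical ANOVA F to machine
  precision, and the sequential SS match type-I ANOVA and vegan's
  `adonis2` on balanced and unbalanced designs. P-values come from free
  permutation of individuals.
* **DAPC.** Columns (genotype dosages or one-hot haplotype-allele counts,
  NaN mean-imputed) are centered and unit-scaled, PCA retains
  `floor(n/3)` components by default, and a linear discriminant analysis
  is fitted on the retained scores; assignment probabilities are the LDA
  posteriors.

## RDA scans and candidate calling

Per locality, settlers and survivors pooled:

1. Predictors with a pairwise |Pearson r| > 0.8 lose the later column in
   canonical order (hatch → larval → settlement variables); every drop is
   logged with the offending correlation. Remaining columns are
   standardized. Moon phases enter as ordinal 0–9 numerics (their vectors
   appear in ordination biplots, implying numeric treatment); a one-hot
   mode is left to the caller by pre-encoding.
2. Missing genotypes are imputed to the within-locality modal genotype
   (ties to the lower code); a SNP absent from a locality falls back to
   the global mode. Genotypes are centered but not variance-scaled
   (scaling is a flag).
3. The fitted matrix — the projection of centered genotypes onto the
   predictor column space — is decomposed by SVD. Since the projection has
   rank ≤ p, the SVD is taken of the p × m matrix QᵀY (Q an orthonormal
   predictor basis), which makes a 300 × 5 000 scan essentially free.
   Eigenvalues are squared singular values over n−1; loadings are the
   unit-norm right singular vectors.
4. Per axis, SNPs with a loading more than 3 SD from the axis mean are
   flagged; the union over all constrained axes (a first-k option exists)
   is the candidate set. Degenerate axes (zero spread) flag nothing.
   Under Gaussian loadings the rule flags a fraction 2(1−Φ(3)) ≈ 0.0027
   per axis; realized genotype-loading distributions are slightly
   heavier-tailed (measured ≈ 0.005 per axis at the default simulation).
5. Each candidate is assigned the predictor with the largest |Pearson r|
   against its imputed genotype vector, with the sign recorded; exact ties
   resolve to the earlier predictor in canonical order. Every flagged
   outlier is a candidate; an optional per-correlation p < 0.05 filter is
   off by default.

## Parallel set and its statistics

A SNP is *parallel* when flagged in **all** localities with the same
assigned predictor and the same correlation sign. The triple coincidence
is the design's multiplicity control — under neutral-only simulation the
parallel set is empty or holds a single SNP — so no further
multiple-testing correction is applied by default.

For the predictor-combination categorization, a SNP is "associated" with
every predictor whose |r| reaches 90 % of its assigned predictor's |r| in
every locality with a consistent sign (the assignment itself defines only
one predictor per SNP; the runner-up threshold is configurable). Each
combination is tested with the exact multi-set intersection distribution:
|A₁∩A₂| ~ Hypergeometric(N, n₁, n₂) and, conditional on a running overlap
m, folding in Aᵢ gives Hypergeometric(N, m, nᵢ); the p-value is the upper
tail at the observed overlap, with the observed statistic counted
SuperExactTest-style (SNPs associated with at least the combination).

Allele-frequency change between settlers and survivors is a Pearson
chi-square without continuity correction on the 2 × 2 allele-count table
(two copies per homozygote, one per heterozygote, missing calls excluded —
no imputation feeds a test). Zero margins return a not-applicable result
with the reason; any expected cell < 5 raises a flag.

## Annotation

BLAST tabular hits (outfmt-6 column order) are filtered at E ≤ 1e-4
(boundary inclusive) and deduplicated on identical subject coordinates;
0/1/≥2 passing hits give unmapped/unique/multiple ("unique" is the strict
reading — exactly one location, no bitscore-margin best-hit rule).
Uniquely mapped intervals are placed against GFF3 genes and exons: any
exon overlap (≥ 1 bp, junction-spanning included) is exonic, inside a gene
without exon overlap is intronic, otherwise intergenic. When several genes
overlap, the longest-overlap gene wins (ties to the lexicographically
lowest ID). GFF3 and BLAST coordinates are 1-based inclusive on input and
converted once to 0-based half-open internally.

Codon effects substitute all alternate alleles of a codon jointly (the
result is identical to sequential substitution), reverse-complementing
positions and alleles for minus-strand genes before translating with the
standard genetic code; codons containing ambiguous bases return an
undetermined effect.

## Numerical conventions and limitations

* Every stochastic routine takes an explicit seed; the pipeline manifest
  records a config hash and SHA-256 checksums, and reruns are
  byte-identical.
* Permutation p-values live on the grid {1/(B+1), …, 1}; B = 999 default.
* Rank decisions (RDA predictors, PERMANOVA designs) use SVD with a
  relative 1e-9/1e-10 tolerance; RDA refuses rank-deficient predictors
  rather than silently dropping one.
* The acceptance checks run at desk scale — hundreds of individuals and
  thousands of SNPs, 500-replicate null calibrations — sizes chosen so the
  whole suite completes in minutes on one CPU while keeping Monte-Carlo
  error well inside the asserted bands.
* Known limitations: no strata-restricted permutations or AMOVA; no
  latent-factor association methods or partial RDA conditioning on
  structure; no FDR across SNPs by default (a Benjamini–Hochberg pass can
  be applied downstream); GO-term semantics and ortholog-tree building are
  out of scope for the annotation module.
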