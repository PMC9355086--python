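# Methods

## Phenotype model and null fit

The quantitative trait is rank-based inverse-normal transformed before
any testing: `z_i = Φ⁻¹((rank_i − 3/8)/(n + 1/4))` with average ranks for
ties (Blom offsets).  The null model is ordinary least squares of the
transformed trait on an intercept, age, sex, BMI, smoking status and the
first five genetic principal components; conditional analyses append
lead-SNP dosages as extra columns.  Collinear columns are detected by a
rank-revealing QR and dropped with a warning; the residual variance uses
the denominator `n − rank(X)`.  A numerically perfect fit (residual sum
of squares below 1e-24 of the phenotype's) is treated as zero residual
variance, and downstream tests then return p = 1 by convention.

## Kernel association test

For one gene, `Q = r'GW²G'r` with `W = diag(w)`.  Missing genotypes are
mean-imputed per variant; zero-variance and zero-weight columns are
dropped before weighting.  The null distribution is the weighted
chi-square mixture with weights equal to the eigenvalues of
`σ̂²·WG'P₀GW`, always computed from the m×m matrix (never the n×n
kernel); eigenvalues below 1e-10 of the largest are discarded.

Minor allele frequencies used for weighting are computed on the analysis
sample after filtering, not read from annotation, so weights always
reflect the tested cohort.

### Weighting schemes

| scheme | weights | partition cutoff | combination |
|---|---|---|---|
| `cadd` | PHRED-scaled CADD score, used directly (score 0 ⇒ weight 0) | — | single kernel |
| `unweighted` | β(1,1) ≡ 1 | — | single kernel |
| `maf_weighted` | rare β(0.5,20), common β(0.5,0.5) | 0.00025 | single kernel (piecewise weights) |
| `commonrare_unweighted` | β(1,1) / β(1,1) | 1/√(2n) | Q_rare + Q_common |
| `commonrare_weighted` | rare β(0.1,25), common β(0.5,0.5) | 0.00025 | Q_rare + Q_common |

The partitioned tests compute the rare and common statistics separately
and sum them; the combined null uses the eigenvalues of the full weighted
projected kernel over the concatenated variant set, which makes the
combination exact (including rare–common correlation) rather than
approximate.  With an unweighted sum this is algebraically identical to a
single kernel with piecewise weights; both code paths exist because the
partition bookkeeping (n_rare, n_common, per-partition degenerate cases)
differs.  The RareOnly restriction uses flat β(1,1) weights so the
cascade is a pure frequency-restriction probe.

### P-values

`P(Σλχ²₁ > Q)` is computed by numerically inverting the mixture's
Laplace transform `M(−s)/s`, `M(−s) = Π(1+2λ_i s)^{−1/2}`, along a
fixed-Talbot contour (N = 32 nodes) that wraps the transform's branch
points on the negative real axis.  In double precision this is accurate
to ≈1e-10 absolute, uniformly in the eigenvalue disparity (validated
against chi-square closed forms and high-precision references).  When the
p-value lies below the inversion accuracy (1e-9) the four-moment
(Liu-Tang-Zhang) approximation is used instead and the result is labelled
`moment_match`; p-values are reported as computed, never clamped to
zero.  The moment approximation agrees with the inversion to better than
1e-3 absolute for p ≤ 1e-2; in the distribution's bulk it is looser (it
is a tail approximation), which is why the method label matters.

### Permutation reference

`permutation_pvalue` recomputes Q under random permutations of the
residual vector.  This is a genuinely different null: the permutation law
conditions on the realized residuals and differs from the Gaussian-theory
mixture by deterministic O(1/n) corrections (without-replacement fourth-
cumulant terms and empirical-kurtosis products).  At n = 100 the two
p-values typically differ by 0.003–0.01 — far more than the Monte-Carlo
error of 200,000 permutations — so the permutation oracle validates the
mixture only to O(1/n), while a parametric (Gaussian-residual) Monte
Carlo validates it to Monte-Carlo precision.  The test suite contains
both checks.

## Single-marker scan and lead SNPs

Variants enter the GWAS scan when MAF > 1%, exact Hardy–Weinberg
p ≥ 1e-10, and missingness < 1% (the filters commute; the recorded
exclusion reason follows MAF → missingness → HWE order).  The HWE test is
the exact conditional test — the sum of probabilities of heterozygote
counts no more probable than the observed one given the allele counts —
without mid-p correction, computed by a normalised log-gamma enumeration.
Each qualifying SNP is tested by OLS of the transformed trait on dosage
plus covariates (two-sided t).  Genome-wide significance is 5e-8.

Significant SNPs are grouped into loci greedily (an inter-SNP gap above
1 Mb starts a new locus; configurable).  Per locus, lead SNPs are chosen
iteratively: the most significant SNP (ties broken by smaller position)
joins the covariates and the locus is rescanned until nothing is
significant, with a 20-round non-convergence guard.  A conditioned lead's
own re-test returns p = 1 because its projected dosage has (numerically)
zero variance.  Conditioning is locus-local during selection; the final
union of lead dosages conditions the gene-based re-tests genome-wide.

## Discovery logic and thresholds

The primary threshold is `0.05/(n_genes_tested × 5)` — at an exome-wide
scale of 19,288 genes this evaluates to 5.18e-7.  Downstream analyses
(conditional schemes and the 7-cutoff RareOnly cascade, with and without
conditioning: 5 + 14 = 19 models) are re-corrected over the significant
genes: `0.05/(N_significant × 19)`; the model count is configurable since
follow-up batteries vary.  Significant genes cluster into loci per
chromosome by iterative lead selection with a 10 Mb window anchored at
interval midpoints; genes more than 5 Mb (strict) from every lead SNP are
non-GWAS-overlapping.  A gene is *rare-driven* when any conditioned
cascade cutoff (0.01%, 0.1%, 0.3%, 0.5%, 1%, 3%, 5%) beats the downstream
threshold; the smallest qualifying cutoff is recorded.  The per-gene p
used for clustering and meta-analysis is the minimum across schemes,
uncorrected for scheme count — anti-conservative by design, matching
lowest-p-per-gene reporting practice.

## Meta-analysis

Per gene, the minimum p across schemes within each stratum is combined by
Fisher's method, `X² = −2Σln p_i ~ χ²(2k)`, on the natural-log scale (a
double-precision log keeps full accuracy down to p ≈ 1e-300, covering the
1e-247 range such studies produce).  The combined p is Bonferroni-
multiplied by m, defaulting to the number of primary-significant genes.

## Synthetic cohorts

The generator emulates the *statistical* structure the analysis assumes,
not the biology of real exomes:

- site frequencies log-uniform on [1e-5, 0.5] — simple, and covering all
  seven cascade cutoffs;
- Hardy–Weinberg genotypes, independent across sites (**no linkage
  disequilibrium**): LD realism is not needed to exercise any formula
  here, and the conditional machinery is probed by placing a common
  causal SNP ~1.2 Mb from a rare-driven gene instead;
- consequence classes high/moderate/other with class-conditional
  truncated-normal CADD-like scores (only their relative magnitude
  matters to the CADD scheme);
- covariate-dependent phenotypes with Gaussian noise (σ = 1); covariate
  coefficients are small but nonzero so the null fit does real work;
- two ancestry strata (94% / 6%) whose non-European allele frequencies
  are log-normal jitters (σ = 0.3) of the European ones — mild
  stratification without a demographic model, partially absorbed by a
  PC1 offset;
- per-gene causal architectures with known variants and effects,
  recorded in a truth manifest.

Causal variants are placed in the requested frequency band and coerced to
a qualifying (moderate-impact) consequence so they survive the inclusion
filter; effect signs are random per variant (the kernel test is
sign-insensitive, the single-marker scan is not).

**The standard cohort** (`standard_cohort_config`) has 10,000 samples and
30 genes of 50–70 variants: two rare-driven, two common-driven, one
mixed, 25 null.  Rare-driven genes carry 30 causal variants at MAF
0.01–0.025% with |β| = 1.2 SD per allele; common-driven genes carry one
causal SNP at MAF 15–40% with |β| = 0.35 SD.  These values come from a
power analysis: the frequency-weighting schemes concentrate weight below
the 0.025% partition cutoff (the Beta densities are discontinuous
across it), so a detectable rare architecture needs many ultra-rare
carriers — noncentrality β²·Σ2n·maf ≈ 140 across ~100 carriers — rather
than a few sub-0.5% variants; real rare-driven genes in such studies
likewise carry hundreds of rare variants.  At these settings each causal
architecture is recovered with ≥99.9% probability per gene at exome-wide
stringency, so the end-to-end recovery check is seed-robust, while null
genes stay controlled at the familywise level by construction.

What passing these tests does **not** show: robustness to LD between
causal and conditioning variants, to imputation error (real GWAS stages
run on imputed dosages; here genotypes are hard calls), to relatedness or
strong population structure, or to non-Gaussian phenotype noise beyond
what the INT absorbs.

Problem sizes used by the automated checks: type-I calibration uses
2,000 null genes at n = 2,000 (≈14,000 variants); oracle comparisons use
n = 100, m ≤ 6 with 200,000 resamples; recovery uses the standard cohort.

## Numerical conventions

- genotype storage float32 with NaN missingness; analysis in float64;
- eigen truncation at 1e-10 of the largest eigenvalue;
- HWE probability ties compared with 1e-12 relative tolerance (exact
  rational ties are orders of magnitude away from that window);
- deterministic tie-breaks everywhere (smaller position wins for equally
  significant SNPs); a single master seed fixes every simulated quantity;
- gene intervals are 1-based inclusive internally and 0-based half-open
  in BED output; variants are 1-based.

## Known limitations

No SKAT-O style rho-optimisation, no binary-trait (logistic) null, no
small-sample moment adjustment, no mixed-model/kinship kernels, and no
X-chromosome handling — all by scope.  The Liu fallback in the extreme
tail (p < 1e-9) is ordinally reliable but can be off by a large relative
factor, as is standard for moment approximations there; extreme p-values
should be read as "far below threshold" rather than as precise
magnitudes.
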