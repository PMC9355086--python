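# exoskat

Exome-wide **gene-based association testing of quantitative traits**, built
around the sequence-kernel (variance-component) score test with
variant-weighting schemes, conditional adjustment for GWAS lead SNPs,
rare-variant cascade classification, and Fisher meta-analysis across cohort
strata.

The package is aimed at statistical geneticists who want a transparent,
fully testable implementation of the discovery logic used in large
whole-exome studies of blood-cell traits (e.g. eosinophil count in
~200,000 exomes): which genes associate with the trait, which of those
signals are explained by common GWAS variants, and which are genuinely
driven by rare coding variation.  Because the real cohorts are
access-restricted, a first-class synthetic-cohort generator emulates the
statistical structure of such a study (site-frequency spectrum, VEP-style
consequence classes, CADD-like scores, covariates, ancestry strata, and
known causal architectures) so every stage can be verified against ground
truth.

## The statistic

For a gene with dosage matrix `G` (n samples × m variants), per-variant
weights `w_j`, and residuals `r` from the null model
`y = Xα + ε` (y the rank-based inverse-normal-transformed trait; X the
covariates age, sex, BMI, smoking, PC1–PC5, plus any conditioning
dosages), the score statistic is

```
Q = r' G W² G' r ,   W = diag(w)
```

Under H₀, `Q ~ Σ_j λ_j χ²₁` where `λ_j` are the eigenvalues of
`σ̂² · W G' P₀ G W` with `P₀ = I − X(X'X)⁻¹X'`.  P-values are obtained by
numerical inversion of the mixture's transform (accurate to ~1e-10),
falling back to a four-moment approximation below the inversion accuracy.

Five weighting schemes are provided: CADD-score weights, flat weights
(β[1,1]), frequency weights (rare β[0.5,20] / common β[0.5,0.5]), and two
partitioned common/rare tests (flat, and β[0.1,25]/β[0.5,0.5]) whose rare
and common statistics are computed separately and summed, with an exact
combined null.  The rare/common partition is MAF 0.00025 for the weighted
schemes (100 alleles in 400,000 chromosomes) and `1/√(2n)` otherwise.

## Worked example

```python
import exoskat as ek

cohort, truth = ek.generate_cohort(ek.standard_cohort_config(seed=7))
result = ek.run_discovery(cohort)

print(result.significant_genes)
cls = result.classification.set_index("gene")
for gene in result.significant_genes:
    row = cls.loc[gene]
    print(gene, truth.architectures[gene], f"p={row['min_p_primary']:.2e}",
          row["best_scheme"], bool(row["significant_after_gwas_adjustment"]),
          bool(row["rare_driven"]))
```

prints

```
['GENE0000', 'GENE0003', 'GENE0007', 'GENE0012', 'GENE0018']
GENE0000 rare_driven   p=8.92e-09 maf_weighted          True  True
GENE0003 rare_driven   p=4.04e-08 maf_weighted          True  True
GENE0007 common_driven p=4.91e-91 commonrare_unweighted False False
GENE0012 common_driven p=3.57e-100 unweighted           False False
GENE0018 mixed         p=4.42e-38 commonrare_unweighted False False
```

All five causal genes (out of 30) are exome-wide significant.  The two
rare-driven genes survive conditioning on the three GWAS lead SNPs and
are flagged by the conditioned RareOnly cascade; the two common-driven
genes lose significance once their causal SNP is a covariate — exactly
the classification logic used to separate rare-variant signals from
GWAS-explained ones.

The meta-analysis module reproduces published worked examples directly:

```python
x2, df, p = ek.fisher_combine([1.98e-6, 4.46e-1])
# X2=27.88, df=4, p=1.32e-05 ; Bonferroni(220): 2.90e-03
```

A command-line interface mirrors the library:

```bash
exoskat simulate --config sim.yaml --out cohort/ --seed 7
exoskat run-all --cohort cohort/ --out results/
exoskat gwas --cohort cohort/ --out gwas/
exoskat meta --results strata.tsv --m 220 --out meta.tsv
```

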