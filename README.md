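# sumrhe

SNP heritability from GWAS summary statistics, with the accuracy of
individual-level randomized Haseman–Elston regression.

## The problem

SNP heritability h² — the fraction of phenotypic variance explained by
genotyped SNPs under an additive model — is routinely estimated from
biobank data by method-of-moments (Haseman–Elston) variance-component
estimators. The accurate estimators need individual genotypes and
phenotypes; the shareable ones (LD-score style) need only GWAS summary
statistics but lose precision. This package implements the reconstruction
that closes the gap: the individual-level randomized HE estimate depends on
the data only through two quantities, one of which (the trace of the
squared genetic relatedness matrix) is a property of the population's LD,
not of the phenotype. A reference cohort can estimate it once with
Hutchinson probe vectors and release it as a tiny text *trace summary*
(ρ̂ with SNP-block jackknife replicates); any GWAS on the same population
then yields an h² estimate

    ĥ² = (N·z'z/M − 1) / (N·ρ̂),   z_j = (β̂_j/s_j)·√N_j / N,

with a block-jackknife standard error, without anyone sharing genotypes.

The package provides, as a library and a CLI:

* PLINK 1 `.bed/.bim/.fam` I/O and divisor-N column standardization;
* polygenic phenotype simulation (sparse and large/small-effect mixture
  architectures) and synthetic genotype panels;
* marginal GWAS producing/consuming the PLINK 2 `.glm.linear` dialect;
* exact and stochastic tr(K²), trace-summary construction, aggregation and
  the `.trace` text format;
* the three estimators (`HE_EXACT`, `RHE`, `SUM_RHE`) with jackknife SEs
  and a one-sided null test;
* a simulation harness for calibration / accuracy grids with paired
  bootstrap relative-MSE comparisons.

See `docs/methods.md` for the model, conventions and design choices.

## Worked example

A reference cohort (N=2000) releases a trace summary; a disjoint target
cohort (N=1500) runs a GWAS on a simulated phenotype with true h² = 0.3 and
causal ratio 0.1; the two artifacts are combined:

```sh
sumrhe simulate-genotypes --n 2000 --m 3000 --seed 7 --out ref
sumrhe simulate-genotypes --n 1500 --m 3000 --seed 8 --out target

sumrhe trace make --bfile ref --b 100 --runs 5 --blocks 50 --seed 1 --out ref.trace
# rho=0.000330663 (N_ref=2000, M=3000, B=500)

sumrhe simulate-pheno --bfile target --h2 0.3 --causal-ratio 0.1 --seed 2 --out target.pheno
sumrhe gwas --bfile target --pheno target.pheno --out target.glm.linear
sumrhe estimate sumrhe --sumstats target.glm.linear --trace ref.trace
# method   h2        se         n_blocks  m     n
# SUM_RHE  0.274103  0.0630223  50        3000  1500
```

ρ̂ ≈ 3.3e-4 ≈ 1/M + 1/N_ref, as expected for unlinked SNPs (it is the
average LD across SNPs). The point estimate 0.274 recovers the simulated
h² = 0.3 well within its jackknife standard error 0.063; the estimate uses
only the two text artifacts, never the genotypes. With individual data the
same phenotype can be analyzed directly
(`sumrhe estimate rhe --bfile target --pheno target.pheno`), and
`sumrhe experiment` runs whole calibration/accuracy grids.

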