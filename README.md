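# sctwas

Cell-type-specific transcriptome-wide association studies (TWAS) from
population-scale single-cell RNA-seq, without heuristic normalization.

## The problem

TWAS tests whether the genetically regulated component of a gene's expression
(GReX) is associated with a trait. With single-cell data, expression per
individual and cell type is a pseudobulk UMI count — sparse, overdispersed,
and measured at wildly different sequencing depths. The common workaround is
to normalize the counts into a continuous variable (CPM/TMM, log, inverse
normal transform) and run the bulk-TWAS elastic net on it; that discards the
count nature of the data and loses power, especially in rare cell types.

This package instead models the counts directly. For individual *i*, with
pseudobulk count *x*ᵢ and cell-type sequencing depth *s*ᵢ, the latent
relative abundance *z*ᵢ satisfies

```
z_i ~ F(mu_i, mu_i^2/theta),   mu_i = g_i' beta + c_i' gamma
x_i | z_i ~ Poisson(s_i z_i)
```

so `E x_i = s_i mu_i` and `Var x_i = s_i mu_i + s_i^2 mu_i^2 / theta`. SNP
weights **β** minimize the inverse-variance-weighted elastic-net loss

```
sum_i w_i (x_i - s_i g_i' beta - s_i c_i' gamma)^2
    + lambda (0.5 ||beta||_1 + 0.5 ||beta||_2^2),   w_i = 1/Var(x_i),
```

fit by iteratively re-weighted least squares (IRLS) since the weights depend
on the coefficients; `lambda` comes from seeded cross-validation and `theta`
from a covariate-only null fit. Stage 2 tests the predicted GReX against a
trait, either from individual-level data (Wald regression test) or from GWAS
summary statistics with an LD reference panel:

```
z_TWAS = beta' z_GWAS / sqrt(beta' V beta).
```

The two baseline pipelines it is compared against — normalize-then-aggregate
(per-cell log-CPM, mean, INT) and aggregate-then-normalize (pseudobulk, TMM,
log-CPM, INT) with a standard elastic net — are included, as is a seeded
simulator (AR(1) genotypes, Gamma-Poisson single-cell counts, LD-aware GWAS
summary statistics) that drives power and type-I-error studies.

Intended users: statistical geneticists building cell-type GReX models from
population-scale scRNA-seq cohorts with matched genotypes, and methodologists who need
a reproducible harness for comparing count-based and normalization-based
Stage-1 training.

## Worked example

```python
import numpy as np
from sctwas import (CountGReXRegressor, SimulationConfig, individual_level_test,
                    simulate_expression_counts, simulate_genotypes, simulate_trait)

gb = simulate_genotypes(n=500, m=30, rho=0.5, seed=7)
cfg = SimulationConfig(n_individuals=500, n_snps=30, cells_per_individual=84,
                       n_replicates=1, seed=7)
rng = np.random.default_rng(7)
cohort = simulate_expression_counts(gb, cfg, seed=rng)
y, _ = simulate_trait(cohort.true_mu, cfg.h2, seed=rng)

est = CountGReXRegressor(random_state=7)
est.fit(cohort.G, cohort.pseudo_x.astype(float), depth=cohort.pseudo_s.astype(float))
p1 = est.cv_prediction_pvalue(cohort.G, cohort.pseudo_x.astype(float), cohort.pseudo_s.astype(float))
stage2 = individual_level_test(y, est.predict(cohort.G))
print(f"theta={est.theta_:.1f} lambda={est.lambda_:.3g} nonzero={np.sum(est.beta_ != 0)}")
print(f"stage1 prediction p={p1:.2e}  stage2 z={stage2.z:.2f} p={stage2.pvalue:.2e}")
```

prints

```
theta=120.4 lambda=56 nonzero=17
stage1 prediction p=2.50e-18  stage2 z=4.49 p=7.14e-06
```

A cohort of 500 individuals with a mean of 84 cells each was simulated with
10 causal cis-SNPs explaining 5% of the trait variance. The null-model
overdispersion (`theta`) of the pseudobulk counts is 120 — pooling ~84 cells
per individual averages away most of the per-cell biological noise, so the
individual-level dispersion is much milder than the per-cell value of 10.
The cross-validated prediction p-value (2.5e-18) says the estimated GReX
tracks observed expression out of sample; the Stage-2 Wald test then finds
the gene-trait association (z = 4.5). The same model can be tested without
individual-level phenotypes via `twas_z` and GWAS summary statistics.

The command-line interface mirrors the library:
`sctwas train` (MTX counts + PLINK/VCF genotypes → per-gene weight store),
`sctwas assoc` (weight store + GWAS TSV + LD panel → association TSV with
Bonferroni flags and 1-Mb locus clumping), and `sctwas simulate` (YAML config
→ per-replicate and summary power/type-I tables).

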