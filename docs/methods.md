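# Methods

## The measurement-model GReX framework

For one gene in one cell type, let `x_i` be the pseudobulk UMI count of
individual `i` (the sum over that individual's cells), and `s_i` the
individual's sequencing depth — the total UMI count across all genes in the
cell type, computed before any gene filtering. The latent relative abundance
`z_i` of the gene is modeled as a nonnegative random variable with mean

    mu_i = g_i' beta + c_i' gamma

(`g_i` cis-genotypes, `c_i` covariates including an intercept) and biological
variance `sigma_i^2 = mu_i^2 / theta`, where `theta` is an overdispersion
parameter (larger `theta` = closer to Poisson). The measurement process is
`x_i | z_i ~ Poisson(s_i z_i)`, which gives the marginal moments

    E(x_i)   = s_i mu_i
    Var(x_i) = s_i mu_i + s_i^2 mu_i^2 / theta.

No parametric form is assumed for `z_i`; it enters only through these moments
and is never instantiated at fit time.

`beta` is estimated by minimizing

    sum_i w_i (x_i - s_i g_i' beta - s_i c_i' gamma)^2
        + lambda (0.5 ||beta||_1 + 0.5 ||beta||_2^2),

with inverse-variance weights `w_i = 1 / Var(x_i)` and `gamma` unpenalized.
Because the weights depend on the coefficients, the fit alternates
(IRLS): solve the weighted elastic net at the current weights, refresh
`mu_i` and hence `w_i`, repeat until the maximum relative coefficient change
drops below `tol`. The predicted GReX for new genotypes is `g' beta`
(depth and covariates excluded).

### Solver

The weighted problem is mapped to ordinary elastic net with response
`x_i sqrt(w_i)` and predictors `(s_i g_i sqrt(w_i), s_i c_i sqrt(w_i))`.
The unpenalized covariate block is removed exactly by QR projection
(partialling out), which is valid because only `beta` carries a penalty; the
covariate coefficients are recovered in closed form afterwards. The
penalized subproblem is solved by coordinate descent (scikit-learn's
`ElasticNet` / `enet_path`); the penalty
`lambda (0.5 l1 + 0.5 l2^2)` corresponds to `alpha = 3 lambda / (4n)`,
`l1_ratio = 1/3` in that parameterization. By default the penalized block is
internally standardized to unit root-mean-square and coefficients are
back-transformed, mirroring the convention of reference elastic-net
implementations; `standardize=False` makes the optimized objective exactly
the formula above (used by the solver-oracle tests).

### Overdispersion and initial weights

`theta` and the initial weights come from a covariate-only null model: a
Poisson GLM of `x` on `C` with log link and offset `log s` (closed form
`sum(x)/sum(s)` for the intercept-only design; a constant-mean fallback is
used if the GLM fails), followed by the method-of-moments estimator

    theta = sum_i (s_i mu0_i)^2
            / sum_i [ (x_i - s_i mu0_i)^2 - s_i mu0_i ],

clamped to [1e-2, 1e6]; a nonpositive denominator (Poisson-like data, no
detectable overdispersion) maps to the upper clamp. `theta` is held fixed
across IRLS iterations; only the weights are re-estimated. Note that when
pseudobulk counts pool many cells, the individual-level `theta` estimated
here is larger than any per-cell dispersion (cell-level biological noise
averages out across cells), which is the quantity the weights need.

Numerical guards: `mu_i` is floored at 1e-10 inside the weight formula (the
linear mean model can produce nonpositive means); IRLS returns the
best-objective iterate with `converged=False` if it oscillates past
`max_iter` (default 25, tolerance 1e-4).

### Penalty selection and prediction evaluation

`lambda` is chosen on a 100-point log-spaced grid from `lambda_max` (the
smallest penalty that zeroes `beta` on the transformed problem) down to
`1e-4 lambda_max`, by seeded k-fold cross-validation (default k=5) minimizing
the held-out weighted squared error; validation weights come from the
training-fold fitted mean, and exact ties — the plateau where `beta = 0` —
break toward the larger penalty. Training-fold path fits use the fold's
null-model weights rather than a full IRLS per grid point: the penalty is
selected once at the initial weights and the IRLS then runs at the selected
penalty, keeping the per-gene cost at a few dozen solver calls instead of
tens of thousands. This matches the ordering of the fitting algorithm
(null-model weights first, then the iterative fit).

Predictiveness is summarized by a cross-validated prediction p-value:
`lambda` is re-selected inside each outer training fold (nested CV, same
seeded partition scheme), held-out predictions `s_i g_i' beta` are
concatenated across folds, and the observed counts are regressed on them
plus the depth-scaled intercept `s_i`, weighted by each fold's model-based
weights; the two-sided Wald p-value of the slope is reported. The baseline
column is `s_i` rather than a constant because the measurement model's
covariate block is scaled by depth — with a free intercept the
`s_i gamma_0` component of the counts would act as unexplained noise and
mask even a perfect GReX whenever depths vary across individuals (at
constant depth the two parameterizations coincide, and the unweighted
normalized-expression evaluation keeps the ordinary intercept). If every fold's weight vector is
identically zero the gene is flagged non-predictive with p = 1; the same
happens for a degenerate constant predictor.

## Baseline recipes

Two normalization-based pipelines feed the standard homoskedastic elastic net
(same 0.5/0.5 penalty, unpenalized covariates, seeded CV):

* **NA (normalize-then-aggregate):** per-cell CPM using the cell's total
  depth, `log(CPM + 1)`, arithmetic mean across each individual's cells, then
  a per-gene rank-based inverse normal transform (INT).
* **AN (aggregate-then-normalize):** pseudobulk counts, TMM scaling factors
  (trimmed mean of M-values, 30% log-ratio trim, 5% abundance trim,
  precision-weighted, rescaled to geometric mean 1, reference sample chosen
  by the upper-quartile rule), `log(CPM + 1)` on TMM-effective library sizes,
  then per-gene INT.

INT uses offset 0.5 — `Phi^{-1}((r - 0.5)/n)` with average ranks for ties —
and the log transform uses pseudocount 1 on the CPM scale in both recipes.
Their prediction p-value is the unweighted analogue of the evaluation above.

## Stage-2 association

With GWAS summary statistics, the association z-score for a gene is

    z = beta' z_GWAS / sqrt(beta' V beta),

standard normal under the null; `V` is the cis-SNP LD correlation matrix from
a reference panel, projected to the nearest positive-semidefinite matrix by
clipping negative eigenvalues (no ridge shrinkage by default), with a 1e-12
floor on the quadratic form. GWAS alleles are harmonized to the model's
orientation by SNP id: swapped alleles flip the z sign, strand-ambiguous
(A/T, C/G) pairs and mismatches are dropped, and the weight vector and `V`
are subset consistently. With individual-level data the same hypothesis is
tested by a Wald test of the GReX coefficient in a linear regression of the
trait on `g' beta` plus covariates; underflowing p-values are reported as the
smallest positive normal double with a flag, never 0.

Multiple testing uses a Bonferroni threshold `0.05 / M`, `M` being the number
of Stage-1-significant genes in the cell type. Significant genes are grouped
into loci greedily by p-value rank: a 1-Mb window is centered on the lead
gene's midpoint `(tss + tes)/2` and collects all unassigned genes whose
midpoints fall inside it (half-open interval). A locus is "known" if it
harbors a GWAS variant with p < 5e-8, else "novel".

## The simulator

The generator reproduces the study conditions the framework is evaluated
under. Defaults (all configurable):

* **Genotypes.** AR(1) Gaussian-copula haplotypes (`rho = 0.5`) thresholded
  at the target MAF quantile (MAF ~ U(0.05, 0.5)), two haplotypes summed to a
  dosage; monomorphic draws are redrawn up to 10 times. The trainer receives
  column-standardized dosages, matching the design in which effect sizes are
  defined on the standardized scale.
* **Expression.** `mu_i = g_i' beta + beta_0` with `beta_0 = 1e-4`; 10 causal
  cis-SNPs with weights from U((-3e-6, -5e-9) u (5e-9, 3e-6)), redrawn if any
  `mu_i <= 0`. Per cell, `z_ij ~ Gamma(shape = theta, scale = mu_i/theta)`
  with `theta = 10`; a per-individual intercept `a_i ~ N(0, (beta_0/100)^2)`
  correlates cells within an individual; counts are
  `x_ij ~ Poisson(s_ij max(z_ij + a_i, 0))` (the clamp guards the rare
  negative rate and essentially never binds at the default intercept scale).
  The random-intercept scale `beta_0/100` is read as a standard deviation
  (the convention of R's `rnorm`, in which such designs are typically coded);
  reading it as a variance would make the intercept noise an order of
  magnitude larger than the baseline expression itself, burying the genetic
  signal and breaking the generator's own moment identities.
* **Cell counts and depths.** Cells per individual are lognormal around the
  abundance-tier mean (tiers {472, 209, 84, 40, 10, 5}) with CV 0.7: the
  tiers are cohort means, and real per-individual capture varies strongly —
  this inter-individual variation is the main source of the depth
  heteroskedasticity the weighted model addresses. Per-cell depths are
  lognormal with median 3000 and IQR 2000-5000 counts. The trainer's
  individual depth is `s_i = sum_j s_ij` (the focal gene's own contribution
  is negligible at `mu ~ 1e-4`); real pipelines would embed the gene in a
  full count matrix instead. With a single simulated gene the AN recipe's
  TMM factors are identically 1, so it reduces to log-CPM + INT.
* **Trait (one-sample).** `y_i = mu_i + e_i` with
  `Var(e) = (1 - h2)/h2 Var(mu)`, so the gene's GReX explains `h2` of trait
  variance (`h2 = 0.05` by default, giving noise/signal 19). Null scenarios:
  `mu_i = beta_0` (expression independent of genotype) or `y ~ N(0, 1)`
  (trait independent of expression).
* **GWAS summary (two-sample).** With `D = diag(sqrt(2 p_j (1 - p_j)))` and
  LD matrix `V`, marginal effects are drawn as
  `beta_hat ~ N(D^-1 V D b, (sigma^2/N) D^-1 V D^-1)` via PSD factorization,
  `SE_j = sigma / sqrt(N 2 p_j (1-p_j))`, `z = beta_hat / SE`; the joint
  effect is `b = gamma_trait beta` with
  `gamma_trait = sqrt(h2 / beta' D V D beta)` and `sigma^2 = 1 - h2`.
  Optional horizontal pleiotropy adds independent `N(0, v)` direct effects
  per SNP; the helper default for `v` makes the direct contribution equal the
  mediated `h2`.
* **Power harness.** All randomness flows from one root seed through
  SeedSequence spawning (one child stream per replicate). A replicate counts
  as a discovery when the Stage-1 prediction p-value is < 0.05 and the
  Stage-2 p-value is < 0.05/M, with M taken from per-tier presets
  {2189, 1234, 580, 476, 122, 91}; null scenarios hold both stages to the
  nominal 0.05. Rates come with Wilson 95% intervals and a config hash;
  replicate failures are logged and counted.

## What the simulations do and do not show

The generator reproduces the sparsity, depth heterogeneity and
overdispersion structure of pseudobulk single-cell counts, but not: LD from
real haplotypes (AR(1) is a single-knob surrogate), embedding of the focal
gene in a full count matrix (so TMM has no leverage in simulation), ambient
RNA/doublets, covariate structure (population stratification, batch), or
cross-study transfer. Passing the power and calibration studies therefore
supports the statistical machinery under the stated generative model, not
end-to-end performance on any particular cohort.

Under the Stage-1 null, cross-validation parks the penalty at the top of the
path and the cross-validated weight vector is exactly zero in a minority of
replicates; those are flagged non-predictive with p = 1 by definition
(a deliberate point mass, conservative for discovery). Calibration checks
therefore test uniformity on the testable replicates and separately bound
the flagged fraction and the lower tail.

## Problem sizes

The shipped studies run at desk scale: solver oracles on 50 instances of
n=30, p=10; two-route equivalence on 200 genes (n=500, 20 SNPs); Stage-2
null calibration over 1000 trait draws; Stage-1 null over 200 replicates
(n=200, 20 SNPs); moment checks over 1e5 cells and 5000 summary draws; the
abundance sweep over tiers {472, 84, 40} with 60 replicates per tier at
n=500 and 30 cis-SNPs. These sizes are the package's chosen trade-off
between Monte-Carlo precision and turnaround on a single CPU.

## Known limitations

* The HWE filter rounds dosages to hard calls; imputation uncertainty is
  ignored there (dosages in (0.5, 1.5) round to heterozygote).
* The evaluation regression includes an intercept and uses normal (not t)
  tail probabilities; at the shipped sample sizes the difference is < 1e-3
  in the rejection rate.
* `lambda` selection at null-model weights (not per-grid-point IRLS) can in
  principle pick a slightly different penalty than a fully iterated
  selection; the nested evaluation guards against optimism either way.
* The locus clump anchors windows on gene midpoints; genes with very long
  spans may straddle windows.
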