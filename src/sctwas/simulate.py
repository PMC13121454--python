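"""Synthetic genotypes, single-cell counts, traits and GWAS summary statistics.

The generative chain mirrors the study design the package is evaluated under:

* genotypes: AR(1) Gaussian-copula haplotypes thresholded at the MAF quantile;
* expression: mu_i = g_i'beta + beta_0 on standardized genotypes with 10 causal
  cis-SNPs, per-cell latent expression z_ij ~ Gamma(shape=theta, scale=mu_i/theta)
  and counts x_ij | z_ij ~ Poisson(s_ij (z_ij + a_i)) with a per-individual
  random intercept a_i;
* trait: y_i = mu_i + e_i with Var(e) = (1-h2)/h2 * Var(mu) so the gene's GReX
  explains h2 of the trait variance;
* two-sample GWAS: marginal effects drawn from
  N(D^-1 V D b, (sigma^2/N) D^-1 V D^-1) with b = gamma_trait * beta scaled so
  beta' D V D beta * gamma_trait^2 = h2 and sigma^2 = 1 - h2.

All randomness flows from one root seed through numpy SeedSequence spawning;
replicate r uses the r-th child stream, so any replicate is reproducible in
isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.stats import norm

from .association import individual_level_test, twas_z
from .baselines import inverse_normal_transform, NormalizedGReXRegressor
from .data import GenotypeBlock, GWASSummary, SctwasError, CellCountMatrix
from .grex import CountGReXRegressor, evaluate_prediction_cv

logger = logging.getLogger(__name__)

#: cells-per-individual tiers of decreasing cell-type abundance
ABUNDANCE_TIERS = (472, 209, 84, 40, 10, 5)
#: Stage-2 Bonferroni divisor presets (number of Stage-1-significant genes per
#: cell type in the cohort the tiers are modeled on)
M_TESTS_BY_TIER = {472: 2189, 209: 1234, 84: 580, 40: 476, 10: 122, 5: 91}

# log-normal cell depth: median 3000 counts/cell, IQR 2000-5000
_DEPTH_MEDIAN = 3000.0
_DEPTH_SIGMA = math.log(5000 / 2000) / (2 * norm.ppf(0.75))


@dataclass
class SimulationConfig:
    """Study-condition knobs for the simulation harness (defaults = study design)."""

    n_individuals: int = 982
    n_snps: int = 30
    maf_range: tuple = (0.05, 0.5)
    ld_rho: float = 0.5
    n_causal: int = 10
    effect_low: float = 5e-9
    effect_high: float = 3e-6
    beta0: float = 1e-4
    theta_true: float = 10.0
    h2: float = 0.05
    n_gwas: float = 3e4
    cells_per_individual: int = 472
    cells_cv: float = 0.7                      # inter-individual CV of cell counts
    depth_median: float = _DEPTH_MEDIAN
    depth_sigma: float = _DEPTH_SIGMA
    intercept_sd: float | None = None          # default beta0 / 100
    null_stage1: bool = False
    null_stage2: bool = False
    pleiotropy_var: float = 0.0
    m_tests: int | None = None                 # default: tier preset
    n_replicates: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.h2 < 1):
            raise ValueError("h2 must be in [0, 1)")
        if self.beta0 <= 0 or self.theta_true <= 0:
            raise ValueError("beta0 and theta_true must be positive")
        if self.effect_low <= 0 or self.effect_high <= self.effect_low:
            raise ValueError("effect magnitudes must satisfy 0 < low < high")
        if self.intercept_sd is None:
            self.intercept_sd = self.beta0 / 100.0
        if self.m_tests is None:
            self.m_tests = M_TESTS_BY_TIER.get(self.cells_per_individual, 100)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class SimulatedCohort:
    """One simulated gene x cell-type cohort.

    Cell-level arrays are flat (one entry per cell); ``cell_individual_idx``
    maps each cell to its individual, since the number of cells per individual
    varies across the cohort.
    """

    genotypes: GenotypeBlock
    G: np.ndarray                              # standardized dosages used in mu
    true_beta: np.ndarray
    true_mu: np.ndarray
    intercepts: np.ndarray                     # a_i
    latent: np.ndarray                         # z_ij, flat over cells
    cell_counts: np.ndarray                    # x_ij, flat over cells
    cell_depths: np.ndarray                    # s_ij, flat over cells
    cell_individual_idx: np.ndarray            # individual index per cell
    n_cells: np.ndarray                        # cells per individual
    pseudo_x: np.ndarray                       # per-individual summed counts
    pseudo_s: np.ndarray                       # per-individual summed depths
    config: SimulationConfig

    def to_cell_count_matrix(self, gene_id: str = "simgene") -> CellCountMatrix:
        """Export as a two-gene cell matrix (focal gene + depth-filler gene)."""
        x = self.cell_counts.astype(np.int64)
        s = self.cell_depths.astype(np.int64)
        filler = np.maximum(s - x, 0)
        counts = np.column_stack([x, filler])
        return CellCountMatrix(
            counts=counts,
            gene_ids=np.array([gene_id, "background"]),
            cell_individual=np.array([f"I{i}" for i in self.cell_individual_idx]),
            cell_type=np.repeat("simulated", len(x)),
            cell_depth=x + filler,
        )


def simulate_genotypes(n: int, m: int, maf_range=(0.05, 0.5), rho: float = 0.5,
                       seed=0) -> GenotypeBlock:
    """AR(1)-correlated biallelic dosages with target MAFs drawn from ``maf_range``."""
    if not (0 <= rho < 1):
        raise ValueError("rho must be in [0, 1)")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie in (0, 0.5]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    target_maf = rng.uniform(lo, hi, size=m)
    thresh = norm.ppf(target_maf)
    for attempt in range(10):
        latent = np.empty((2 * n, m))
        latent[:, 0] = rng.standard_normal(2 * n)
        innov = rng.standard_normal((2 * n, m))
        scale = math.sqrt(1 - rho ** 2)
        for j in range(1, m):
            latent[:, j] = rho * latent[:, j - 1] + scale * innov[:, j]
        hap = (latent < thresh[None, :]).astype(np.int8)
        dosage = (hap[:n] + hap[n:]).astype(float)
        if np.all(dosage.std(axis=0) > 0):
            break
    else:
        raise SctwasError("monomorphic SNPs after 10 redraws; "
                          "increase n or the MAF floor")
    return GenotypeBlock(
        dosage=dosage,
        snp_id=np.array([f"snp{j}" for j in range(m)]),
        chrom=np.repeat("1", m),
        pos=np.arange(1, m + 1) * 10_000,
        a1=np.repeat("A", m),
        a2=np.repeat("G", m),
        individuals=np.array([f"I{i}" for i in range(n)]),
    )


def simulate_expression_counts(gb: GenotypeBlock, config: SimulationConfig,
                               seed=0) -> SimulatedCohort:
    """Draw the Gamma-Poisson single-cell counts for one gene.

    The Poisson rate is clamped at zero (the normal random intercept can push
    z_ij + a_i slightly negative); with the default intercept scale the clamp
    essentially never binds.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = gb.n_individuals
    m = gb.n_snps
    G = gb.standardized()
    theta = config.theta_true

    beta = np.zeros(m)
    if config.null_stage1:
        mu = np.full(n, config.beta0)
    else:
        for attempt in range(10):
            beta = np.zeros(m)
            causal = rng.choice(m, size=min(config.n_causal, m), replace=False)
            mag = rng.uniform(config.effect_low, config.effect_high, size=len(causal))
            sign = rng.choice([-1.0, 1.0], size=len(causal))
            beta[causal] = sign * mag
            mu = G @ beta + config.beta0
            if np.all(mu > 0):
                break
        else:
            raise SctwasError("could not draw causal effects keeping mu positive")

    # cells per individual: lognormal around the tier mean (the abundance
    # tiers are cohort means; real per-individual capture varies widely)
    J = config.cells_per_individual
    if config.cells_cv > 0:
        sig = math.sqrt(math.log(1.0 + config.cells_cv ** 2))
        n_cells = np.maximum(
            np.rint(rng.lognormal(math.log(J) - sig ** 2 / 2.0, sig, size=n)),
            1).astype(np.int64)
    else:
        n_cells = np.full(n, J, dtype=np.int64)
    idx = np.repeat(np.arange(n), n_cells)
    total = int(n_cells.sum())

    s = np.maximum(
        np.rint(rng.lognormal(math.log(config.depth_median), config.depth_sigma,
                              size=total)), 1.0)
    z = rng.gamma(shape=theta, scale=np.repeat(mu, n_cells) / theta, size=total)
    a = rng.normal(0.0, config.intercept_sd, size=n)
    rate = np.maximum(z + a[idx], 0.0)
    x = rng.poisson(s * rate).astype(np.int64)
    return SimulatedCohort(
        genotypes=gb, G=G, true_beta=beta, true_mu=mu, intercepts=a, latent=z,
        cell_counts=x, cell_depths=s, cell_individual_idx=idx, n_cells=n_cells,
        pseudo_x=np.bincount(idx, weights=x, minlength=n).astype(np.int64),
        pseudo_s=np.bincount(idx, weights=s, minlength=n), config=config,
    )


def simulate_trait(mu, h2: float, seed=0, null_stage2: bool = False):
    """Trait y = mu + e with Var(e) = (1-h2)/h2 Var(mu); or N(0,1) under the Stage-2 null."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mu = np.asarray(mu, float)
    if null_stage2:
        y = rng.standard_normal(len(mu))
        return y, y.copy()
    if h2 <= 0:
        raise SctwasError("h2 = 0 without the null_stage2 flag: trait variance undefined")
    var_mu = float(np.var(mu))
    if var_mu <= 0:
        raise SctwasError("Var(mu) = 0: cannot scale trait noise")
    e = rng.normal(0.0, math.sqrt((1 - h2) / h2 * var_mu), size=len(mu))
    return mu + e, e


@dataclass
class GwasSummarySim:
    b_gwas: np.ndarray
    gamma_trait: float
    sigma: float
    summary: GWASSummary


def default_pleiotropy_var(gb: GenotypeBlock, h2: float) -> float:
    """Direct-effect variance making the pleiotropic contribution equal the mediated h2."""
    return h2 / float(np.sum(gb.sd_diag ** 2))


def simulate_gwas_summary(true_beta, gb: GenotypeBlock, h2: float, n_gwas: float,
                          seed=0, pleiotropy_var: float = 0.0) -> GwasSummarySim:
    """LD-aware marginal GWAS summary statistics for the gene's cis-SNPs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    beta = np.asarray(true_beta, float)
    if not (0 <= h2 < 1):
        raise ValueError("h2 must be in [0, 1)")
    D = np.asarray(gb.sd_diag, float)
    V = np.asarray(gb.ld, float)
    DVD = (D[:, None] * V * D[None, :])
    quad = float(beta @ DVD @ beta)
    if h2 > 0:
        if quad <= 0:
            raise SctwasError("beta' DVD beta must be positive when h2 > 0")
        gamma_trait = math.sqrt(h2 / quad)
    else:
        gamma_trait = 0.0
    b = gamma_trait * beta
    if pleiotropy_var > 0:
        b = b + rng.normal(0.0, math.sqrt(pleiotropy_var), size=len(b))
    sigma2 = 1.0 - h2

    vals, vecs = np.linalg.eigh((V + V.T) / 2.0)
    vals = np.clip(vals, 0.0, None)
    Dinv = 1.0 / D
    mean = Dinv * (V @ (D * b))
    root = (Dinv[:, None] * vecs) * np.sqrt(vals * sigma2 / n_gwas)[None, :]
    beta_hat = mean + root @ rng.standard_normal(len(b))
    se = math.sqrt(sigma2) / (math.sqrt(n_gwas) * D)
    summary = GWASSummary(
        snp_id=gb.snp_id, a1=gb.a1, a2=gb.a2, z=beta_hat / se,
        n=n_gwas, beta_hat=beta_hat, se=se, chrom=gb.chrom, pos=gb.pos,
    )
    return GwasSummarySim(b_gwas=b, gamma_trait=gamma_trait,
                          sigma=math.sqrt(sigma2), summary=summary)


def wilson_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    z = norm.ppf(0.5 + level / 2.0)
    phat = k / n
    denom = 1 + z ** 2 / n
    center = (phat + z ** 2 / (2 * n)) / denom
    half = z * math.sqrt(phat * (1 - phat) / n + z ** 2 / (4 * n ** 2)) / denom
    # the interval contains phat analytically; enforce it under roundoff too
    return (max(0.0, min(center - half, phat)), min(1.0, max(center + half, phat)))


@dataclass
class PowerResult:
    """Per-method power / type-I rates and per-replicate Stage-1/2 p-values."""

    mode: str
    rates: dict
    ci: dict
    stage1_p: dict
    stage2_p: dict
    stage1_rate: dict
    stage2_rate: dict
    n_replicates: int
    n_failures: int
    config_hash: str


def _na_values(cohort: SimulatedCohort) -> np.ndarray:
    """Normalize-then-aggregate values of the focal gene (log-CPM mean + INT)."""
    logcpm = np.log1p(cohort.cell_counts / cohort.cell_depths * 1e6)
    n = len(cohort.true_mu)
    means = np.bincount(cohort.cell_individual_idx, weights=logcpm,
                        minlength=n) / cohort.n_cells
    return inverse_normal_transform(means)


def _an_values(cohort: SimulatedCohort) -> np.ndarray:
    """Aggregate-then-normalize values of the focal gene.

    With a single simulated gene the TMM factors have no other genes to be
    estimated from and are identically 1, so the recipe reduces to log-CPM of
    the pseudobulk counts (library size s_i) followed by INT.
    """
    logcpm = np.log1p(cohort.pseudo_x / cohort.pseudo_s * 1e6)
    return inverse_normal_transform(logcpm)


def _fit_stage1(method: str, cohort: SimulatedCohort, seed: int):
    """Returns (prediction_pvalue, beta_hat) for one method on one cohort."""
    G = cohort.G
    if method == "sctwas":
        x, s = cohort.pseudo_x.astype(float), cohort.pseudo_s.astype(float)
        p1 = evaluate_prediction_cv(x, s, G, seed=seed)
        est = CountGReXRegressor(random_state=seed).fit(G, x, depth=s)
        return p1, est.beta_
    xt = _na_values(cohort) if method == "na" else _an_values(cohort)
    est = NormalizedGReXRegressor(random_state=seed,
                                  method_tag=f"elasticnet_{method.upper()}")
    est.fit(G, xt)
    p1 = est.cv_prediction_pvalue(G, xt)
    return p1, est.beta_


def run_power_study(config: SimulationConfig, methods=("sctwas", "na", "an"),
                    mode: str = "one-sample") -> PowerResult:
    """Seeded power / type-I-error study over ``config.n_replicates`` replicates.

    A replicate succeeds (power mode) when Stage-1 prediction p < 0.05 and the
    Stage-2 p-value clears 0.05 / M; in the null scenarios both stages are held
    to the nominal 0.05. Replicate failures are logged and counted, never
    silently dropped.
    """
    if config.n_replicates < 1:
        raise SctwasError("n_replicates must be at least 1")
    null_mode = config.null_stage1 or config.null_stage2
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_replicates)

    stage1_p = {m: [] for m in methods}
    stage2_p = {m: [] for m in methods}
    n_failures = 0
    for rep, child in enumerate(children):
        rng = np.random.default_rng(child)
        fold_seed = int(child.generate_state(1)[0] % (2 ** 31))
        try:
            gb = simulate_genotypes(config.n_individuals, config.n_snps,
                                    config.maf_range, config.ld_rho, seed=rng)
            cohort = simulate_expression_counts(gb, config, seed=rng)
            if mode == "one-sample":
                y, _ = simulate_trait(cohort.true_mu, config.h2, seed=rng,
                                      null_stage2=config.null_stage2)
            else:
                h2_gwas = 0.0 if config.null_stage2 else config.h2
                sim_gwas = simulate_gwas_summary(
                    cohort.true_beta, gb, h2_gwas, config.n_gwas, seed=rng,
                    pleiotropy_var=config.pleiotropy_var)
            for method in methods:
                p1, beta_hat = _fit_stage1(method, cohort, fold_seed)
                if not np.any(beta_hat != 0):
                    p2 = 1.0
                elif mode == "one-sample":
                    p2 = individual_level_test(y, cohort.G @ beta_hat).pvalue
                else:
                    p2 = twas_z(beta_hat, sim_gwas.summary.z, gb.ld).pvalue
                stage1_p[method].append(p1)
                stage2_p[method].append(p2)
        except SctwasError as exc:
            n_failures += 1
            logger.warning("replicate %d failed: %s", rep, exc)
            for method in methods:
                stage1_p[method].append(np.nan)
                stage2_p[method].append(np.nan)

    thr2 = 0.05 if null_mode else 0.05 / config.m_tests
    rates, cis, r1, r2 = {}, {}, {}, {}
    for method in methods:
        p1 = np.array(stage1_p[method])
        p2 = np.array(stage2_p[method])
        ok = ~np.isnan(p1)
        joint = (p1[ok] < 0.05) & (p2[ok] < thr2)
        rates[method] = float(joint.mean()) if ok.any() else float("nan")
        cis[method] = wilson_ci(int(joint.sum()), int(ok.sum()))
        r1[method] = float((p1[ok] < 0.05).mean()) if ok.any() else float("nan")
        r2[method] = float((p2[ok] < thr2).mean()) if ok.any() else float("nan")
    return PowerResult(
        mode="type1" if null_mode else "power",
        rates=rates, ci=cis, stage1_p=stage1_p, stage2_p=stage2_p,
        stage1_rate=r1, stage2_rate=r2,
        n_replicates=config.n_replicates, n_failures=n_failures,
        config_hash=config.hash(),
    )
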