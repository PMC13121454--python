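"""Self-contained validation studies: solver oracles, calibration, power sweeps.

Each function recomputes a published-property check from scratch with seeded
randomness; they back both the acceptance test suite and the
``scripts/acceptance.py`` reporting script.  The oracles here (closed-form
weighted least squares, a FISTA proximal-gradient solver, brute-force
enumeration) are deliberately independent of the solver implementation in
:mod:`sctwas.grex`.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest, norm

from .association import individual_level_test, twas_z
from .data import GenotypeBlock
from .grex import (CountGReXRegressor, evaluate_prediction_cv,
                   fit_weighted_elastic_net, weighted_enet_objective)
from .simulate import (SimulationConfig, run_power_study,
                       simulate_expression_counts, simulate_genotypes,
                       simulate_trait, wilson_ci)


def _fista_enet(X, y, lam, n_iter=5000):
    """Independent proximal-gradient (FISTA) solver for
    min ||y - X b||^2 + lam (0.5 ||b||_1 + 0.5 ||b||_2^2)."""
    n, p = X.shape
    L = 2.0 * np.linalg.norm(X, 2) ** 2 + lam
    b = np.zeros(p)
    v = b.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = 2.0 * X.T @ (X @ v - y) + lam * v
        w = v - grad / L
        thresh = 0.5 * lam / L
        b_new = np.sign(w) * np.maximum(np.abs(w) - thresh, 0.0)
        t_new = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
        v = b_new + ((t - 1.0) / t_new) * (b_new - b)
        b, t = b_new, t_new
    return b


def solver_oracle_study(n_instances=50, n=30, p=10, q=3, seed=0) -> dict:
    """Compare the weighted elastic-net solver against two independent oracles.

    At lambda=0 the full (beta, gamma) solution must match closed-form weighted
    least squares; at lambda>0 the attained objective must match a FISTA
    proximal-gradient solve of the same (covariate-partialled) problem.
    Returns the max relative discrepancies over ``n_instances`` random draws.
    """
    rng = np.random.default_rng(seed)
    wls_err = 0.0
    prox_err = 0.0
    for _ in range(n_instances):
        G = rng.standard_normal((n, p))
        C = np.column_stack([np.ones(n), rng.standard_normal((n, q - 1))])
        s = rng.uniform(0.5, 2.0, n)
        w = rng.uniform(0.2, 3.0, n)
        coef_true = rng.standard_normal(p + q)
        A = np.column_stack([G * s[:, None], C * s[:, None]])
        x = A @ coef_true + rng.standard_normal(n)

        # lambda = 0: closed-form weighted least squares on [sG, sC]
        beta, gamma = fit_weighted_elastic_net(x, s, G, C, w, lam=0.0,
                                               standardize=False)
        AtW = A.T * w
        ref = np.linalg.solve(AtW @ A, AtW @ x)
        got = np.concatenate([beta, gamma])
        wls_err = max(wls_err, float(np.max(np.abs(got - ref))
                                     / max(np.max(np.abs(ref)), 1e-12)))

        # lambda > 0: objective vs FISTA on the residualized transformed problem
        # (the unpenalized covariate block is profiled out exactly by the
        # optimal gamma, so the reduced objectives are directly comparable)
        lam = 0.5
        beta, _ = fit_weighted_elastic_net(x, s, G, C, w, lam=lam,
                                           standardize=False)
        sw = np.sqrt(w)
        y_t = x * sw
        Xg = G * (s * sw)[:, None]
        Xc = C * (s * sw)[:, None]
        Q, _ = np.linalg.qr(Xc)
        yr = y_t - Q @ (Q.T @ y_t)
        Xr = Xg - Q @ (Q.T @ Xg)
        b_ref = _fista_enet(Xr, yr, lam)

        def reduced_obj(b):
            return (float(np.sum((yr - Xr @ b) ** 2))
                    + lam * (0.5 * np.sum(np.abs(b)) + 0.5 * np.sum(b ** 2)))

        prox_err = max(prox_err, abs(reduced_obj(beta) - reduced_obj(b_ref))
                       / max(abs(reduced_obj(b_ref)), 1e-12))
    return {"wls_max_rel_err": wls_err, "prox_obj_max_rel_err": prox_err}


def two_route_study(n_genes=200, n=500, m=20, seed=0) -> dict:
    """Correlation between summary-based and individual-level Stage-2 z-scores.

    For each simulated gene: train the count-based Stage-1 model, compute
    in-sample marginal GWAS z-scores and LD from the same cohort, and compare
    the summary-statistic z with the individual-level regression z.
    """
    root = np.random.SeedSequence(seed)
    z_summary, z_individual = [], []
    for child in root.spawn(n_genes):
        rng = np.random.default_rng(child)
        fold_seed = int(child.generate_state(1)[0] % (2 ** 31))
        gb = simulate_genotypes(n, m, rho=0.5, seed=rng)
        cfg = SimulationConfig(n_individuals=n, n_snps=m,
                               cells_per_individual=84, n_replicates=1, seed=0)
        cohort = simulate_expression_counts(gb, cfg, seed=rng)
        y, _ = simulate_trait(cohort.true_mu, cfg.h2, seed=rng)
        est = CountGReXRegressor(random_state=fold_seed).fit(
            cohort.G, cohort.pseudo_x.astype(float),
            depth=cohort.pseudo_s.astype(float))
        if not np.any(est.beta_ != 0):
            continue
        G = cohort.G
        z_gwas = np.array([individual_level_test(y, G[:, j]).z
                           for j in range(G.shape[1])])
        V = np.corrcoef(G, rowvar=False)
        z_summary.append(twas_z(est.beta_, z_gwas, V).z)
        z_individual.append(individual_level_test(y, est.predict(G)).z)
    corr = float(np.corrcoef(z_summary, z_individual)[0, 1])
    return {"correlation": corr, "n_genes": len(z_summary)}


def stage2_null_calibration(n_replicates=1000, n=500, m=20, n_cohorts=10,
                            seed=0) -> dict:
    """Stage-2 rejection rate at nominal 0.05 when the trait is N(0,1) noise.

    Trained GReX models are reused across independent trait draws (the trait is
    independent of everything, so each draw is a fresh null replicate).
    """
    root = np.random.SeedSequence(seed)
    models = []
    cohort_children = root.spawn(n_cohorts + 1)
    for child in cohort_children[:-1]:
        rng = np.random.default_rng(child)
        fold_seed = int(child.generate_state(1)[0] % (2 ** 31))
        gb = simulate_genotypes(n, m, rho=0.5, seed=rng)
        cfg = SimulationConfig(n_individuals=n, n_snps=m,
                               cells_per_individual=84, n_replicates=1, seed=0)
        cohort = simulate_expression_counts(gb, cfg, seed=rng)
        est = CountGReXRegressor(random_state=fold_seed).fit(
            cohort.G, cohort.pseudo_x.astype(float),
            depth=cohort.pseudo_s.astype(float))
        grex = est.predict(cohort.G)
        if np.ptp(grex) > 0:
            models.append(grex)
    rng = np.random.default_rng(cohort_children[-1])
    rejections = 0
    for rep in range(n_replicates):
        grex = models[rep % len(models)]
        y = rng.standard_normal(len(grex))
        if individual_level_test(y, grex).pvalue < 0.05:
            rejections += 1
    rate = rejections / n_replicates
    lo, hi = wilson_ci(rejections, n_replicates)
    return {"rate": rate, "ci": (lo, hi), "n": n_replicates}


def stage1_null_study(n_replicates=200, n=200, m=20, cells=84, seed=0) -> dict:
    """Stage-1 prediction p-values when expression is independent of genotype.

    Returns the p-values, the fraction flagged non-predictive (exactly 1, from
    all-zero cross-validated weight vectors) and a KS uniformity p-value over
    the testable replicates (p < 1).
    """
    root = np.random.SeedSequence(seed)
    pvals = []
    for child in root.spawn(n_replicates):
        rng = np.random.default_rng(child)
        fold_seed = int(child.generate_state(1)[0] % (2 ** 31))
        gb = simulate_genotypes(n, m, rho=0.5, seed=rng)
        cfg = SimulationConfig(n_individuals=n, n_snps=m,
                               cells_per_individual=cells, null_stage1=True,
                               n_replicates=1, seed=0)
        cohort = simulate_expression_counts(gb, cfg, seed=rng)
        pvals.append(evaluate_prediction_cv(
            cohort.pseudo_x.astype(float), cohort.pseudo_s.astype(float),
            cohort.G, seed=fold_seed))
    pvals = np.array(pvals)
    testable = pvals[pvals < 1.0]
    ks_p = float(kstest(testable, "uniform").pvalue) if len(testable) > 10 else float("nan")
    return {"pvalues": pvals, "frac_nonpredictive": float((pvals == 1.0).mean()),
            "ks_pvalue_testable": ks_p}


def moment_check_study(seed=0) -> dict:
    """Marginal-moment and summary-covariance checks of the generators.

    * Gamma-Poisson cells: mean/s vs mu and variance vs
      s mu + s^2 mu^2/theta + s^2 sd_a^2 over 1e5 cells at fixed mu, s.
    * Two-sample summary draw: empirical covariance of beta_hat over 5000
      draws vs (sigma^2/N) D^-1 V D^-1 on a 5-SNP block.
    * Trait noise: Var(e)/Var(mu) = (1-h2)/h2 = 19 at h2 = 0.05.
    """
    rng = np.random.default_rng(seed)
    # --- Gamma-Poisson marginal moments: 1e5 one-cell individuals, fixed s
    n_cells = 100_000
    cfg = SimulationConfig(n_individuals=n_cells, n_snps=2,
                           cells_per_individual=1, cells_cv=0.0,
                           null_stage1=True, depth_sigma=0.0,
                           n_replicates=1, seed=0)
    gb = simulate_genotypes(n_cells, 2, seed=rng)
    cohort = simulate_expression_counts(gb, cfg, seed=rng)
    s = float(cohort.cell_depths[0])
    mu = cfg.beta0
    x = cohort.cell_counts.astype(float)
    mean_expected = s * mu
    var_expected = s * mu + (s * mu) ** 2 / cfg.theta_true \
        + (s * cfg.intercept_sd) ** 2
    mean_err = abs(x.mean() - mean_expected)
    mean_se = np.sqrt(var_expected / n_cells)
    var_rel_err = abs(np.var(x) - var_expected) / var_expected

    # --- summary-statistic covariance on a 5-SNP high-LD block
    from .simulate import simulate_gwas_summary
    gb5 = simulate_genotypes(4000, 5, maf_range=(0.2, 0.4), rho=0.9, seed=rng)
    n_gwas = 1e4
    draws = np.array([
        simulate_gwas_summary(np.zeros(5), gb5, h2=0.0, n_gwas=n_gwas,
                              seed=rng).summary.beta_hat
        for _ in range(5000)])
    emp_cov = np.cov(draws, rowvar=False)
    Dinv = 1.0 / gb5.sd_diag
    cov_expected = (1.0 / n_gwas) * (Dinv[:, None] * gb5.ld * Dinv[None, :])
    cov_rel_err = float(np.max(np.abs(emp_cov - cov_expected)
                               / np.abs(cov_expected)))

    # --- trait noise-to-signal ratio at h2 = 0.05
    mu_tr = rng.normal(1e-4, 5e-6, size=10_000)
    _, e = simulate_trait(mu_tr, 0.05, seed=rng)
    ratio = float(np.var(e) / np.var(mu_tr))
    return {
        "mean_abs_err_in_se": float(mean_err / mean_se),
        "var_rel_err": float(var_rel_err),
        "gwas_cov_max_rel_err": cov_rel_err,
        "noise_signal_ratio": ratio,
        "noise_signal_ratio_construction": (1 - 0.05) / 0.05,
    }


def abundance_power_study(tiers=(472, 84, 40), n_replicates=60, n=500, m=30,
                          seed=0) -> dict:
    """One-sample power of all three methods across cell-abundance tiers."""
    results = {}
    for tier in tiers:
        cfg = SimulationConfig(n_individuals=n, n_snps=m,
                               cells_per_individual=tier,
                               n_replicates=n_replicates, seed=seed)
        results[tier] = run_power_study(cfg)
    return results


def make_two_snp_example() -> float:
    """The closed-form two-SNP summary-test example: z = 1.5 / sqrt(0.75)."""
    res = twas_z(np.array([0.5, 0.5]), np.array([2.0, 1.0]),
                 np.array([[1.0, 0.5], [0.5, 1.0]]))
    return res.z


def se_formula_example() -> float:
    """SE of a marginal GWAS effect at sigma=1, N=1e4, p=0.5."""
    from .simulate import simulate_gwas_summary
    gb = GenotypeBlock(
        dosage=np.array([[0.0], [1.0], [2.0], [1.0]]),
        snp_id=np.array(["s1"]), chrom=np.array(["1"]), pos=np.array([100]),
        a1=np.array(["A"]), a2=np.array(["G"]))
    sim = simulate_gwas_summary(np.array([0.0]), gb, h2=0.0, n_gwas=1e4, seed=0)
    return float(sim.summary.se[0])
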