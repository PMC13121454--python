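"""Count-based GReX model training.

Stage 1 models pseudobulk counts x_i with a measurement model: the latent
relative abundance z_i has mean mu_i = g_i'beta + c_i'gamma and biological
variance sigma_i^2 = mu_i^2 / theta, and x_i | z_i ~ Poisson(s_i z_i), giving

    E(x_i)   = s_i mu_i
    Var(x_i) = s_i mu_i + s_i^2 mu_i^2 / theta.

beta is estimated by minimizing the variance-weighted elastic-net loss

    sum_i w_i (x_i - s_i g_i'beta - s_i c_i'gamma)^2
        + lambda (0.5 ||beta||_1 + 0.5 ||beta||_2^2),

with w_i = 1 / Var(x_i), gamma unpenalized, and w_i updated by IRLS since they
depend on the coefficients.  The overdispersion theta and the initial weights
come from a covariate-only null model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import solve_triangular
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .data import CovariateMatrix, GReXModel, NotModelableError, SctwasError

MU_FLOOR = 1e-10
THETA_MIN, THETA_MAX = 1e-2, 1e6
#: elastic-net mixing: the penalty is lambda (0.5 ||b||_1 + 0.5 ||b||_2^2)
MIXING = 0.5


def _as_covariates(C, n: int) -> np.ndarray:
    if C is None:
        return np.ones((n, 1))
    if isinstance(C, CovariateMatrix):
        return C.values
    return np.asarray(C, dtype=float)


def compute_weights(mu: np.ndarray, s: np.ndarray, theta: float,
                    floor: float = MU_FLOOR) -> np.ndarray:
    """Inverse-variance observation weights 1 / (s mu + s^2 mu^2 / theta).

    mu is floored at a small positive value so the weights stay finite when the
    linear mean model produces nonpositive means.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("depths must be positive")
    m = np.maximum(np.asarray(mu, dtype=float), floor)
    return 1.0 / (s * m + (s * m) ** 2 / theta)


def estimate_null_overdispersion(x, s, C=None, theta_bounds=(THETA_MIN, THETA_MAX),
                                 floor: float = MU_FLOOR):
    """Estimate theta and initial weights from a covariate-only null model.

    The null mean is a Poisson GLM of x on C with log link and offset log(s)
    (closed form (sum x)/(sum s) for the intercept-only design); theta comes
    from the method of moments on the null residuals,

        theta = sum_i (s_i mu0_i)^2 / sum_i [ (x_i - s_i mu0_i)^2 - s_i mu0_i ],

    clamped to ``theta_bounds``; nonpositive denominators map to the upper
    clamp (Poisson-like data).  Returns (theta, weights, mu0).
    """
    x = np.asarray(x, dtype=float)
    s = np.asarray(s, dtype=float)
    C = _as_covariates(C, len(x))
    if len(x) < 10:
        raise NotModelableError("need at least 10 individuals")
    if x.sum() <= 0:
        raise NotModelableError("gene not modelable: all pseudobulk counts are zero")

    if C.shape[1] == 1 and np.allclose(C[:, 0], 1.0):
        mu0 = np.full(len(x), x.sum() / s.sum())
    else:
        try:
            import statsmodels.api as sm
            res = sm.GLM(x, C, family=sm.families.Poisson(),
                         offset=np.log(s)).fit(maxiter=100)
            mu0 = np.asarray(res.mu) / s
            if not np.all(np.isfinite(mu0)):
                raise ValueError
        except Exception:
            mu0 = np.full(len(x), x.sum() / s.sum())

    num = float(np.sum((s * mu0) ** 2))
    den = float(np.sum((x - s * mu0) ** 2 - s * mu0))
    lo, hi = theta_bounds
    theta = hi if den <= num / hi else min(max(num / den, lo), hi)
    return theta, compute_weights(mu0, s, theta, floor), mu0


class _WeightedProblem:
    """The transformed penalized problem at fixed weights.

    Response x_i sqrt(w_i); penalized predictors s_i g_i sqrt(w_i); the
    unpenalized covariate block s_i c_i sqrt(w_i) is partialled out exactly
    (valid because it carries no penalty), and the penalized block is
    optionally standardized to unit root-mean-square with coefficients
    back-transformed, mirroring glmnet's internal standardization.
    """

    def __init__(self, x, s, G, C, weights, standardize=True):
        x = np.asarray(x, dtype=float)
        s = np.asarray(s, dtype=float)
        G = np.atleast_2d(np.asarray(G, dtype=float))
        if G.size == 0:
            G = G.reshape(len(x), 0)
        C = _as_covariates(C, len(x))
        w = np.asarray(weights, dtype=float)
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(G))
                and np.all(np.isfinite(C)) and np.all(np.isfinite(w))):
            raise SctwasError("non-finite values in solver inputs")
        sw = np.sqrt(w)
        self.n = len(x)
        self.y = x * sw
        self.Xg = G * (s * sw)[:, None]
        self.Xc = C * (s * sw)[:, None]
        self.Q, self.R = np.linalg.qr(self.Xc)
        self.yr = self.y - self.Q @ (self.Q.T @ self.y)
        Xr = self.Xg - self.Q @ (self.Q.T @ self.Xg)
        if standardize and Xr.shape[1]:
            scale = np.sqrt(np.mean(Xr ** 2, axis=0))
            scale[scale < 1e-12] = 1.0
        else:
            scale = np.ones(Xr.shape[1])
        self.scale = scale
        self.Xs = Xr / scale if Xr.shape[1] else Xr

    def gamma_for(self, beta: np.ndarray) -> np.ndarray:
        rhs = self.Q.T @ (self.y - self.Xg @ beta)
        return solve_triangular(self.R, rhs)

    def lambda_max(self) -> float:
        if self.Xs.shape[1] == 0:
            return 1.0
        return max(4.0 * float(np.max(np.abs(self.Xs.T @ self.yr))), 1e-12)

    def _alpha(self, lam: float) -> float:
        # penalty lambda(0.5 l1 + 0.5 l2^2)  <->  sklearn alpha=3 lam/(4n), l1_ratio=1/3
        return 3.0 * lam / (4.0 * self.n)

    def solve(self, lam: float) -> tuple[np.ndarray, np.ndarray]:
        """Coefficients (beta, gamma) minimizing the penalized weighted loss."""
        p = self.Xs.shape[1]
        if p == 0:
            beta = np.zeros(0)
        elif lam == 0:
            beta = np.linalg.lstsq(self.Xs, self.yr, rcond=None)[0] / self.scale
        else:
            est = ElasticNet(alpha=self._alpha(lam), l1_ratio=1.0 / 3.0,
                             fit_intercept=False, max_iter=20000, tol=1e-8)
            est.fit(self.Xs, self.yr)
            beta = est.coef_ / self.scale
        return beta, self.gamma_for(beta)

    def path(self, lams: np.ndarray) -> np.ndarray:
        """beta for each lambda (descending order), shape (p, n_lambdas)."""
        p = self.Xs.shape[1]
        if p == 0:
            return np.zeros((0, len(lams)))
        alphas = np.array([self._alpha(l) for l in lams])
        _, coefs, _ = enet_path(self.Xs, self.yr, l1_ratio=1.0 / 3.0,
                                alphas=alphas, tol=1e-7)
        return coefs / self.scale[:, None]


def weighted_enet_objective(x, s, G, C, weights, lam, beta, gamma) -> float:
    """The penalized weighted loss at (beta, gamma), penalty on raw beta."""
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    G = np.atleast_2d(np.asarray(G, float))
    if G.size == 0:
        G = G.reshape(len(x), 0)
    C = _as_covariates(C, len(x))
    resid = x - s * (G @ beta) - s * (C @ gamma)
    return float(np.sum(weights * resid ** 2)
                 + lam * (0.5 * np.sum(np.abs(beta)) + 0.5 * np.sum(beta ** 2)))


def fit_weighted_elastic_net(x, s, G, C, weights, lam, standardize=True):
    """One weighted elastic-net fit at fixed weights; returns (beta, gamma)."""
    if lam < 0:
        raise ValueError("lambda must be nonnegative")
    return _WeightedProblem(x, s, G, C, weights, standardize=standardize).solve(lam)


def lambda_grid(lam_max: float, n_lambdas: int = 100,
                min_ratio: float = 1e-4) -> np.ndarray:
    """Log-spaced descending grid from lam_max down to min_ratio * lam_max."""
    if n_lambdas == 1:
        return np.array([lam_max])
    return lam_max * np.logspace(0, np.log10(min_ratio), n_lambdas)


@dataclass
class IRLSResult:
    beta: np.ndarray
    gamma: np.ndarray
    mu: np.ndarray
    weights: np.ndarray
    residual: np.ndarray
    theta: float
    lam: float
    n_iter: int
    converged: bool
    objective_trace: list = field(default_factory=list)


def irls_fit(x, s, G, C, lam, theta, weights0=None, max_iter=25, tol=1e-4,
             standardize=True, floor=MU_FLOOR) -> IRLSResult:
    """Iteratively re-weighted penalized fit at a fixed lambda and theta.

    Alternates (i) the weighted elastic-net fit at the current weights and
    (ii) the weight update w_i = 1/(s_i mu_i + s_i^2 mu_i^2/theta) from the
    refreshed mean mu_i = g_i'beta + c_i'gamma, until the max relative change
    in the coefficients drops below ``tol``.  If the loop exhausts
    ``max_iter`` the best-objective iterate is returned with converged=False.
    """
    x = np.asarray(x, float)
    s = np.asarray(s, float)
    G = np.atleast_2d(np.asarray(G, float))
    if G.size == 0:
        G = G.reshape(len(x), 0)
    C = _as_covariates(C, len(x))
    if weights0 is None:
        theta_est, weights0, _ = estimate_null_overdispersion(x, s, C, floor=floor)
        if theta is None:
            theta = theta_est
    w = np.asarray(weights0, float)

    coef_old = None
    best = None
    trace = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        prob = _WeightedProblem(x, s, G, C, w, standardize=standardize)
        beta, gamma = prob.solve(lam)
        obj = weighted_enet_objective(x, s, G, C, w, lam, beta, gamma)
        trace.append(obj)
        mu = G @ beta + C @ gamma
        w_new = compute_weights(mu, s, theta, floor=floor)
        coef = np.concatenate([beta, gamma])
        if best is None or obj < best[0]:
            resid = x - s * mu
            best = (obj, beta, gamma, mu, w, resid)
        if coef_old is not None:
            denom = max(float(np.max(np.abs(coef_old))), 1e-12)
            if float(np.max(np.abs(coef - coef_old))) / denom < tol:
                converged = True
                best = (obj, beta, gamma, mu, w, x - s * mu)
                break
        coef_old = coef
        w = w_new

    _, beta, gamma, mu, _, resid = best
    w_final = compute_weights(mu, s, theta, floor=floor)
    return IRLSResult(beta=beta, gamma=gamma, mu=mu, weights=w_final, residual=resid,
                      theta=theta, lam=lam, n_iter=n_iter, converged=converged,
                      objective_trace=trace)


def select_lambda_cv(x, s, G, C=None, k=5, seed=0, n_lambdas=100,
                     lambda_min_ratio=1e-4, standardize=True, weighted=True,
                     return_info=False):
    """Select lambda on a log-spaced grid by k-fold cross-validation.

    Training-fold fits run along the full path at the fold's null-model weights;
    the held-out loss is the weighted squared error with validation weights
    computed from the training-fold fitted mean.  Ties (the exact plateau where
    beta = 0) break toward the larger lambda.  With ``weighted=False`` the
    procedure reduces to the standard homoskedastic elastic-net CV (s=1, w=1).
    """
    x = np.asarray(x, float)
    s = np.asarray(s, float) if weighted else np.ones(len(x))
    G = np.atleast_2d(np.asarray(G, float))
    C = _as_covariates(C, len(x))
    n = len(x)
    if n < 2 * k:
        raise SctwasError(f"need at least {2 * k} samples for {k}-fold CV")

    if weighted:
        theta_full, w_full, _ = estimate_null_overdispersion(x, s, C)
    else:
        theta_full, w_full = None, np.ones(n)
    grid = lambda_grid(_WeightedProblem(x, s, G, C, w_full,
                                        standardize=standardize).lambda_max(),
                       n_lambdas, lambda_min_ratio)

    losses = np.zeros(len(grid))
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, va in folds.split(x):
        if weighted:
            theta_f, w_tr, _ = estimate_null_overdispersion(x[tr], s[tr], C[tr])
        else:
            theta_f, w_tr = None, np.ones(len(tr))
        prob = _WeightedProblem(x[tr], s[tr], G[tr], C[tr], w_tr,
                                standardize=standardize)
        betas = prob.path(grid)
        for idx in range(len(grid)):
            beta = betas[:, idx]
            gamma = prob.gamma_for(beta)
            mu_va = G[va] @ beta + C[va] @ gamma
            if weighted:
                w_va = compute_weights(mu_va, s[va], theta_f)
            else:
                w_va = np.ones(len(va))
            losses[idx] += float(np.sum(w_va * (x[va] - s[va] * mu_va) ** 2))

    best = int(np.argmin(losses))             # grid descends: first min = largest lambda
    if return_info:
        return grid[best], {"grid": grid, "cv_loss": losses, "theta": theta_full,
                            "weights0": w_full}
    return grid[best]


def _wald_slope_pvalue(x, pred, weights=None, intercept=None):
    """Two-sided Wald p-value for the slope of x on pred.

    ``intercept`` is the baseline column (all-ones by default; the
    depth-scaled intercept s_i for the count-scale evaluation, matching the
    measurement model whose covariate block is scaled by depth).
    """
    n = len(x)
    w = np.ones(n) if weights is None else np.asarray(weights, float)
    base = np.ones(n) if intercept is None else np.asarray(intercept, float)
    A = np.column_stack([base, pred])
    AtW = A.T * w
    cov_inv = AtW @ A
    try:
        coef = np.linalg.solve(cov_inv, AtW @ x)
    except np.linalg.LinAlgError:
        return 1.0, 0.0
    resid = x - A @ coef
    dof = max(n - 2, 1)
    sigma2 = float(np.sum(w * resid ** 2)) / dof
    cov = sigma2 * np.linalg.inv(cov_inv)
    se = np.sqrt(cov[1, 1])
    if se == 0 or not np.isfinite(se):
        return 1.0, 0.0
    z = coef[1] / se
    return float(2.0 * norm.sf(abs(z))), float(z)


def evaluate_prediction_cv(x, s, G, C=None, k=5, seed=0, n_lambdas=100,
                           lambda_min_ratio=1e-4, standardize=True,
                           weighted=True, return_info=False):
    """Cross-validated prediction p-value for the genetic component.

    Nested scheme: lambda is re-selected by inner CV within each outer training
    fold; the observed counts are regressed on the held-out predictions
    s_i g_i'beta (concatenated over folds) plus the depth-scaled intercept
    s_i, with weights from each fold's fitted model, and the two-sided Wald
    p-value of the slope is returned.  The depth-scaled intercept matches the
    measurement model, whose covariate block is scaled by depth; in the
    unweighted (normalized-expression) mode it reduces to the ordinary
    intercept.  If every fold's beta is the zero vector the gene is flagged
    non-predictive (p = 1).
    """
    x = np.asarray(x, float)
    s = np.asarray(s, float) if weighted else np.ones(len(x))
    G = np.atleast_2d(np.asarray(G, float))
    C = _as_covariates(C, len(x))
    n = len(x)

    pred = np.zeros(n)
    wts = np.ones(n)
    any_nonzero = False
    folds = KFold(n_splits=k, shuffle=True, random_state=seed)
    for tr, va in folds.split(x):
        lam = select_lambda_cv(x[tr], s[tr], G[tr], C[tr], k=k, seed=seed,
                               n_lambdas=n_lambdas,
                               lambda_min_ratio=lambda_min_ratio,
                               standardize=standardize, weighted=weighted)
        if weighted:
            theta_f, w0, _ = estimate_null_overdispersion(x[tr], s[tr], C[tr])
            fit = irls_fit(x[tr], s[tr], G[tr], C[tr], lam, theta_f, w0,
                           standardize=standardize)
            mu_va = G[va] @ fit.beta + C[va] @ fit.gamma
            wts[va] = compute_weights(mu_va, s[va], theta_f)
        else:
            prob = _WeightedProblem(x[tr], s[tr], G[tr], C[tr],
                                    np.ones(len(tr)), standardize=standardize)
            fit_beta, fit_gamma = prob.solve(lam)
            fit = IRLSResult(beta=fit_beta, gamma=fit_gamma, mu=np.zeros(0),
                             weights=np.ones(len(tr)), residual=np.zeros(0),
                             theta=np.nan, lam=lam, n_iter=1, converged=True)
        pred[va] = s[va] * (G[va] @ fit.beta)
        if np.any(fit.beta != 0):
            any_nonzero = True

    flag = None
    if not any_nonzero:
        p, z = 1.0, 0.0
        flag = "non-predictive"
    elif np.ptp(pred) == 0:
        p, z = 1.0, 0.0
        flag = "degenerate-predictor"
    else:
        p, z = _wald_slope_pvalue(x, pred, wts if weighted else None,
                                  intercept=s if weighted else None)
    if return_info:
        return p, {"pred": pred, "weights": wts, "flag": flag, "z": z}
    return p


def predict_grex(G_new, model) -> np.ndarray:
    """Predicted GReX G_new @ beta (covariates and depths excluded).

    ``model`` may be a fitted estimator, an IRLSResult, or a GReXModel record.
    The caller is responsible for allele orientation; use
    :func:`sctwas.association.harmonize_alleles` when mixing sources.
    """
    beta = getattr(model, "beta_", None)
    if beta is None:
        beta = model.beta
    G_new = np.atleast_2d(np.asarray(G_new, float))
    if G_new.shape[1] != len(beta):
        raise SctwasError(
            f"SNP dimension mismatch: genotypes have {G_new.shape[1]}, model has "
            f"{len(beta)}; harmonize alleles/SNPs first")
    return G_new @ np.asarray(beta, float)


class CountGReXRegressor(RegressorMixin, BaseEstimator):
    """Genetically-regulated-expression model on pseudobulk counts.

    Fits the measurement-model weighted elastic net by IRLS: overdispersion and
    initial weights from a covariate-only null fit, lambda by seeded k-fold CV,
    then alternating coefficient/weight updates.  ``predict`` returns the GReX
    g'beta on the relative-abundance scale.

    Parameters
    ----------
    n_lambdas, lambda_min_ratio : grid of candidate penalties, log-spaced down
        from the smallest lambda that zeroes beta.
    cv : folds for lambda selection and prediction evaluation.
    max_iter, tol : IRLS stopping rule (max relative coefficient change).
    standardize : standardize the penalized block internally (glmnet-style),
        back-transforming coefficients.
    random_state : seed for the CV fold partition.
    """

    mixing = MIXING

    def __init__(self, n_lambdas=100, lambda_min_ratio=1e-4, cv=5, max_iter=25,
                 tol=1e-4, standardize=True, mu_floor=MU_FLOOR, random_state=0):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.max_iter = max_iter
        self.tol = tol
        self.standardize = standardize
        self.mu_floor = mu_floor
        self.random_state = random_state

    def fit(self, G, x, depth=None, covariates=None, lam=None):
        G = np.atleast_2d(np.asarray(G, float))
        x = np.asarray(x, float)
        if depth is None:
            raise ValueError("depth (per-individual sequencing depth s_i) is required")
        s = np.asarray(depth, float)
        C = _as_covariates(covariates, len(x))
        theta, w0, mu0 = estimate_null_overdispersion(x, s, C, floor=self.mu_floor)
        if lam is None:
            lam = select_lambda_cv(x, s, G, C, k=self.cv, seed=self.random_state,
                                   n_lambdas=self.n_lambdas,
                                   lambda_min_ratio=self.lambda_min_ratio,
                                   standardize=self.standardize)
        res = irls_fit(x, s, G, C, lam, theta, w0, max_iter=self.max_iter,
                       tol=self.tol, standardize=self.standardize,
                       floor=self.mu_floor)
        self.beta_ = res.beta
        self.gamma_ = res.gamma
        self.lambda_ = float(lam)
        self.theta_ = float(theta)
        self.mu_ = res.mu
        self.weights_ = res.weights
        self.residual_ = res.residual
        self.n_iter_ = res.n_iter
        self.converged_ = res.converged
        self.objective_trace_ = res.objective_trace
        self.n_features_in_ = G.shape[1]
        return self

    def predict(self, G):
        check_is_fitted(self, "beta_")
        return np.atleast_2d(np.asarray(G, float)) @ self.beta_

    def cv_prediction_pvalue(self, G, x, depth, covariates=None):
        """Nested-CV prediction p-value; stored as ``prediction_pvalue_``."""
        p, info = evaluate_prediction_cv(
            x, depth, G, covariates, k=self.cv, seed=self.random_state,
            n_lambdas=self.n_lambdas, lambda_min_ratio=self.lambda_min_ratio,
            standardize=self.standardize, weighted=True, return_info=True)
        self.prediction_pvalue_ = p
        self.predictive_flag_ = info["flag"]
        return p

    def to_model(self, gene_id, cell_type, snp_id, a1, a2,
                 method_tag="sctwas") -> GReXModel:
        check_is_fitted(self, "beta_")
        return GReXModel(
            gene_id=gene_id, cell_type=cell_type,
            snp_id=np.asarray(snp_id), a1=np.asarray(a1), a2=np.asarray(a2),
            beta=self.beta_, gamma=self.gamma_, lam=self.lambda_,
            theta=self.theta_,
            prediction_pvalue=getattr(self, "prediction_pvalue_", None),
            method_tag=method_tag, mixing=self.mixing,
            n_iter=self.n_iter_, converged=self.converged_,
            mu=self.mu_, weights=self.weights_, residual=self.residual_,
            predictive_flag=getattr(self, "predictive_flag_", None),
        )
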