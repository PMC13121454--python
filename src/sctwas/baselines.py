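"""Baseline normalization-based GReX pipelines.

Two comparison recipes operate on normalized continuous expression x~_i and the
standard homoskedastic elastic net

    sum_i (x~_i - g_i'beta - c_i'gamma)^2 + lambda (0.5 ||beta||_1 + 0.5 ||beta||_2^2):

* NA (normalize-then-aggregate): per-cell CPM -> log(CPM+1) -> per-individual
  mean over cells -> per-gene rank-based inverse normal transform (INT).
* AN (aggregate-then-normalize): pseudobulk counts -> TMM effective library
  sizes -> log(CPM+1) -> per-gene INT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from .data import CellCountMatrix, GReXModel, PseudobulkDataset, SctwasError
from .grex import (_WeightedProblem, _as_covariates, evaluate_prediction_cv,
                   select_lambda_cv, MIXING)

logger = logging.getLogger(__name__)


@dataclass
class NormalizedExpression:
    """Individual x gene normalized expression produced by the NA or AN recipe."""

    values: np.ndarray
    gene_ids: np.ndarray
    individuals: np.ndarray
    recipe: str                              # "NA" | "AN"
    tmm_factors: np.ndarray | None = None

    def gene_values(self, gene_id) -> np.ndarray:
        j = np.flatnonzero(self.gene_ids == gene_id)
        if j.size == 0:
            raise KeyError(gene_id)
        return self.values[:, j[0]]


def inverse_normal_transform(v) -> np.ndarray:
    """Rank-based INT: v'_i = Phi^{-1}((rank_i - 0.5)/n), average ranks for ties."""
    v = np.asarray(v, dtype=float)
    if len(v) < 3:
        raise SctwasError("inverse normal transform needs at least 3 values")
    r = rankdata(v, method="average")
    return norm.ppf((r - 0.5) / len(v))


def tmm_factors(pb: PseudobulkDataset, logratio_trim: float = 0.3,
                abs_trim: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values scaling factors, rescaled to geometric mean 1.

    The reference sample is the one whose upper-quartile/depth ratio is closest
    to the mean such ratio.  For each sample, M (log2 expression ratio to the
    reference) and A (average log2 abundance) are computed over genes expressed
    in both, doubly trimmed (30% on M, 5% on A by default), and combined by a
    precision-weighted mean; the factor is 2 to that mean.
    """
    counts = np.asarray(pb.counts, dtype=float)
    lib = np.asarray(pb.depth, dtype=float)
    n = counts.shape[0]
    if n < 2:
        raise SctwasError("TMM needs at least 2 samples")
    if np.any(lib <= 0):
        raise SctwasError("TMM needs positive depths")

    f75 = np.array([np.quantile(counts[i], 0.75) / lib[i] for i in range(n)])
    ref = int(np.argmin(np.abs(f75 - f75.mean())))

    factors = np.ones(n)
    for i in range(n):
        if i == ref:
            continue
        both = (counts[i] > 0) & (counts[ref] > 0)
        if not both.any():
            logger.warning("sample %d shares no expressed genes with the reference; "
                           "TMM factor set to 1", i)
            continue
        oi, orf = counts[i, both], counts[ref, both]
        ri, rr = oi / lib[i], orf / lib[ref]
        M = np.log2(ri / rr)
        A = 0.5 * np.log2(ri * rr)
        if np.max(np.abs(M)) < 1e-6:          # identical relative profiles
            continue
        # delta-method variance of M; the weighted mean uses its inverse
        v = (lib[i] - oi) / (lib[i] * oi) + (lib[ref] - orf) / (lib[ref] * orf)
        m = len(M)
        loM = np.floor(m * logratio_trim) + 1
        hiM = m + 1 - loM
        loA = np.floor(m * abs_trim) + 1
        hiA = m + 1 - loA
        rM = rankdata(M, method="average")
        rA = rankdata(A, method="average")
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if not keep.any():
            continue
        factors[i] = 2.0 ** (np.sum(M[keep] / v[keep]) / np.sum(1.0 / v[keep]))
    return factors / np.exp(np.mean(np.log(factors)))


def na_normalize(cells: CellCountMatrix, cell_type: str) -> NormalizedExpression:
    """Normalize-then-aggregate: cell CPM -> log1p -> mean per individual -> INT."""
    from .pseudobulk import ALL_CELL_TYPES

    if cell_type == ALL_CELL_TYPES:
        mask = np.ones(cells.n_cells, dtype=bool)
    else:
        mask = cells.cell_type == cell_type
        if not mask.any():
            raise SctwasError(f"no cells of type {cell_type!r}; "
                              f"available: {cells.cell_types()}")
    counts = np.asarray(cells.counts[mask], dtype=float)
    depth = np.asarray(cells.cell_depth[mask], dtype=float)
    logcpm = np.log1p(counts / depth[:, None] * 1e6)
    inds = cells.cell_individual[mask]
    order = pd.unique(inds)
    codes = pd.Categorical(inds, categories=order).codes
    agg = np.zeros((len(order), cells.n_genes))
    np.add.at(agg, codes, logcpm)
    agg /= np.bincount(codes)[:, None]
    # deterministic ordering of equal aggregated values: stable by individual ID
    values = np.column_stack([inverse_normal_transform(agg[:, j])
                              for j in range(agg.shape[1])])
    return NormalizedExpression(values=values, gene_ids=cells.gene_ids,
                                individuals=order, recipe="NA")


def an_normalize(pb: PseudobulkDataset) -> NormalizedExpression:
    """Aggregate-then-normalize: TMM effective sizes -> log(CPM+1) -> INT."""
    factors = tmm_factors(pb)
    eff = pb.depth * factors
    logcpm = np.log1p(np.asarray(pb.counts, dtype=float) / eff[:, None] * 1e6)
    values = np.column_stack([inverse_normal_transform(logcpm[:, j])
                              for j in range(logcpm.shape[1])])
    return NormalizedExpression(values=values, gene_ids=pb.gene_ids,
                                individuals=pb.individuals, recipe="AN",
                                tmm_factors=factors)


class NormalizedGReXRegressor(RegressorMixin, BaseEstimator):
    """Standard elastic net on normalized expression (the NA/AN Stage-1 model).

    Minimizes the homoskedastic loss with the same 0.5/0.5 penalty as the
    count-based model, gamma unpenalized, lambda by seeded k-fold CV.  Shares
    the solver core with the weighted model through s = 1, w = 1.
    """

    mixing = MIXING

    def __init__(self, n_lambdas=100, lambda_min_ratio=1e-4, cv=5,
                 standardize=True, method_tag="elasticnet_NA", random_state=0):
        self.n_lambdas = n_lambdas
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.standardize = standardize
        self.method_tag = method_tag
        self.random_state = random_state

    def fit(self, G, x, covariates=None, lam=None):
        G = np.atleast_2d(np.asarray(G, float))
        x = np.asarray(x, float)
        C = _as_covariates(covariates, len(x))
        ones = np.ones(len(x))
        if lam is None:
            lam = select_lambda_cv(x, ones, G, C, k=self.cv,
                                   seed=self.random_state,
                                   n_lambdas=self.n_lambdas,
                                   lambda_min_ratio=self.lambda_min_ratio,
                                   standardize=self.standardize, weighted=False)
        prob = _WeightedProblem(x, ones, G, C, ones, standardize=self.standardize)
        self.beta_, self.gamma_ = prob.solve(lam)
        self.lambda_ = float(lam)
        self.residual_ = x - G @ self.beta_ - C @ self.gamma_
        self.n_features_in_ = G.shape[1]
        return self

    def predict(self, G):
        check_is_fitted(self, "beta_")
        return np.atleast_2d(np.asarray(G, float)) @ self.beta_

    def cv_prediction_pvalue(self, G, x, covariates=None):
        """Unweighted nested-CV prediction p-value; stored as ``prediction_pvalue_``."""
        p, info = evaluate_prediction_cv(
            x, np.ones(len(x)), G, covariates, k=self.cv,
            seed=self.random_state, n_lambdas=self.n_lambdas,
            lambda_min_ratio=self.lambda_min_ratio,
            standardize=self.standardize, weighted=False, return_info=True)
        self.prediction_pvalue_ = p
        self.predictive_flag_ = info["flag"]
        return p

    def to_model(self, gene_id, cell_type, snp_id, a1, a2) -> GReXModel:
        check_is_fitted(self, "beta_")
        return GReXModel(
            gene_id=gene_id, cell_type=cell_type,
            snp_id=np.asarray(snp_id), a1=np.asarray(a1), a2=np.asarray(a2),
            beta=self.beta_, gamma=self.gamma_, lam=self.lambda_, theta=None,
            prediction_pvalue=getattr(self, "prediction_pvalue_", None),
            method_tag=self.method_tag, mixing=self.mixing,
            residual=self.residual_,
            predictive_flag=getattr(self, "predictive_flag_", None),
        )


def fit_elastic_net_standard(x_tilde, G, C=None, k=5, seed=0,
                             method_tag="elasticnet_NA") -> NormalizedGReXRegressor:
    """Functional wrapper over :class:`NormalizedGReXRegressor`."""
    est = NormalizedGReXRegressor(cv=k, random_state=seed, method_tag=method_tag)
    return est.fit(G, x_tilde, covariates=C)


def evaluate_prediction_ols(x_tilde, G, C=None, k=5, seed=0):
    """Unweighted cross-validated prediction p-value for normalized expression."""
    return evaluate_prediction_cv(x_tilde, np.ones(len(x_tilde)), G, C, k=k,
                                  seed=seed, weighted=False)
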