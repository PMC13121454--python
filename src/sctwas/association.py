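"""Stage-2 association testing, multiple-testing control and locus definition.

The summary-statistic test combines Stage-1 SNP weights beta with marginal GWAS
z-scores and an LD matrix V:

    z = beta' z_GWAS / sqrt(beta' V beta),

standard normal under the null; V is projected to the nearest PSD matrix by
eigenvalue clipping before the quadratic form.  With individual-level data the
same hypothesis is tested by regressing the trait on the predicted GReX.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .data import GWASSummary, SctwasError, UntestableGeneError

logger = logging.getLogger(__name__)

MIN_PVALUE = np.finfo(float).tiny            # smallest positive normal double
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class TwasResult:
    gene_id: str
    cell_type: str
    z: float
    pvalue: float
    n_tests: int = 1
    significant: bool | None = None
    flag: str | None = None

    def __post_init__(self) -> None:
        if self.flag is None and np.isfinite(self.z):
            expect = max(2.0 * norm.sf(abs(self.z)), MIN_PVALUE)
            if abs(self.pvalue - expect) > 1e-12 * max(expect, 1.0):
                raise ValueError("pvalue inconsistent with z")


@dataclass
class Locus:
    chrom: str
    window_start: float
    window_end: float
    member_genes: list = field(default_factory=list)
    lead_gene: str = ""
    status: str | None = None                # "known" | "novel"


def harmonize_alleles(model_snp_id, model_a1, model_a2, gwas: GWASSummary):
    """Align GWAS z-scores to the model's allele orientation.

    Matches on SNP id; flips the z sign when the model's a1/a2 are swapped
    relative to the GWAS; drops strand-ambiguous (A/T, C/G) pairs, allele
    mismatches and unmatched SNPs.  Returns (z_aligned, keep_mask) where the
    mask indexes the model's SNPs so beta and V can be subset consistently.
    """
    model_snp_id = np.asarray(model_snp_id)
    model_a1 = np.char.upper(np.asarray(model_a1, dtype=str))
    model_a2 = np.char.upper(np.asarray(model_a2, dtype=str))
    gw = {str(sid): (str(a1).upper(), str(a2).upper(), float(z))
          for sid, a1, a2, z in zip(gwas.snp_id, gwas.a1, gwas.a2, gwas.z)}

    keep = np.zeros(len(model_snp_id), dtype=bool)
    z_out = []
    for j, sid in enumerate(model_snp_id):
        rec = gw.get(str(sid))
        if rec is None:
            continue
        ga1, ga2, z = rec
        if frozenset((model_a1[j], model_a2[j])) in _AMBIGUOUS:
            continue
        if (model_a1[j], model_a2[j]) == (ga1, ga2):
            keep[j] = True
            z_out.append(z)
        elif (model_a1[j], model_a2[j]) == (ga2, ga1):
            keep[j] = True
            z_out.append(-z)
        # allele mismatch: drop
    if not keep.any():
        raise UntestableGeneError("no SNPs remain after allele harmonization")
    return np.array(z_out), keep


def _psd_clip(V: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh((V + V.T) / 2.0)
    return (vecs * np.clip(vals, 0.0, None)) @ vecs.T


def twas_z(beta, z_gwas, V, gene_id: str = "", cell_type: str = "") -> TwasResult:
    """Summary-statistic association z-score and p-value for one gene."""
    beta = np.asarray(beta, float)
    z_gwas = np.asarray(z_gwas, float)
    V = np.asarray(V, float)
    if not np.any(beta != 0):
        raise UntestableGeneError("beta is the zero vector; no test")
    denom = float(beta @ _psd_clip(V) @ beta)
    # z is scale-invariant in beta, so degeneracy is judged relative to
    # ||beta||^2 (V has unit diagonal): catches weights living entirely in
    # the null space of the clipped LD matrix at any coefficient scale
    if denom <= 1e-12 * float(beta @ beta):
        raise UntestableGeneError("degenerate variance, no test")
    z = float(beta @ z_gwas) / np.sqrt(denom)
    p = 2.0 * norm.sf(abs(z))
    flag = None
    if p < MIN_PVALUE:
        p, flag = MIN_PVALUE, "pvalue-underflow"
    return TwasResult(gene_id=gene_id, cell_type=cell_type, z=z, pvalue=p, flag=flag)


def individual_level_test(y, grex, C=None, gene_id: str = "",
                          cell_type: str = "") -> TwasResult:
    """Wald test of the GReX coefficient in a linear regression of the trait.

    Design: [intercept, grex, covariates].  Returns z and the two-sided normal
    p-value; a constant GReX vector yields an untestable flag with p = 1.
    """
    y = np.asarray(y, float)
    grex = np.asarray(grex, float)
    if np.ptp(grex) == 0:
        return TwasResult(gene_id=gene_id, cell_type=cell_type, z=0.0, pvalue=1.0,
                          flag="untestable")
    n = len(y)
    extra = np.zeros((n, 0))
    if C is not None:
        Cv = C.values if hasattr(C, "values") else np.atleast_2d(np.asarray(C, float))
        # drop an intercept column if the covariate matrix carries one
        extra = Cv[:, 1:] if np.allclose(Cv[:, 0], 1.0) else Cv
    A = np.column_stack([np.ones(n), grex, extra])
    k = 1                                     # grex column
    coef, _, _, _ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = max(n - A.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(A.T @ A)
    se = np.sqrt(cov[k, k])
    if se == 0 or not np.isfinite(se):
        return TwasResult(gene_id=gene_id, cell_type=cell_type, z=0.0, pvalue=1.0,
                          flag="untestable")
    z = float(coef[k] / se)
    p = 2.0 * norm.sf(abs(z))
    flag = None
    if p < MIN_PVALUE:
        p, flag = MIN_PVALUE, "pvalue-underflow"
    return TwasResult(gene_id=gene_id, cell_type=cell_type, z=z, pvalue=p, flag=flag)


def bonferroni_filter(results: list[TwasResult], alpha: float = 0.05,
                      m: int | None = None) -> list[TwasResult]:
    """Flag results significant at alpha / M; M defaults to len(results)."""
    m = len(results) if m is None else int(m)
    if m < 1:
        raise SctwasError("M must be at least 1")
    for r in results:
        r.n_tests = m
        r.significant = bool(r.pvalue < alpha / m)
    return results


def define_loci(significant_results: list[TwasResult], gene_positions: dict,
                window: int = 1_000_000) -> list[Locus]:
    """Greedy 1-Mb clumping of significant genes by p-value rank.

    ``gene_positions`` maps gene_id -> (chrom, midpoint).  Repeatedly takes the
    unassigned gene with the smallest p-value, opens a window of ``window``
    base pairs centered on its midpoint, and assigns every unassigned gene on
    the same chromosome whose midpoint falls inside it.
    """
    remaining = sorted(significant_results, key=lambda r: (r.pvalue, r.gene_id))
    loci: list[Locus] = []
    assigned: set[str] = set()
    for lead in remaining:
        if lead.gene_id in assigned:
            continue
        chrom, mid = gene_positions[lead.gene_id]
        start, end = mid - window / 2.0, mid + window / 2.0
        members = []
        for r in remaining:
            if r.gene_id in assigned:
                continue
            c, m_ = gene_positions[r.gene_id]
            if str(c) == str(chrom) and start <= m_ < end:
                members.append(r.gene_id)
                assigned.add(r.gene_id)
        loci.append(Locus(chrom=str(chrom), window_start=start, window_end=end,
                          member_genes=members, lead_gene=lead.gene_id))
    return loci


def classify_novel(loci: list[Locus], gwas: GWASSummary,
                   gw_threshold: float = 5e-8) -> list[Locus]:
    """Mark each locus known iff it harbors a genome-wide significant GWAS variant."""
    if gwas.chrom is None or gwas.pos is None:
        raise SctwasError("GWAS summary lacks positions; cannot classify loci")
    p = gwas.pvalues()
    chrom = np.asarray(gwas.chrom).astype(str)
    pos = np.asarray(gwas.pos)
    for locus in loci:
        inside = (chrom == locus.chrom) & (pos >= locus.window_start) \
            & (pos < locus.window_end)
        locus.status = "known" if np.any(p[inside] < gw_threshold) else "novel"
    return loci
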