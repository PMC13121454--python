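"""Core containers for cell-level counts, pseudobulk, genotypes and GWAS summaries.

All containers are light dataclasses around numpy arrays / pandas indexes; heavier
behaviour (aggregation, QC, model fitting) lives in the dedicated modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class SctwasError(Exception):
    """Base class for labeled errors raised by this package."""


class ParseError(SctwasError):
    """A file violated its declared format; message carries the line number."""


class UntestableGeneError(SctwasError):
    """A gene cannot be tested (no SNPs after harmonization, degenerate variance...)."""


class NotModelableError(SctwasError):
    """A gene cannot be modelled in Stage 1 (all-zero counts, empty cis-window...)."""


@dataclass
class CellCountMatrix:
    """Cell x gene UMI counts with per-cell individual / cell-type labels.

    ``cell_depth`` is the per-cell total UMI count over *all* genes (s_ij); when the
    matrix holds every gene it equals the row sums, but a sliced matrix keeps the
    original depths.
    """

    counts: np.ndarray                       # (n_cells, n_genes), nonnegative ints
    gene_ids: np.ndarray
    cell_individual: np.ndarray              # (n_cells,)
    cell_type: np.ndarray                    # (n_cells,)
    cell_depth: np.ndarray                   # (n_cells,) total counts over all genes

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")
        self.gene_ids = np.asarray(self.gene_ids)
        self.cell_individual = np.asarray(self.cell_individual)
        self.cell_type = np.asarray(self.cell_type)
        self.cell_depth = np.asarray(self.cell_depth)
        n = self.counts.shape[0]
        for name in ("cell_individual", "cell_type", "cell_depth"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match number of cells")
        if self.counts.shape[1] != len(self.gene_ids):
            raise ValueError("gene_ids length does not match number of genes")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def cell_types(self) -> list:
        return sorted(pd.unique(self.cell_type).tolist())


@dataclass
class PseudobulkDataset:
    """Individual x gene summed UMI counts for one cell type (or all cells).

    ``depth`` (s_i) is the per-individual total count over all genes in the cell
    type, computed *before* any gene filtering.
    """

    counts: np.ndarray                       # (n_individuals, n_genes)
    gene_ids: np.ndarray
    individuals: np.ndarray
    depth: np.ndarray                        # (n_individuals,)
    cell_type: str
    n_cells: np.ndarray                      # cells per individual

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = np.asarray(self.gene_ids)
        self.individuals = np.asarray(self.individuals)
        self.depth = np.asarray(self.depth, dtype=float)
        self.n_cells = np.asarray(self.n_cells)
        if np.any(self.depth <= 0):
            raise ValueError("retained individuals must have positive depth")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    def gene_counts(self, gene_id) -> np.ndarray:
        j = np.flatnonzero(self.gene_ids == gene_id)
        if j.size == 0:
            raise KeyError(f"gene {gene_id!r} not in dataset")
        return self.counts[:, j[0]]


@dataclass
class GenotypeBlock:
    """Dosages plus per-SNP metadata, allele frequencies and the LD matrix."""

    dosage: np.ndarray                       # (n_individuals, n_snps), values in [0, 2]
    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    maf: np.ndarray | None = None
    sd_diag: np.ndarray | None = None        # sqrt(2 p (1-p))
    ld: np.ndarray | None = None             # SNP x SNP correlation (V)
    individuals: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.snp_id = np.asarray(self.snp_id)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.a1 = np.asarray(self.a1)
        self.a2 = np.asarray(self.a2)
        if self.maf is None:
            self.recompute_stats()

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    def recompute_stats(self) -> None:
        """Recompute maf, sd_diag and ld from the dosage matrix."""
        p = self.dosage.mean(axis=0) / 2.0
        self.maf = np.minimum(p, 1.0 - p)
        self.sd_diag = np.sqrt(2.0 * self.maf * (1.0 - self.maf))
        self.ld = ld_matrix(self.dosage)

    def standardized(self) -> np.ndarray:
        """Column-standardized dosages (mean 0, unit sample SD)."""
        g = self.dosage - self.dosage.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        return g / sd

    def subset(self, mask: np.ndarray, recompute: bool = True) -> "GenotypeBlock":
        idx = np.asarray(mask)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        gb = GenotypeBlock(
            dosage=self.dosage[:, idx],
            snp_id=self.snp_id[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            a1=self.a1[idx],
            a2=self.a2[idx],
            maf=None if recompute else self.maf[idx],
            sd_diag=None if recompute else self.sd_diag[idx],
            ld=None if recompute else self.ld[np.ix_(idx, idx)],
            individuals=self.individuals,
        )
        if not recompute and gb.maf is None:
            gb.recompute_stats()
        return gb


def ld_matrix(dosage: np.ndarray) -> np.ndarray:
    """SNP x SNP Pearson correlation with unit diagonal; monomorphic SNPs get 0 off-diagonal."""
    g = np.asarray(dosage, dtype=float)
    g = g - g.mean(axis=0)
    sd = g.std(axis=0)
    ok = sd > 0
    gs = np.where(ok, g / np.where(ok, sd, 1.0), 0.0)
    v = gs.T @ gs / g.shape[0]
    np.fill_diagonal(v, 1.0)
    return v


@dataclass
class CovariateMatrix:
    """Individual x covariate design; the first column is the intercept."""

    values: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.allclose(self.values[:, 0], 1.0):
            raise ValueError("first covariate column must be the intercept (all ones)")
        if np.linalg.matrix_rank(self.values) < self.values.shape[1]:
            raise ValueError("covariate matrix is rank deficient")
        if not self.names:
            self.names = ["intercept"] + [f"cov{j}" for j in range(1, self.values.shape[1])]

    @classmethod
    def intercept_only(cls, n: int) -> "CovariateMatrix":
        return cls(values=np.ones((n, 1)), names=["intercept"])


@dataclass
class GWASSummary:
    """Per-SNP marginal GWAS summary statistics."""

    snp_id: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    z: np.ndarray
    n: float | None = None
    beta_hat: np.ndarray | None = None
    se: np.ndarray | None = None
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id)
        self.a1 = np.asarray(self.a1)
        self.a2 = np.asarray(self.a2)
        if self.z is None and self.beta_hat is not None and self.se is not None:
            self.z = np.asarray(self.beta_hat, dtype=float) / np.asarray(self.se, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.se is not None and np.any(np.asarray(self.se) <= 0):
            raise ValueError("se must be positive")
        if self.beta_hat is not None and self.se is not None:
            if not np.allclose(self.z, np.asarray(self.beta_hat) / np.asarray(self.se),
                               atol=1e-8, rtol=0):
                raise ValueError("z inconsistent with beta_hat / se")

    def pvalues(self) -> np.ndarray:
        from scipy.stats import norm
        return 2.0 * norm.sf(np.abs(self.z))


@dataclass
class GeneAnnotation:
    """Gene coordinates (1-based, inclusive); strand is ignored throughout."""

    gene_id: str
    chrom: str
    tss: int
    tes: int

    def __post_init__(self) -> None:
        if self.tss > self.tes:
            raise ValueError(f"gene {self.gene_id}: tss > tes")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.tss + self.tes)


@dataclass
class GReXModel:
    """Per-gene GReX prediction model: SNP weights plus fit diagnostics.

    ``beta`` acts on dosages on the relative-abundance scale for the count-based
    method, or on normalized expression for the baseline recipes; ``method_tag``
    records which (sctwas | elasticnet_NA | elasticnet_AN).
    """

    gene_id: str
    cell_type: str
    snp_id: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    beta: np.ndarray
    gamma: np.ndarray
    lam: float
    theta: float | None
    prediction_pvalue: float | None
    method_tag: str
    mixing: float = 0.5
    n_iter: int | None = None
    converged: bool | None = None
    mu: np.ndarray | None = None
    weights: np.ndarray | None = None
    residual: np.ndarray | None = None
    predictive_flag: str | None = None

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.snp_id = np.asarray(self.snp_id)
        if self.lam < 0:
            raise ValueError("lambda must be nonnegative")
        if self.theta is not None and self.theta <= 0:
            raise ValueError("theta must be positive")
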