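"""Genotype QC (MAF / Hardy-Weinberg) and cis-window extraction."""

from __future__ import annotations

import logging
import math

import numpy as np

from .data import GenotypeBlock, GeneAnnotation, NotModelableError, SctwasError

logger = logging.getLogger(__name__)


def hwe_exact_pvalue(n_het: int, n_hom1: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg test p-value from hard-call genotype counts.

    Standard exact test on the number of heterozygotes conditional on the allele
    counts (sum of probabilities of configurations no more likely than observed).
    """
    n_hom_rare, n_hom_common = sorted((n_hom1, n_hom2))
    rare = 2 * n_hom_rare + n_het
    n = n_het + n_hom1 + n_hom2
    if n == 0 or rare == 0:
        return 1.0

    # log-probability of each possible heterozygote count with same allele totals
    het_values = np.arange(rare % 2, rare + 1, 2)
    logps = []
    lf = math.lgamma
    for h in het_values:
        a = (rare - h) // 2                      # rare homozygotes
        b = n - h - a                            # common homozygotes
        lp = (h * math.log(2) + lf(n + 1) - lf(h + 1) - lf(a + 1) - lf(b + 1)
              + lf(rare + 1) + lf(2 * n - rare + 1) - lf(2 * n + 1))
        logps.append(lp)
    logps = np.array(logps)
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[het_values == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hard_calls(dosage: np.ndarray) -> np.ndarray:
    """Round dosages to hard calls; values in (0.5, 1.5) round to 1."""
    calls = np.full(dosage.shape, 1, dtype=np.int8)
    calls[dosage <= 0.5] = 0
    calls[dosage >= 1.5] = 2
    return calls


def qc_genotypes(gb: GenotypeBlock, maf_min: float = 0.01,
                 hwe_p_min: float = 1e-6) -> GenotypeBlock:
    """Drop SNPs with MAF <= maf_min or exact HWE p-value < hwe_p_min.

    HWE is tested on hard calls (rounded dosages). maf, sd_diag and the LD matrix
    are recomputed on the surviving SNPs.
    """
    calls = _hard_calls(gb.dosage)
    keep = np.ones(gb.n_snps, dtype=bool)
    p = gb.dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep &= maf > maf_min
    for j in np.flatnonzero(keep):
        col = calls[:, j]
        n_het = int((col == 1).sum())
        n0 = int((col == 0).sum())
        n2 = int((col == 2).sum())
        if hwe_exact_pvalue(n_het, n0, n2) < hwe_p_min:
            keep[j] = False
    if not keep.any():
        raise SctwasError("no SNPs survive MAF/HWE QC")
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("QC removed %d of %d SNPs", n_dropped, gb.n_snps)
    return gb.subset(keep)


def cis_window(gene: GeneAnnotation, gb: GenotypeBlock,
               flank: int = 500_000) -> GenotypeBlock:
    """SNPs within the closed interval [tss - flank, tes + flank] on the gene's chromosome."""
    on_chrom = np.asarray(gb.chrom).astype(str) == str(gene.chrom)
    if not on_chrom.any():
        raise NotModelableError(
            f"gene {gene.gene_id}: chromosome {gene.chrom!r} absent from genotype block"
        )
    keep = on_chrom & (gb.pos >= gene.tss - flank) & (gb.pos <= gene.tes + flank)
    if not keep.any():
        raise NotModelableError(f"gene {gene.gene_id}: empty cis-window")
    return gb.subset(keep)
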