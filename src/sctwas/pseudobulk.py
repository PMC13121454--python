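"""Pseudobulk construction and gene-level QC.

Pseudobulk counts are the per-individual sums of UMI counts over the cells of one
cell type (or all cells, for the bulk-like mode); the per-individual depth s_i is
the total count over all genes and is computed before any gene filtering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .data import CellCountMatrix, PseudobulkDataset, SctwasError

logger = logging.getLogger(__name__)

ALL_CELL_TYPES = "ALL"


def aggregate_pseudobulk(cells: CellCountMatrix, cell_type: str) -> PseudobulkDataset:
    """Sum UMI counts per individual over cells of ``cell_type`` (or ``"ALL"``).

    Individuals with zero matching cells are excluded (their count is logged).
    Depth is the per-individual sum of per-cell depths, i.e. the total count over
    all genes in the cell type.
    """
    if cell_type == ALL_CELL_TYPES:
        mask = np.ones(cells.n_cells, dtype=bool)
    else:
        mask = cells.cell_type == cell_type
        if not mask.any():
            raise SctwasError(
                f"unknown or empty cell type {cell_type!r}; available: {cells.cell_types()}"
            )

    individuals = cells.cell_individual[mask]
    uniq = pd.unique(cells.cell_individual)
    codes = pd.Categorical(individuals, categories=pd.unique(individuals)).codes
    kept = pd.unique(individuals)
    n_groups = len(kept)

    counts = np.zeros((n_groups, cells.n_genes), dtype=np.int64)
    np.add.at(counts, codes, np.asarray(cells.counts[mask], dtype=np.int64))
    depth = np.zeros(n_groups)
    np.add.at(depth, codes, np.asarray(cells.cell_depth[mask], dtype=float))
    n_cells = np.bincount(codes, minlength=n_groups)

    n_excluded = len(uniq) - n_groups
    if n_excluded:
        logger.warning(
            "%d individual(s) had no cells of type %r and were excluded",
            n_excluded, cell_type,
        )
    return PseudobulkDataset(
        counts=counts,
        gene_ids=cells.gene_ids,
        individuals=kept,
        depth=depth,
        cell_type=cell_type,
        n_cells=n_cells,
    )


def filter_genes(pb: PseudobulkDataset, min_total: int = 1000) -> PseudobulkDataset:
    """Keep genes whose total count across individuals is >= ``min_total``.

    Depth is left untouched: s_i is defined over all genes before filtering.
    """
    if min_total < 0:
        raise ValueError("min_total must be nonnegative")
    totals = pb.counts.sum(axis=0)
    keep = totals >= min_total
    if not keep.any():
        logger.warning("all %d genes removed by min_total=%d filter", pb.counts.shape[1], min_total)
    return PseudobulkDataset(
        counts=pb.counts[:, keep],
        gene_ids=pb.gene_ids[keep],
        individuals=pb.individuals,
        depth=pb.depth,
        cell_type=pb.cell_type,
        n_cells=pb.n_cells,
    )
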