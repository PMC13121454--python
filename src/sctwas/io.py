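"""Readers and writers for the standard formats the pipeline touches.

Supported formats: PLINK1 bed/bim/fam (minimal 2-bit decoder/encoder), VCF
(through cyvcf2, GT or DS), MatrixMarket cell x gene count directories
(matrix.mtx + features.tsv + barcodes.tsv + cell_metadata.tsv), GWAS summary TSV,
gene-annotation TSV, and the per-gene weight store (TSV + JSON sidecar).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .data import (
    CellCountMatrix,
    GenotypeBlock,
    GeneAnnotation,
    GReXModel,
    GWASSummary,
    ParseError,
)

logger = logging.getLogger(__name__)

_PLINK_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes, SNP-major: 00=hom a1, 01=missing, 10=het, 11=hom a2.
# Dosage convention: count of a1 alleles.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix: str | Path) -> GenotypeBlock:
    """Read a PLINK1 bed/bim/fam fileset into a GenotypeBlock.

    Missing genotypes are imputed to the per-SNP mean (count logged).
    """
    prefix = str(prefix)
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
                      dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str})
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    n, m = len(fam), len(bim)
    raw = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if raw[:3].tobytes() != _PLINK_MAGIC:
        raise ParseError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK1 bed)")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise ParseError(f"{prefix}.bed: size mismatch ({body.size} body bytes, "
                         f"expected {bytes_per_snp * m})")
    blocks = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.stack([(blocks >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1)
    codes = codes.reshape(m, -1)[:, :n]
    dosage = _CODE_TO_DOSAGE[codes].T.copy()     # individuals x SNPs
    dosage = _impute_missing(dosage)
    return GenotypeBlock(
        dosage=dosage,
        snp_id=bim["snp_id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        a1=bim["a1"].to_numpy(),
        a2=bim["a2"].to_numpy(),
        individuals=fam["iid"].to_numpy(),
    )


def write_plink(gb: GenotypeBlock, prefix: str | Path) -> None:
    """Write hard-called dosages as a PLINK1 bed/bim/fam fileset."""
    prefix = str(prefix)
    n, m = gb.dosage.shape
    with open(prefix + ".bim", "w") as fh:
        for j in range(m):
            fh.write(f"{gb.chrom[j]}\t{gb.snp_id[j]}\t0\t{gb.pos[j]}\t{gb.a1[j]}\t{gb.a2[j]}\n")
    inds = gb.individuals if gb.individuals is not None else [f"I{i}" for i in range(n)]
    with open(prefix + ".fam", "w") as fh:
        for iid in inds:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")
    calls = np.rint(gb.dosage).astype(int)
    code = np.where(calls == 2, 0, np.where(calls == 1, 2, 3)).astype(np.uint8)
    pad = (-n) % 4
    if pad:
        code = np.hstack([code.T, np.zeros((m, pad), dtype=np.uint8)])
    else:
        code = code.T.copy()
    packed = (code[:, 0::4] | (code[:, 1::4] << 2) | (code[:, 2::4] << 4)
              | (code[:, 3::4] << 6)).astype(np.uint8)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_PLINK_MAGIC)
        fh.write(packed.tobytes())


def read_vcf(path: str | Path) -> GenotypeBlock:
    """Read genotypes from a VCF (DS dosage field if present, else GT hard calls)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = np.array(vcf.samples)
    snp_id, chrom, pos, a1, a2, rows = [], [], [], [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("skipping multi-allelic variant %s", var.ID)
            continue
        try:
            ds = var.format("DS")
            row = np.asarray(ds, dtype=float).ravel()
        except (KeyError, TypeError):
            gts = np.asarray(var.genotype.array())[:, :2]
            row = np.where((gts < 0).any(axis=1), np.nan, gts.clip(0).sum(axis=1)).astype(float)
        snp_id.append(var.ID or f"{var.CHROM}:{var.POS}")
        chrom.append(var.CHROM)
        pos.append(var.POS)
        a1.append(var.ALT[0])    # dosage counts the alternate allele
        a2.append(var.REF)
        rows.append(row)
    dosage = _impute_missing(np.array(rows).T)
    return GenotypeBlock(
        dosage=dosage, snp_id=np.array(snp_id), chrom=np.array(chrom),
        pos=np.array(pos), a1=np.array(a1), a2=np.array(a2), individuals=individuals,
    )


def _impute_missing(dosage: np.ndarray) -> np.ndarray:
    missing = np.isnan(dosage)
    if missing.any():
        logger.warning("imputing %d missing dosages (%.3f%%) to per-SNP means",
                       int(missing.sum()), 100 * missing.mean())
        means = np.nanmean(dosage, axis=0)
        means = np.where(np.isnan(means), 0.0, means)
        dosage = np.where(missing, means[None, :], dosage)
    return dosage


def read_genotypes(path: str | Path, format: str | None = None) -> GenotypeBlock:
    """Dispatch to the PLINK or VCF reader; format inferred from the path if omitted."""
    path = str(path)
    if format is None:
        format = "vcf" if path.endswith((".vcf", ".vcf.gz")) else "plink"
    if format == "plink":
        return read_plink(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def read_gwas(path: str | Path) -> GWASSummary:
    """Read a GWAS summary TSV (SNP, A1, A2, [Z | BETA, SE], and optional CHR, POS, N)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.upper() for c in df.columns]
    required = {"SNP", "A1", "A2"}
    if not required <= set(df.columns):
        raise ParseError(f"{path}: header line 1 must contain {sorted(required)}; "
                         f"found {list(df.columns)}")
    if "Z" in df.columns:
        z = df["Z"].to_numpy(dtype=float)
        beta_hat = df["BETA"].to_numpy(dtype=float) if "BETA" in df.columns else None
        se = df["SE"].to_numpy(dtype=float) if "SE" in df.columns else None
    elif {"BETA", "SE"} <= set(df.columns):
        beta_hat = df["BETA"].to_numpy(dtype=float)
        se = df["SE"].to_numpy(dtype=float)
        z = beta_hat / se
    else:
        raise ParseError(f"{path}: need either a Z column or BETA and SE columns")
    return GWASSummary(
        snp_id=df["SNP"].astype(str).to_numpy(),
        a1=df["A1"].astype(str).to_numpy(),
        a2=df["A2"].astype(str).to_numpy(),
        z=z, beta_hat=beta_hat, se=se,
        n=float(df["N"].iloc[0]) if "N" in df.columns else None,
        chrom=df["CHR"].astype(str).to_numpy() if "CHR" in df.columns else None,
        pos=df["POS"].to_numpy(dtype=np.int64) if "POS" in df.columns else None,
    )


def read_cells(path: str | Path) -> CellCountMatrix:
    """Read a 10x-style MTX directory into a CellCountMatrix.

    Expects matrix.mtx (features x barcodes), features.tsv, barcodes.tsv and
    cell_metadata.tsv with columns barcode, individual, cell_type.
    """
    path = Path(path)
    mat = scipy.io.mmread(path / "matrix.mtx")
    features = pd.read_csv(path / "features.tsv", sep="\t", header=None)
    barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    meta = pd.read_csv(path / "cell_metadata.tsv", sep="\t")
    for col in ("barcode", "individual", "cell_type"):
        if col not in meta.columns:
            raise ParseError(f"{path}/cell_metadata.tsv: missing column {col!r}")
    counts = np.asarray(scipy.sparse.csr_matrix(mat).todense())
    if counts.shape == (len(features), len(barcodes)):
        counts = counts.T                      # features x barcodes -> cells x genes
    elif counts.shape != (len(barcodes), len(features)):
        raise ParseError(f"{path}/matrix.mtx: shape {counts.shape} matches neither orientation")
    meta = meta.set_index("barcode").loc[barcodes]
    return CellCountMatrix(
        counts=counts.astype(np.int64),
        gene_ids=features[0].astype(str).to_numpy(),
        cell_individual=meta["individual"].astype(str).to_numpy(),
        cell_type=meta["cell_type"].astype(str).to_numpy(),
        cell_depth=counts.sum(axis=1),
    )


def read_gene_annotations(path: str | Path) -> list[GeneAnnotation]:
    """Read a gene annotation TSV with columns gene_id, chrom, tss, tes."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
    return [GeneAnnotation(r.gene_id, r.chrom, int(r.tss), int(r.tes))
            for r in df.itertuples()]


def write_weights(models: list[GReXModel], path: str | Path) -> None:
    """Write a weight store: per-gene <gene>.<cell_type>.weights.tsv + .json sidecar.

    Floats are written with 17 significant digits so that a round trip reproduces
    beta, gamma, lambda, theta and the prediction p-value bit-comparably.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    index = []
    for m in models:
        stem = f"{m.gene_id}.{m.cell_type}"
        with open(path / f"{stem}.weights.tsv", "w") as fh:
            fh.write("snp_id\ta1\ta2\tbeta\n")
            for j in range(len(m.snp_id)):
                fh.write(f"{m.snp_id[j]}\t{m.a1[j]}\t{m.a2[j]}\t{m.beta[j]:.17g}\n")
        sidecar = {
            "gene_id": m.gene_id,
            "cell_type": m.cell_type,
            "method_tag": m.method_tag,
            "mixing": m.mixing,
            "lambda": float(m.lam),
            "theta": None if m.theta is None else float(m.theta),
            "prediction_pvalue": None if m.prediction_pvalue is None
            else float(m.prediction_pvalue),
            "gamma": [float(g) for g in m.gamma],
            "n_iter": m.n_iter,
            "converged": m.converged,
            "predictive_flag": m.predictive_flag,
        }
        with open(path / f"{stem}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
        index.append(stem)
    with open(path / "INDEX.json", "w") as fh:
        json.dump(index, fh, indent=1)


def read_weights(path: str | Path) -> list[GReXModel]:
    """Read a weight store written by :func:`write_weights`."""
    path = Path(path)
    with open(path / "INDEX.json") as fh:
        index = json.load(fh)
    models = []
    for stem in index:
        tab = pd.read_csv(path / f"{stem}.weights.tsv", sep="\t",
                          dtype={"snp_id": str, "a1": str, "a2": str})
        with open(path / f"{stem}.json") as fh:
            side = json.load(fh)
        models.append(GReXModel(
            gene_id=side["gene_id"],
            cell_type=side["cell_type"],
            snp_id=tab["snp_id"].to_numpy(),
            a1=tab["a1"].to_numpy(),
            a2=tab["a2"].to_numpy(),
            beta=tab["beta"].to_numpy(dtype=float),
            gamma=np.array(side["gamma"], dtype=float),
            lam=side["lambda"],
            theta=side["theta"],
            prediction_pvalue=side["prediction_pvalue"],
            method_tag=side["method_tag"],
            mixing=side["mixing"],
            n_iter=side["n_iter"],
            converged=side["converged"],
            predictive_flag=side["predictive_flag"],
        ))
    return models


def write_cells(cells: CellCountMatrix, path: str | Path) -> None:
    """Write a CellCountMatrix as a 10x-style MTX directory (inverse of read_cells)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(path / "matrix.mtx"),
                     scipy.sparse.coo_matrix(cells.counts.T))
    pd.DataFrame({0: cells.gene_ids}).to_csv(path / "features.tsv", sep="\t",
                                             header=False, index=False)
    barcodes = [f"cell{i}" for i in range(cells.n_cells)]
    pd.DataFrame({0: barcodes}).to_csv(path / "barcodes.tsv", sep="\t",
                                       header=False, index=False)
    pd.DataFrame({
        "barcode": barcodes,
        "individual": cells.cell_individual,
        "cell_type": cells.cell_type,
    }).to_csv(path / "cell_metadata.tsv", sep="\t", index=False)
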