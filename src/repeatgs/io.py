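"""Readers and writers for genotype matrices and phenotype tables.

Two genotype dialects are supported: a delimited text matrix (plants x
SNPs, header row of SNP ids, first column ``plant_id``, optional second
column ``cross``, missing = ``NA``) and plain-text VCF (GT field only,
biallelic records).
"""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix


def read_genotypes(path: str, format: str = "matrix") -> GenotypeMatrix:
    """Load a genotype matrix from ``matrix`` or ``vcf`` format."""
    if format == "matrix":
        return read_genotype_matrix(path)
    if format == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def read_genotype_matrix(path: str, sep: str = ",") -> GenotypeMatrix:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    if df.columns[0] != "plant_id":
        raise ValueError(f"{path}: first column must be 'plant_id'")
    cross = None
    first_snp = 1
    if len(df.columns) > 1 and df.columns[1] == "cross":
        cross = df["cross"].to_numpy(dtype=object)
        first_snp = 2
    snp_ids = df.columns[first_snp:].to_numpy(dtype=object)
    raw = df.iloc[:, first_snp:].to_numpy(dtype=object)
    codes = np.empty(raw.shape, dtype=np.int16)
    for j in range(raw.shape[1]):
        col = raw[:, j]
        for i, cell in enumerate(col):
            if cell == "NA" or cell == "":
                codes[i, j] = MISSING
            else:
                try:
                    codes[i, j] = int(cell)
                except ValueError:
                    raise ValueError(
                        f"{path}: unparseable cell {cell!r} at row "
                        f"{i + 2}, column {snp_ids[j]!r}"
                    ) from None
    return GenotypeMatrix(
        codes=codes,
        plant_ids=df["plant_id"].to_numpy(dtype=object),
        snp_ids=snp_ids,
        cross=cross,
    )


def write_genotype_matrix(g: GenotypeMatrix, path: str, sep: str = ",") -> None:
    data = {"plant_id": g.plant_ids}
    if g.cross is not None:
        data["cross"] = g.cross
    for j, sid in enumerate(g.snp_ids):
        col = g.codes[:, j].astype(object)
        col[g.codes[:, j] == MISSING] = "NA"
        data[sid] = col
    pd.DataFrame(data).to_csv(path, sep=sep, index=False)


def read_vcf(path: str) -> GenotypeMatrix:
    """Import diploid GT calls from a (plain or bgzipped) VCF."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    plant_ids = np.asarray(vcf.samples, dtype=object)
    snp_ids, chrom, pos, cols = [], [], [], []
    for k, variant in enumerate(vcf):
        if len(variant.ALT) != 1:
            raise ValueError(
                f"{path}: multi-allelic record at {variant.CHROM}:"
                f"{variant.POS} not supported"
            )
        snp_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        chrom.append(variant.CHROM)
        pos.append(variant.POS)
        col = np.empty(len(plant_ids), dtype=np.int16)
        for i, gt in enumerate(variant.genotypes):
            a, b = gt[0], gt[1]
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        cols.append(col)
    vcf.close()
    if not cols:
        raise ValueError(f"{path}: no variant records")
    return GenotypeMatrix(
        codes=np.column_stack(cols),
        plant_ids=plant_ids,
        snp_ids=np.asarray(snp_ids, dtype=object),
        cross=None,
        chrom=np.asarray(chrom, dtype=object),
        pos_cm=np.asarray(pos, dtype=float),
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(g: GenotypeMatrix, path: str) -> None:
    """Write genotypes as an uncompressed VCF (GT field only).

    Positions are the cM positions scaled to integer base pairs
    (1 cM -> 10 kb) when a map is attached, else the SNP index.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(p) for p in g.plant_ids)
            + "\n"
        )
        for j, sid in enumerate(g.snp_ids):
            if g.chrom is not None:
                chrom = str(g.chrom[j])
                pos = int(round(g.pos_cm[j] * 10000)) + 1
            else:
                chrom, pos = "1", j + 1
            gts = "\t".join(_GT[int(c)] for c in g.codes[:, j])
            fh.write(f"{chrom}\t{pos}\t{sid}\tA\tB\t.\tPASS\t.\tGT\t{gts}\n")


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"plant", "year", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {sorted(missing)}")
    return df


def write_phenotypes(records: pd.DataFrame, path: str) -> None:
    records.to_csv(path, index=False)
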