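"""Genotype quality control: call-rate, monomorphism and MAF editing.

Editing rules follow the order sample call-rate -> SNP call-rate /
monomorphic-in-all-crosses -> within-cross MAF. Thresholds are strict:
samples and SNPs are discarded at call-rate <= threshold, SNPs at
MAF < threshold.

Monomorphism is assessed on genotype calls (a single observed genotype
class), so a locus where every plant is heterozygous counts as
non-segregating even though its allele frequency is 0.5; the report also
carries the allele-frequency-based flag (MAF = 0) separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix


def filter_samples_by_callrate(
    g: GenotypeMatrix, threshold: float = 0.90
) -> Tuple[GenotypeMatrix, list]:
    """Discard samples with call-rate <= ``threshold`` (strict)."""
    cr = g.sample_call_rate()
    keep = cr > threshold
    removed = list(g.plant_ids[~keep])
    return g.subset_plants(np.flatnonzero(keep)), removed


def _observed_classes(codes: np.ndarray) -> np.ndarray:
    """Number of distinct observed genotype classes per SNP column."""
    out = np.zeros(codes.shape[1], dtype=int)
    for code in (0, 1, 2):
        out += (codes == code).any(axis=0)
    return out


def monomorphic_by_genotype(g: GenotypeMatrix) -> np.ndarray:
    """True where at most one genotype class is observed (per SNP)."""
    return _observed_classes(g.codes) <= 1


def _monomorphic_in_all_crosses(g: GenotypeMatrix) -> np.ndarray:
    if g.cross is None:
        return monomorphic_by_genotype(g)
    mono = np.ones(g.n_snps, dtype=bool)
    for label in g.crosses():
        sub = g.subset_plants(np.flatnonzero(g.cross == label))
        mono &= monomorphic_by_genotype(sub)
    return mono


def filter_snps(
    g: GenotypeMatrix,
    callrate_threshold: float = 0.90,
    drop_monomorphic_all: bool = True,
) -> Tuple[GenotypeMatrix, list]:
    """Remove SNPs with call-rate <= threshold over all samples, or
    monomorphic in every cross (when labels are present)."""
    low_cr = g.snp_call_rate() <= callrate_threshold
    drop = low_cr.copy()
    if drop_monomorphic_all:
        drop |= _monomorphic_in_all_crosses(g)
    removed = list(g.snp_ids[drop])
    return g.subset_snps(np.flatnonzero(~drop)), removed


def maf(g: GenotypeMatrix, scope: str = "pooled"):
    """Per-locus minor allele frequency over non-missing calls.

    ``scope='pooled'`` returns one vector; ``scope='per-cross'`` returns a
    mapping cross label -> vector. Loci with all calls missing are NaN.
    """
    if scope == "pooled":
        return _maf_vector(g.codes)
    if scope == "per-cross":
        if g.cross is None:
            raise ValueError("per-cross MAF needs cross labels")
        return {
            label: _maf_vector(
                g.codes[np.flatnonzero(g.cross == label)]
            )
            for label in g.crosses()
        }
    raise ValueError(f"unknown scope {scope!r}")


def _maf_vector(codes: np.ndarray) -> np.ndarray:
    observed = codes != MISSING
    n_obs = observed.sum(axis=0)
    alt = np.where(observed, codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_obs)
    p = np.where(n_obs == 0, np.nan, p)
    return np.minimum(p, 1.0 - p)


def filter_maf(g: GenotypeMatrix, threshold: float = 0.01) -> GenotypeMatrix:
    """Drop loci with MAF < threshold (strict) or undefined MAF.

    Intended to run within a single cross, just before GBLUP.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold outside [0, 0.5]")
    f = _maf_vector(g.codes)
    keep = ~np.isnan(f) & (f >= threshold)
    return g.subset_snps(np.flatnonzero(keep))


@dataclass
class QCReport:
    """Table-style QC summary with per-filter accounting.

    ``per_cross`` rows mirror the published layout (cross, samples before
    and after the call-rate edit, residual missing rate, monomorphic
    fraction, mean MAF among polymorphic loci). Residual missing rate is
    reported both over all samples and over call-rate-passing samples,
    since the two conventions differ.
    """

    per_cross: pd.DataFrame
    overall: Dict[str, float]
    removed: Dict[str, int]

    def to_dataframe(self) -> pd.DataFrame:
        overall_row = {"cross": "Entire dataset", **self.overall}
        return pd.concat(
            [self.per_cross, pd.DataFrame([overall_row])], ignore_index=True
        )

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def check_conservation(self) -> None:
        """before - removed = after, for every recorded filter."""
        for key in ("samples", "snps"):
            before = self.removed[f"{key}_before"]
            removed = self.removed[f"{key}_removed"]
            after = self.removed[f"{key}_after"]
            if before - removed != after:
                raise AssertionError(
                    f"{key} accounting broken: {before} - {removed} != {after}"
                )


def _cross_stats(g: GenotypeMatrix, label: str, idx: np.ndarray) -> dict:
    sub = g.subset_plants(idx)
    passing, _ = filter_samples_by_callrate(sub)
    mono = monomorphic_by_genotype(sub)
    f = _maf_vector(sub.codes)
    maf0 = np.nan_to_num(f, nan=0.0) == 0.0
    poly = ~mono & ~np.isnan(f)
    mr_pass = (
        passing.missing_rate() if passing.n_plants else float("nan")
    )
    return {
        "cross": label,
        "samples": sub.n_plants,
        "samples_cr_ok": passing.n_plants,
        "missing_rate": round(sub.missing_rate(), 6),
        "missing_rate_cr_ok": round(mr_pass, 6),
        "monomorphic_frac": round(float(mono.mean()), 6),
        "maf0_frac": round(float(maf0.mean()), 6),
        "mean_maf": round(float(f[poly].mean()), 6) if poly.any() else float("nan"),
    }


def qc_summary(g: GenotypeMatrix) -> QCReport:
    """Per-cross and overall genotype summary plus filter accounting."""
    if g.cross is None:
        raise ValueError("qc_summary needs cross labels")
    rows = [
        _cross_stats(g, label, np.flatnonzero(g.cross == label))
        for label in g.crosses()
    ]
    g_samples, removed_samples = filter_samples_by_callrate(g)
    g_snps, removed_snps = filter_snps(g_samples)
    overall = _cross_stats(g, "__all__", np.arange(g.n_plants))
    overall.pop("cross")
    removed = {
        "samples_before": g.n_plants,
        "samples_removed": len(removed_samples),
        "samples_after": g_samples.n_plants,
        "snps_before": g_samples.n_snps,
        "snps_removed": len(removed_snps),
        "snps_after": g_snps.n_snps,
    }
    report = QCReport(
        per_cross=pd.DataFrame(rows), overall=overall, removed=removed
    )
    report.check_conservation()
    return report
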