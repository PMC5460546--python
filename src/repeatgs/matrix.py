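"""Core genotype containers shared across the package.

Genotypes are stored as integer codes counting copies of the alternate
allele (0, 1, 2), with ``MISSING`` (-1) as the missing sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Missing-genotype sentinel used throughout the package.
MISSING: int = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


@dataclass
class GenotypeMatrix:
    """Plants x SNPs matrix of integer genotype codes.

    Parameters
    ----------
    codes
        ``(n_plants, n_snps)`` integer array with entries in ``{0, 1, 2}``
        or :data:`MISSING`.
    plant_ids, snp_ids
        Unique string identifiers for rows and columns.
    cross
        Optional per-plant cross (population) label.
    chrom, pos_cm
        Optional per-SNP chromosome id and genetic position (centiMorgans).
        Positions must be non-decreasing within each chromosome.
    """

    codes: np.ndarray
    plant_ids: np.ndarray
    snp_ids: np.ndarray
    cross: Optional[np.ndarray] = None
    chrom: Optional[np.ndarray] = None
    pos_cm: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int16)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D plants x SNPs array")
        self.plant_ids = np.asarray(self.plant_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        n, m = self.codes.shape
        if len(self.plant_ids) != n:
            raise ValueError(f"{len(self.plant_ids)} plant ids for {n} rows")
        if len(self.snp_ids) != m:
            raise ValueError(f"{len(self.snp_ids)} SNP ids for {m} columns")
        if len(set(self.plant_ids)) != n:
            raise ValueError("plant ids must be unique")
        if len(set(self.snp_ids)) != m:
            raise ValueError("SNP ids must be unique")
        bad = ~np.isin(self.codes, (-1, 0, 1, 2))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid genotype code {self.codes[i, j]} at plant "
                f"{self.plant_ids[i]!r}, SNP {self.snp_ids[j]!r}"
            )
        if self.cross is not None:
            self.cross = np.asarray(self.cross, dtype=object)
            if len(self.cross) != n:
                raise ValueError("cross labels must match plant count")
        if (self.chrom is None) != (self.pos_cm is None):
            raise ValueError("chrom and pos_cm must be given together")
        if self.chrom is not None:
            self.chrom = np.asarray(self.chrom)
            self.pos_cm = np.asarray(self.pos_cm, dtype=float)
            if len(self.chrom) != m or len(self.pos_cm) != m:
                raise ValueError("map arrays must match SNP count")
            if (self.pos_cm < 0).any():
                raise ValueError("genetic positions must be non-negative")
            for c in np.unique(self.chrom):
                p = self.pos_cm[self.chrom == c]
                if (np.diff(p) < 0).any():
                    raise ValueError(
                        f"positions not sorted within chromosome {c}"
                    )

    # -- basic geometry -------------------------------------------------
    @property
    def n_plants(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def is_complete(self) -> bool:
        return bool((self.codes != MISSING).all())

    def missing_rate(self) -> float:
        return float((self.codes == MISSING).mean())

    def sample_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per plant."""
        return (self.codes != MISSING).mean(axis=1)

    def snp_call_rate(self) -> np.ndarray:
        """Fraction of non-missing calls per SNP."""
        return (self.codes != MISSING).mean(axis=0)

    # -- subsetting -----------------------------------------------------
    def subset_plants(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            codes=self.codes[index].copy(),
            plant_ids=self.plant_ids[index],
            snp_ids=self.snp_ids,
            cross=None if self.cross is None else self.cross[index],
            chrom=self.chrom,
            pos_cm=self.pos_cm,
        )

    def subset_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index)
        return GenotypeMatrix(
            codes=self.codes[:, index].copy(),
            plant_ids=self.plant_ids,
            snp_ids=self.snp_ids[index],
            cross=self.cross,
            chrom=None if self.chrom is None else self.chrom[index],
            pos_cm=None if self.pos_cm is None else self.pos_cm[index],
        )

    def copy(self) -> "GenotypeMatrix":
        return self.subset_plants(np.arange(self.n_plants))

    def crosses(self) -> list:
        """Distinct cross labels in order of first appearance."""
        if self.cross is None:
            raise ValueError("genotype matrix has no cross labels")
        seen: dict = {}
        for c in self.cross:
            seen.setdefault(c, None)
        return list(seen)


@dataclass
class MissingMask:
    """Positions and true values of entries hidden from a complete matrix."""

    rows: np.ndarray
    cols: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.intp)
        self.cols = np.asarray(self.cols, dtype=np.intp)
        self.values = np.asarray(self.values, dtype=np.int16)
        if not (len(self.rows) == len(self.cols) == len(self.values)):
            raise ValueError("mask arrays must have equal length")

    def __len__(self) -> int:
        return len(self.rows)
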