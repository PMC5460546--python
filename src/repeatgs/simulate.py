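"""Simulation of F1 biparental progenies and repeated-record phenotypes.

The generator draws two heterozygous parents, recombines their phased
haplotypes into progeny gametes (Haldane model, no interference) and
produces per-plant, per-year phenotype records under an additive +
permanent-environment + year + residual model, so that downstream
variance-component machinery can be validated against known truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .matrix import MISSING, GenotypeMatrix, MissingMask

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid simulation parameters."""


@dataclass(frozen=True)
class LinkageMap:
    """Genetic map: chromosome id and cM position for each SNP."""

    chrom: np.ndarray
    pos_cm: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", np.asarray(self.chrom))
        object.__setattr__(
            self, "pos_cm", np.asarray(self.pos_cm, dtype=float)
        )
        if len(self.chrom) != len(self.pos_cm):
            raise ConfigError("map arrays must have equal length")
        if len(self.chrom) == 0:
            raise ConfigError("empty linkage map")
        if (self.pos_cm < 0).any():
            raise ConfigError("positions must be non-negative")
        for c in np.unique(self.chrom):
            p = self.pos_cm[self.chrom == c]
            if (np.diff(p) < 0).any():
                raise ConfigError(f"positions not sorted on chromosome {c}")

    @property
    def n_snps(self) -> int:
        return len(self.chrom)


@dataclass(frozen=True)
class ParentPair:
    """Two parents, each a pair of phased binary haplotypes."""

    haplotypes: np.ndarray  # shape (2 parents, 2 haplotypes, n_snps)

    def __post_init__(self) -> None:
        h = np.asarray(self.haplotypes, dtype=np.int8)
        object.__setattr__(self, "haplotypes", h)
        if h.ndim != 3 or h.shape[:2] != (2, 2):
            raise ConfigError("haplotypes must have shape (2, 2, n_snps)")
        if not np.isin(h, (0, 1)).all():
            raise ConfigError("haplotype alleles must be 0/1")

    @property
    def n_snps(self) -> int:
        return self.haplotypes.shape[2]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated cross.

    ``sigma2_a`` scales additive values drawn from N(0, G * sigma2_a)
    where G is the standardized genomic relationship matrix of the
    simulated progeny (unit average self-relationship), so the realized
    additive variance matches ``sigma2_a`` and the design heritability is
    ``sigma2_a / (sigma2_a + sigma2_pe + sigma2_e)``.
    """

    n_progeny: int = 150
    n_snp: int = 800
    n_chromosomes: int = 8
    chromosome_length_cm: float = 100.0
    parental_heterozygosity: float = 0.45
    missing_rate: float = 0.0
    n_years: int = 3
    year_effects: Tuple[float, ...] = (0.0, 0.0, 0.0)
    mu: float = 0.0
    sigma2_a: float = 0.5
    sigma2_pe: float = 0.2
    sigma2_e: float = 0.3
    seed: int = 0
    dropout: float = 0.0
    trait: str = "trait"
    cross_label: str = "SIM"

    def __post_init__(self) -> None:
        if self.n_progeny < 1 or self.n_snp < 1 or self.n_chromosomes < 1:
            raise ConfigError("counts must be positive")
        if self.n_snp < self.n_chromosomes:
            raise ConfigError("need at least one SNP per chromosome")
        if self.chromosome_length_cm <= 0:
            raise ConfigError("chromosome length must be positive")
        for name in ("parental_heterozygosity", "missing_rate", "dropout"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        for name in ("sigma2_a", "sigma2_pe", "sigma2_e"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.n_years < 1:
            raise ConfigError("n_years must be positive")
        if len(self.year_effects) != self.n_years:
            raise ConfigError("year_effects length must equal n_years")


def _even_map(config: SimConfig) -> LinkageMap:
    base, extra = divmod(config.n_snp, config.n_chromosomes)
    chrom, pos = [], []
    for c in range(config.n_chromosomes):
        s = base + (1 if c < extra else 0)
        spacing = config.chromosome_length_cm / s
        chrom.extend([c + 1] * s)
        pos.extend(np.arange(s) * spacing)
    return LinkageMap(np.asarray(chrom), np.asarray(pos))


def simulate_parents(config: SimConfig) -> Tuple[ParentPair, LinkageMap]:
    """Draw two phased parents and an evenly spaced linkage map.

    Each SNP is heterozygous in a given parent with probability
    ``parental_heterozygosity``; homozygous SNPs carry a random allele.
    Deterministic for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    lmap = _even_map(config)
    m = config.n_snp
    haps = np.zeros((2, 2, m), dtype=np.int8)
    for parent in range(2):
        het = rng.random(m) < config.parental_heterozygosity
        flip = rng.random(m) < 0.5  # which haplotype carries the 1 allele
        hom_allele = (rng.random(m) < 0.5).astype(np.int8)
        haps[parent, 0] = np.where(het, flip, hom_allele)
        haps[parent, 1] = np.where(het, ~flip, hom_allele)
    return ParentPair(haps), lmap


def _gametes(
    hap_pair: np.ndarray,
    lmap: LinkageMap,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Recombinant gametes from one parent's phased haplotype pair.

    Crossovers follow a Poisson process on the cM scale; between adjacent
    SNPs at distance d the switch probability is the Haldane recombination
    fraction (1 - exp(-2 d / 100)) / 2.
    """
    m = lmap.n_snps
    out = np.empty((n, m), dtype=np.int8)
    for c in np.unique(lmap.chrom):
        idx = np.flatnonzero(lmap.chrom == c)
        d = np.diff(lmap.pos_cm[idx])
        r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
        start = rng.integers(0, 2, size=(n, 1))
        switches = rng.random((n, len(d))) < r
        hap_idx = (start + np.cumsum(
            np.concatenate([np.zeros((n, 1), dtype=int), switches], axis=1),
            axis=1,
        )) % 2
        out[:, idx] = hap_pair[hap_idx, idx[np.newaxis, :]]
    return out


def simulate_progeny(
    parents: ParentPair,
    lmap: LinkageMap,
    n_progeny: int,
    seed: int = 0,
    cross_label: str = "SIM",
    id_prefix: str = "P",
) -> GenotypeMatrix:
    """Cross the two parents: each progeny is the sum of two recombinant
    gametes, one per parent, giving genotype codes in {0, 1, 2}."""
    if lmap.n_snps != parents.n_snps:
        raise ConfigError("linkage map does not cover the parental SNPs")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    g1 = _gametes(parents.haplotypes[0], lmap, n_progeny, rng)
    g2 = _gametes(parents.haplotypes[1], lmap, n_progeny, rng)
    codes = (g1 + g2).astype(np.int16)
    width = max(4, len(str(n_progeny)))
    ids = np.array(
        [f"{cross_label}_{id_prefix}{i + 1:0{width}d}" for i in range(n_progeny)],
        dtype=object,
    )
    snp_ids = np.array(
        [f"snp{j + 1:05d}" for j in range(lmap.n_snps)], dtype=object
    )
    return GenotypeMatrix(
        codes=codes,
        plant_ids=ids,
        snp_ids=snp_ids,
        cross=np.array([cross_label] * n_progeny, dtype=object),
        chrom=lmap.chrom,
        pos_cm=lmap.pos_cm,
    )


def inject_missing(
    g: GenotypeMatrix, rate: float, seed: int = 0
) -> Tuple[GenotypeMatrix, MissingMask]:
    """Hide exactly ``round(rate * n_entries)`` entries of a complete matrix.

    Cells are chosen uniformly without replacement; the returned mask
    records their coordinates and true genotype codes.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"masking rate {rate} outside [0, 1]")
    if not g.is_complete:
        raise ValueError("inject_missing requires a complete matrix")
    total = g.n_plants * g.n_snps
    n_mask = int(round(rate * total))
    rng = np.random.default_rng(seed)
    flat = rng.choice(total, size=n_mask, replace=False)
    rows, cols = np.unravel_index(flat, g.codes.shape)
    out = g.copy()
    values = out.codes[rows, cols].copy()
    out.codes[rows, cols] = MISSING
    return out, MissingMask(rows, cols, values)


@dataclass(frozen=True)
class TrueValues:
    """Simulated effects (and the drawing kinship) kept aside for
    recovery tests."""

    a: np.ndarray
    pe: np.ndarray
    year_effects: np.ndarray
    mu: float
    kinship: object = None  # KinshipMatrix used to draw breeding values


def simulation_kinship(g: GenotypeMatrix):
    """Kinship used to draw breeding values: the standardized GRM on the
    polymorphic loci of ``g``, rescaled to unit mean self-relationship so
    the realized additive variance matches ``sigma2_a``."""
    from .kinship import KinshipMatrix, compute_grm

    freq = g.codes.mean(axis=0) / 2.0
    poly = (freq > 0.0) & (freq < 1.0)
    if not poly.any():
        raise ValueError("no polymorphic locus to build the kinship from")
    K = compute_grm(g.subset_snps(np.flatnonzero(poly)), scale="standard")
    Gn = K.matrix / np.diag(K.matrix).mean()
    return KinshipMatrix(
        ids=K.ids, matrix=Gn, freqs=K.freqs, scope="simulation"
    )


def simulate_phenotypes(
    g: GenotypeMatrix, config: SimConfig, kinship=None
) -> Tuple[pd.DataFrame, TrueValues]:
    """Repeated-record phenotypes: value = mu + year + a + pe + e.

    Breeding values are multivariate normal with covariance G * sigma2_a
    (G from :func:`simulation_kinship` unless ``kinship`` is supplied;
    1e-6 diagonal jitter before factorization); permanent-environment
    effects are iid per plant and residuals iid per record. One record
    per plant per year unless ``dropout`` > 0. The kinship actually used
    is returned in :class:`TrueValues` so the fitted model can match the
    generating model exactly.
    """
    if not g.is_complete:
        raise ValueError("genotypes must be complete; impute first")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    n = g.n_plants

    K = kinship if kinship is not None else simulation_kinship(g)
    G = K.matrix + 1e-6 * np.eye(n)
    try:
        L = np.linalg.cholesky(G)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise ValueError(
            "kinship matrix G not positive definite after jitter"
        ) from exc

    a = np.sqrt(config.sigma2_a) * (L @ rng.standard_normal(n))
    pe = np.sqrt(config.sigma2_pe) * rng.standard_normal(n)

    rows = []
    for year_idx in range(config.n_years):
        keep = rng.random(n) >= config.dropout
        e = np.sqrt(config.sigma2_e) * rng.standard_normal(n)
        values = (
            config.mu + config.year_effects[year_idx] + a + pe + e
        )
        for i in np.flatnonzero(keep):
            rows.append(
                (g.plant_ids[i], year_idx + 1, config.trait, values[i])
            )
    records = pd.DataFrame(rows, columns=["plant", "year", "trait", "value"])
    truth = TrueValues(
        a=a,
        pe=pe,
        year_effects=np.asarray(config.year_effects, dtype=float),
        mu=config.mu,
        kinship=K,
    )
    return records, truth


def simulate_cross(
    config: SimConfig,
) -> Tuple[GenotypeMatrix, pd.DataFrame, TrueValues]:
    """Full single-cross simulation: parents, progeny, phenotypes, then
    optional missingness injected into the released genotypes."""
    parents, lmap = simulate_parents(config)
    g = simulate_progeny(
        parents,
        lmap,
        config.n_progeny,
        seed=config.seed,
        cross_label=config.cross_label,
    )
    records, truth = simulate_phenotypes(g, config)
    if config.missing_rate > 0:
        g, _ = inject_missing(g, config.missing_rate, seed=config.seed + 17)
    return g, records, truth


def simulate_dataset(
    config: SimConfig, n_crosses: int = 3
) -> Tuple[GenotypeMatrix, pd.DataFrame]:
    """Several independent crosses stacked into one labelled dataset.

    Crosses share the SNP panel/map but descend from independent parent
    pairs, mimicking a multi-progeny design.
    """
    if n_crosses < 1:
        raise ConfigError("n_crosses must be positive")
    parts, tables = [], []
    for c in range(n_crosses):
        label = f"C{c + 1:02d}"
        cfg = SimConfig(
            **{
                **config.__dict__,
                "seed": config.seed + 1000 * c,
                "cross_label": label,
            }
        )
        g, records, _ = simulate_cross(cfg)
        parts.append(g)
        tables.append(records.assign(cross=label))
    codes = np.concatenate([p.codes for p in parts], axis=0)
    plant_ids = np.concatenate([p.plant_ids for p in parts])
    cross = np.concatenate([p.cross for p in parts])
    g_all = GenotypeMatrix(
        codes=codes,
        plant_ids=plant_ids,
        snp_ids=parts[0].snp_ids,
        cross=cross,
        chrom=parts[0].chrom,
        pos_cm=parts[0].pos_cm,
    )
    return g_all, pd.concat(tables, ignore_index=True)
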