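import numpy as np
import pytest

from repeatgs.matrix import GenotypeMatrix
from repeatgs.simulate import SimConfig, simulate_cross, simulate_parents, simulate_progeny


@pytest.fixture(scope="session")
def small_cross():
    """A modest complete F1 cross reused by several test modules."""
    cfg = SimConfig(
        n_progeny=50,
        n_snp=200,
        n_chromosomes=4,
        parental_heterozygosity=0.6,
        seed=42,
    )
    parents, lmap = simulate_parents(cfg)
    return simulate_progeny(parents, lmap, cfg.n_progeny, seed=42)


@pytest.fixture(scope="session")
def simulated_fit_instance():
    """Simulated cross with phenotypes at (h2, R) = (0.5, 0.7)."""
    cfg = SimConfig(
        n_progeny=120,
        n_snp=500,
        sigma2_a=0.5,
        sigma2_pe=0.2,
        sigma2_e=0.3,
        year_effects=(0.0, 0.5, -0.3),
        mu=10.0,
        seed=7,
    )
    g, records, truth = simulate_cross(cfg)
    return cfg, g, records, truth


def toy_matrix(codes, cross=None, chrom=None, pos_cm=None):
    codes = np.asarray(codes)
    n, m = codes.shape
    return GenotypeMatrix(
        codes=codes,
        plant_ids=[f"p{i}" for i in range(n)],
        snp_ids=[f"s{j}" for j in range(m)],
        cross=cross,
        chrom=chrom,
        pos_cm=pos_cm,
    )
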