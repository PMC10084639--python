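"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

import pleioscan as ps


@pytest.fixture(scope="session")
def small_cohort():
    """~500 animals x 1200 variants, 3 correlated traits, one pleiotropic QTL."""
    R = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.2], [0.3, 0.2, 1.0]])
    cfg = ps.SimConfig(
        n_samples=500,
        n_variants=1200,
        chrom_lengths={"1": 5_000_000, "2": 5_000_000},
        trait_groups={"prod": ["T1", "T2", "T3"]},
        h2={"T1": 0.4, "T2": 0.3, "T3": 0.3},
        genetic_corr=R,
        qtl=[ps.QTL("1", 2_000_000, {"T1": 0.06, "T2": 0.04})],
        missing_rate=0.1,
        seed=7,
    )
    geno = ps.simulate_genotypes(cfg)
    phen, truth = ps.simulate_phenotypes(geno, cfg)
    return cfg, geno, phen, truth


@pytest.fixture(scope="session")
def small_grm(small_cohort):
    _, geno, _, _ = small_cohort
    return ps.compute_grm_centered(geno)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
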