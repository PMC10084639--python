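"""Shared cohort builder for the example scripts."""

import numpy as np

import pleioscan as ps


def pleiotropic_cohort(seed=11, n=1000, m=4000):
    cfg = ps.SimConfig(
        n_samples=n,
        n_variants=m,
        chrom_lengths={str(c): 5_000_000 for c in range(1, 5)},
        trait_groups={"production": ["ADFI", "DWG", "BFT"]},
        h2={"ADFI": 0.37, "DWG": 0.24, "BFT": 0.47},
        genetic_corr=np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.2], [0.3, 0.2, 1.0]]),
        qtl=[ps.QTL("1", 2_500_000, {"ADFI": 0.04, "DWG": 0.03})],
        missing_rate=0.15,
        seed=seed,
    )
    geno = ps.simulate_genotypes(cfg)
    phen, truth = ps.simulate_phenotypes(geno, cfg)
    return cfg, geno, phen, truth
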