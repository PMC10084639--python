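"""Simulator: determinism, allele frequencies, LD structure, phenotype
variance partition, eligibility filters and imputation masking."""

import numpy as np
import pytest

import pleioscan as ps
from pleioscan.sim import ConfigError


def _cfg(**kw):
    base = dict(
        n_samples=300,
        n_variants=400,
        chrom_lengths={"1": 2_000_000, "2": 2_000_000},
        trait_groups={"g": ["A"]},
        h2={"A": 0.3},
        seed=11,
    )
    base.update(kw)
    return ps.SimConfig(**base)


class TestSimulateGenotypes:
    def test_deterministic_under_fixed_seed(self):
        g1 = ps.simulate_genotypes(_cfg())
        g2 = ps.simulate_genotypes(_cfg())
        assert np.array_equal(g1.dosages, g2.dosages)
        assert g1.variants.equals(g2.variants)

    def test_different_seed_changes_data(self):
        g1 = ps.simulate_genotypes(_cfg(seed=1))
        g2 = ps.simulate_genotypes(_cfg(seed=2))
        assert not np.array_equal(g1.dosages, g2.dosages)

    def test_forced_half_frequency(self):
        # maf_range pinned at 0.5: realized MAF ~ 0.5 within 3 binomial SE
        g = ps.simulate_genotypes(_cfg(n_samples=2000, maf_range=(0.5, 0.5)))
        se = np.sqrt(0.5 * 0.5 / (2 * 2000))
        # founder sampling adds variance beyond binomial; allow a loose band
        assert np.all(np.abs(g.maf().mean() - 0.5) < 3 * se + 0.02)
        assert np.median(np.abs(g.maf() - 0.5)) < 0.1

    def test_blocks_create_ld_and_singletons_do_not(self):
        g_ld = ps.simulate_genotypes(_cfg(n_samples=1000, ld_block_size=20))
        g_no = ps.simulate_genotypes(_cfg(n_samples=1000, ld_block_size=1))

        def mean_adjacent_r2(g):
            x = g.dosages
            r2 = []
            for j in range(0, g.n_variants - 1, 2):
                a, b = x[:, j], x[:, j + 1]
                if a.std() > 0 and b.std() > 0:
                    r2.append(np.corrcoef(a, b)[0, 1] ** 2)
            return float(np.mean(r2))

        assert mean_adjacent_r2(g_no) < 0.05
        # with k founders per block, expected pairwise r2 is ~1/(k-1)
        assert mean_adjacent_r2(g_ld) > 0.08

    def test_maf_within_configured_range(self):
        g = ps.simulate_genotypes(_cfg(n_samples=2000, maf_range=(0.2, 0.4)))
        # founder-count granularity is 1/8; allow that plus sampling error
        assert g.maf().min() > 0.2 - 1 / 16 - 0.03
        assert g.maf().max() < 0.4 + 1 / 16 + 0.03

    def test_positions_strictly_increasing_within_chromosome(self):
        g = ps.simulate_genotypes(_cfg())
        for _, sub in g.variants.groupby("chrom"):
            assert np.all(np.diff(sub["pos"].to_numpy()) > 0)

    @pytest.mark.parametrize(
        "bad",
        [dict(maf_range=(0.0, 0.5)), dict(maf_range=(0.4, 0.2)),
         dict(ld_block_size=10_000), dict(ld_block_size=0)],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigError):
            ps.simulate_genotypes(_cfg(**bad))


class TestSimulatePhenotypes:
    def test_no_signal_gives_uncorrelated_traits(self):
        cfg = _cfg(
            n_samples=1500,
            trait_groups={"g": ["A", "B", "C"]},
            h2={"A": 0.0, "B": 0.0, "C": 0.0},
        )
        geno = ps.simulate_genotypes(cfg)
        phen, truth = ps.simulate_phenotypes(geno, cfg)
        C = np.corrcoef(phen.values, rowvar=False)
        off = C[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 3 / np.sqrt(1500))
        assert all(v < 0.01 for v in truth.realized_h2.values())

    def test_qtl_variance_fraction_recovered_by_regression(self):
        cfg = _cfg(
            n_samples=2000, n_variants=600,
            h2={"A": 0.3},
            qtl=[ps.QTL("1", 1_000_000, {"A": 0.10})],
        )
        geno = ps.simulate_genotypes(cfg)
        phen, truth = ps.simulate_phenotypes(geno, cfg)
        x = geno.dosages[:, geno.column_of("1_1000000")]
        y = phen.values[:, 0]
        r2 = np.corrcoef(x, y)[0, 1] ** 2
        assert r2 == pytest.approx(0.10, abs=0.03)
        assert truth.realized_qtl_variance_fraction[("1_1000000", "A")] == pytest.approx(
            0.10, abs=0.03
        )

    def test_missing_rate_realized(self):
        cfg = _cfg(n_samples=3000, missing_rate=0.37)
        geno = ps.simulate_genotypes(cfg)
        phen, _ = ps.simulate_phenotypes(geno, cfg)
        frac = np.isnan(phen.values[:, 0]).mean()
        se = np.sqrt(0.37 * 0.63 / 3000)
        assert abs(frac - 0.37) < 4 * se

    def test_qtl_outside_genotypes_rejected(self):
        cfg = _cfg(qtl=[ps.QTL("1", 999_999, {"A": 0.05})])
        geno = ps.simulate_genotypes(_cfg())  # without the QTL variant
        with pytest.raises(ConfigError):
            ps.simulate_phenotypes(geno, cfg)

    def test_realized_h2_tracks_target(self):
        cfg = _cfg(n_samples=2000, n_variants=800, h2={"A": 0.5})
        geno = ps.simulate_genotypes(cfg)
        _, truth = ps.simulate_phenotypes(geno, cfg)
        assert truth.realized_h2["A"] == pytest.approx(0.5, abs=0.08)

    def test_weights_are_monotone_in_reliability(self, small_cohort):
        _, _, phen, _ = small_cohort
        r = phen.reliability.ravel()
        w = phen.weight.ravel()
        order = np.argsort(r)
        assert np.all(np.diff(w[order]) >= 0)


class TestDrebvFilters:
    def test_no_op_when_everything_eligible(self, small_cohort):
        _, _, phen, _ = small_cohort
        out = ps.apply_drebv_filters(phen, min_reliability=0.0, sd_limit=50.0,
                                     min_records=1)
        assert np.array_equal(out.values, phen.values, equal_nan=True)

    def test_outlier_removed_at_five_sd(self):
        vals = np.zeros((100, 1))
        vals[:50, 0] = 1.0
        vals[0, 0] = 40.0  # way beyond 5 SD
        phen = ps.PhenotypeSet(
            samples=[f"s{i}" for i in range(100)], traits=["A"], values=vals,
            reliability=np.ones((100, 1)), weight=np.ones((100, 1)),
            group_of={"A": "g"},
        )
        out = ps.apply_drebv_filters(phen, min_reliability=0.0, sd_limit=5.0,
                                     min_records=1)
        assert np.isnan(out.values[0, 0])
        assert np.sum(np.isnan(out.values)) == 1

    def test_low_reliability_set_missing(self, small_cohort):
        _, _, phen, _ = small_cohort
        out = ps.apply_drebv_filters(phen, min_reliability=0.6, sd_limit=50.0,
                                     min_records=1)
        low = phen.reliability <= 0.6
        assert np.all(np.isnan(out.values[low]))

    def test_underpowered_trait_dropped(self):
        vals = np.random.default_rng(0).normal(size=(50, 2))
        vals[10:, 1] = np.nan  # 40 missing -> only 10 records
        phen = ps.PhenotypeSet(
            samples=[f"s{i}" for i in range(50)], traits=["A", "B"], values=vals,
            reliability=np.ones((50, 2)), weight=np.ones((50, 2)),
            group_of={"A": "g", "B": "g"},
        )
        out = ps.apply_drebv_filters(phen, min_reliability=0.0, sd_limit=50.0,
                                     min_records=20)
        assert out.traits == ["A"]


class TestCompleteCase:
    def test_identity_without_missingness(self):
        cfg = _cfg(missing_rate=0.0)
        geno = ps.simulate_genotypes(cfg)
        phen, _ = ps.simulate_phenotypes(geno, cfg)
        cc = ps.complete_case_subset(phen, "g")
        assert cc.n_samples == phen.n_samples

    def test_forced_exclusion(self):
        vals = np.ones((3, 1))
        vals[1, 0] = np.nan
        phen = ps.PhenotypeSet(
            samples=["s1", "s2", "s3"], traits=["A"], values=vals,
            reliability=np.ones((3, 1)), weight=np.ones((3, 1)),
            group_of={"A": "g"},
        )
        cc = ps.complete_case_subset(phen, "g")
        assert cc.samples == ["s1", "s3"]

    def test_multiplicative_shrinkage_of_complete_cases(self):
        d = 12
        cfg = _cfg(
            n_samples=4000,
            trait_groups={"g": [f"T{i}" for i in range(d)]},
            h2={f"T{i}": 0.1 for i in range(d)},
            missing_rate=0.05,
        )
        geno = ps.simulate_genotypes(cfg)
        phen, _ = ps.simulate_phenotypes(geno, cfg)
        cc = ps.complete_case_subset(phen, "g")
        expected = 4000 * 0.95**d
        assert cc.n_samples == pytest.approx(expected, rel=0.1)

    def test_empty_group_errors(self, small_cohort):
        _, _, phen, _ = small_cohort
        with pytest.raises(KeyError):
            ps.complete_case_subset(phen, "nonexistent")


class TestImputationMask:
    def test_mask_shapes_and_round_trip(self, small_cohort):
        _, geno, _, _ = small_cohort
        ids = list(geno.variants["id"])
        keep = ids[::2]
        holdout = geno.samples[:10]
        masked, truth = ps.mask_for_imputation_cv(geno, keep, holdout)
        n_masked_sites = geno.n_variants - len(keep)
        assert truth.dosages.shape == (10, n_masked_sites)
        # unmasked entries identical to the input
        keep_cols = geno.variants["id"].isin(keep).to_numpy()
        assert np.array_equal(
            masked.dosages[:, keep_cols], geno.dosages[:, keep_cols], equal_nan=True
        )
        other_rows = np.arange(10, geno.n_samples)
        assert np.array_equal(
            masked.dosages[other_rows], geno.dosages[other_rows], equal_nan=True
        )
        # masked entries are missing, truth holds the originals
        assert np.all(np.isnan(masked.dosages[np.ix_(range(10), np.flatnonzero(~keep_cols))]))
        assert np.array_equal(
            truth.dosages, geno.dosages[np.ix_(range(10), np.flatnonzero(~keep_cols))]
        )

    def test_keep_all_sites_gives_empty_truth(self, small_cohort):
        _, geno, _, _ = small_cohort
        _, truth = ps.mask_for_imputation_cv(
            geno, list(geno.variants["id"]), geno.samples[:5]
        )
        assert truth.n_variants == 0

    def test_unknown_holdout_rejected(self, small_cohort):
        _, geno, _, _ = small_cohort
        with pytest.raises(KeyError):
            ps.mask_for_imputation_cv(geno, list(geno.variants["id"][:5]), ["ghost"])
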