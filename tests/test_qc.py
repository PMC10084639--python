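"""QC: panel merging, exact HWE test, filter cascade, GRM, PCA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import pleioscan as ps
from pleioscan.qc import hwe_pvalues


def _panel(samples, rows, dosages):
    variants = pd.DataFrame(rows, columns=["chrom", "pos", "id", "ref", "alt"])
    return ps.GenotypeMatrix(samples=samples, variants=variants,
                             dosages=np.asarray(dosages, dtype=float))


class TestMergePanels:
    def test_disjoint_samples_same_map(self):
        rows = [("1", 100, "v1", "A", "C"), ("1", 200, "v2", "G", "T")]
        p1 = _panel(["a", "b"], rows, [[0, 1], [2, 0]])
        p2 = _panel(["c"], rows, [[1, 1]])
        merged = ps.merge_panels([p1, p2])
        assert merged.samples == ["a", "b", "c"]
        assert merged.n_variants == 2
        assert np.array_equal(merged.dosages, [[0, 1], [2, 0], [1, 1]])

    def test_allele_swap_flips_dosage(self):
        p1 = _panel(["a"], [("1", 100, "v1", "A", "C")], [[0.0]])
        p2 = _panel(["b"], [("1", 100, "v1", "C", "A")], [[0.0]])
        merged = ps.merge_panels([p1, p2])
        assert merged.dosages[0, 0] == 0.0   # panel-1 convention kept
        assert merged.dosages[1, 0] == 2.0   # panel-2 flipped

    def test_conflicting_alleles_dropped(self):
        p1 = _panel(["a"], [("1", 100, "v1", "A", "C")], [[1.0]])
        p2 = _panel(["b"], [("1", 100, "v1", "G", "T")], [[1.0]])
        merged = ps.merge_panels([p1, p2])
        assert merged.n_variants == 0

    def test_missing_where_panel_lacks_variant(self):
        p1 = _panel(["a"], [("1", 100, "v1", "A", "C")], [[1.0]])
        p2 = _panel(["b"], [("1", 200, "v2", "G", "T")], [[2.0]])
        merged = ps.merge_panels([p1, p2])
        assert merged.n_variants == 2
        assert np.isnan(merged.dosages[0, 1]) and np.isnan(merged.dosages[1, 0])
        assert merged.dosages[0, 0] == 1.0 and merged.dosages[1, 1] == 2.0


class TestHweExact:
    def test_mode_table_has_p_one(self):
        assert ps.hwe_exact_p(25, 50, 25) == pytest.approx(1.0)

    def test_extreme_heterozygote_excess(self):
        assert ps.hwe_exact_p(0, 50, 0) < 1e-5

    def test_monomorphic_is_one(self):
        assert ps.hwe_exact_p(40, 0, 0) == 1.0
        assert ps.hwe_exact_p(0, 0, 40) == 1.0

    @pytest.mark.parametrize("counts", [(5, 10, 5), (30, 10, 2), (1, 1, 1),
                                        (0, 3, 17), (12, 0, 8)])
    def test_matches_full_enumeration(self, counts):
        """Oracle: enumerate every genotype table with the observed allele
        counts, weight by the exact conditional probability, sum tables no
        more probable than the observed."""
        n_AA, n_Aa, n_aa = counts
        n = sum(counts)
        n_a = 2 * n_aa + n_Aa

        def log_prob(het):
            aa = (n_a - het) // 2
            AA = n - het - aa
            # multivariate hypergeometric-style conditional probability
            from math import lgamma

            def lf(x):
                return lgamma(x + 1)

            return (lf(n) - lf(AA) - lf(het) - lf(aa) + het * np.log(2)
                    + lf(n_a) + lf(2 * n - n_a) - lf(2 * n))

        hets = [h for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)]
        probs = np.exp([log_prob(h) for h in hets])
        probs /= probs.sum()
        p_obs = probs[hets.index(n_Aa)]
        expected = probs[probs <= p_obs * (1 + 1e-12)].sum()
        assert ps.hwe_exact_p(n_AA, n_Aa, n_aa) == pytest.approx(expected, rel=1e-10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ps.hwe_exact_p(0, 0, 0)


class TestQcFilter:
    def test_maf_filter_counts(self, rng):
        d = rng.integers(0, 3, size=(1000, 10)).astype(float)
        d[:, 0] = 0.0
        d[:4, 0] = 1.0  # MAF 0.002 < 0.005
        variants = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, 11) * 100,
            "id": [f"v{i}" for i in range(10)], "ref": "A", "alt": "C",
        })
        geno = ps.GenotypeMatrix(samples=[f"s{i}" for i in range(1000)],
                                 variants=variants, dosages=d)
        out, report = ps.qc_filter(geno, maf_min=0.005)
        assert out.n_variants == 9
        assert report.n_removed_by["maf"] == 1

    def test_dr2_filter_under_post_imputation_preset(self, rng):
        d = rng.integers(0, 3, size=(200, 4)).astype(float)
        variants = pd.DataFrame({
            "chrom": "1", "pos": [100, 200, 300, 400],
            "id": ["v0", "v1", "v2", "v3"], "ref": "A", "alt": "C",
            "dr2": [0.9, 0.5, 0.95, 0.61],
        })
        geno = ps.GenotypeMatrix(samples=[f"s{i}" for i in range(200)],
                                 variants=variants, dosages=d)
        out, report = ps.qc_filter(geno, maf_min=0.0, hwe_p_min=0.0, dr2_min=0.6)
        assert "v1" not in set(out.variants["id"])
        assert report.n_removed_by["dr2"] == 1

    def test_all_zero_thresholds_identity(self, small_cohort):
        _, geno, _, _ = small_cohort
        out, report = ps.qc_filter(geno)
        assert out.n_variants == geno.n_variants
        assert report.n_removed_samples == 0

    def test_idempotent(self, small_cohort):
        _, geno, _, _ = small_cohort
        kw = dict(maf_min=0.1, hwe_p_min=1e-5, var_call_min=0.8, sample_call_min=0.8)
        once, _ = ps.qc_filter(geno, **kw)
        twice, rep = ps.qc_filter(once, **kw)
        assert twice.n_variants == once.n_variants
        assert all(v == 0 for v in rep.n_removed_by.values())

    def test_report_counts_consistent(self, small_cohort):
        _, geno, _, _ = small_cohort
        _, report = ps.qc_filter(geno, maf_min=0.2, hwe_p_min=1e-3)
        assert (report.n_input_variants - sum(report.n_removed_by.values())
                == report.n_output_variants)

    def test_hwe_filter_removes_violations(self, rng):
        n = 500
        good = rng.binomial(2, 0.4, size=(n, 3)).astype(float)
        bad = np.ones((n, 1))  # all heterozygous: gross HWE violation
        d = np.hstack([good, bad])
        variants = pd.DataFrame({
            "chrom": "1", "pos": [100, 200, 300, 400],
            "id": list("abcd"), "ref": "A", "alt": "C",
        })
        geno = ps.GenotypeMatrix([f"s{i}" for i in range(n)], variants, d)
        out, report = ps.qc_filter(geno, hwe_p_min=1e-5)
        assert "d" not in set(out.variants["id"])
        assert report.n_removed_by["hwe"] >= 1
        ps_ = hwe_pvalues(geno)
        assert ps_[3] < 1e-5


class TestGrm:
    def test_two_sample_hand_computed(self):
        variants = pd.DataFrame({
            "chrom": "1", "pos": [100, 200, 300],
            "id": ["a", "b", "c"], "ref": "A", "alt": "C",
        })
        geno = ps.GenotypeMatrix(["s1", "s2"], variants,
                                 np.array([[0, 0, 0], [2, 2, 2]], dtype=float))
        grm = ps.compute_grm_centered(geno)
        assert np.allclose(grm.matrix, [[1, -1], [-1, 1]])

    def test_row_sums_zero(self, small_grm):
        n = small_grm.n_samples
        assert np.all(np.abs(small_grm.matrix.sum(axis=1)) < 1e-8 * n)

    def test_matches_brute_force_double_loop(self, rng):
        n, m = 20, 50
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        d[rng.random((n, m)) < 0.05] = np.nan
        variants = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, m + 1),
            "id": [f"v{i}" for i in range(m)], "ref": "A", "alt": "C",
        })
        geno = ps.GenotypeMatrix([f"s{i}" for i in range(n)], variants, d)
        grm = ps.compute_grm_centered(geno)

        X = d.copy()
        for j in range(m):
            mu = np.nanmean(X[:, j])
            col = X[:, j]
            col[np.isnan(col)] = mu
            X[:, j] = col - mu
        expect = np.zeros((n, n))
        for i in range(n):
            for k in range(n):
                expect[i, k] = np.dot(X[i], X[k]) / m
        assert np.allclose(grm.matrix, expect, atol=1e-10)

    def test_duplicated_individual_identical_rows(self, rng):
        n, m = 10, 30
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        d[1] = d[0]
        variants = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, m + 1),
            "id": [f"v{i}" for i in range(m)], "ref": "A", "alt": "C",
        })
        geno = ps.GenotypeMatrix([f"s{i}" for i in range(n)], variants, d)
        grm = ps.compute_grm_centered(geno)
        assert np.allclose(grm.matrix[0], grm.matrix[1])

    def test_psd_up_to_tolerance(self, small_grm):
        assert np.linalg.eigvalsh(small_grm.matrix).min() > -1e-8


class TestPcaGrm:
    def test_two_clusters_separated_by_pc1(self, rng):
        m = 200
        a = rng.integers(0, 3, size=m).astype(float)
        b = rng.integers(0, 3, size=m).astype(float)
        d = np.vstack([np.tile(a, (5, 1)), np.tile(b, (5, 1))])
        d += rng.normal(0, 0.01, size=d.shape)
        d = np.clip(d, 0, 2)
        variants = pd.DataFrame({
            "chrom": "1", "pos": np.arange(1, m + 1),
            "id": [f"v{i}" for i in range(m)], "ref": "A", "alt": "C",
        })
        geno = ps.GenotypeMatrix([f"s{i}" for i in range(10)], variants, d)
        coords, frac = ps.pca_grm(ps.compute_grm_centered(geno), k=3)
        pc1 = coords["PC1"].to_numpy()
        assert (pc1[:5] > 0).all() != (pc1[5:] > 0).all()  # clusters on opposite sides
        assert frac[0] > 0.9

    def test_fractions_sorted_and_bounded(self, small_grm):
        _, frac = ps.pca_grm(small_grm, k=10)
        assert np.all(np.diff(frac) <= 1e-12)
        assert frac.sum() <= 1.0 + 1e-9

    def test_k_larger_than_n_rejected(self, small_grm):
        with pytest.raises(ValueError):
            ps.pca_grm(small_grm, k=small_grm.n_samples + 1)
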