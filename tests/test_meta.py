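"""Meta-analysis: t-matrix assembly, V estimation, chi-square statistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import pleioscan as ps
from pleioscan.meta import TMatrix, VMatrix


def _stats(trait, ids, betas, ses, ea="C", oa="A", n=100, pos=None):
    m = len(ids)
    pos = pos if pos is not None else np.arange(1, m + 1) * 1000
    rec = pd.DataFrame({
        "variant_id": ids, "chrom": "1", "pos": pos,
        "effect_allele": [ea] * m if isinstance(ea, str) else ea,
        "other_allele": [oa] * m if isinstance(oa, str) else oa,
        "af": 0.3, "beta": betas, "se": ses,
        "p": 2 * sstats.norm.sf(np.abs(np.asarray(betas) / np.asarray(ses))),
        "n": n,
    })
    return ps.SummaryStats(trait=trait, records=rec)


class TestAssembleT:
    def test_t_is_beta_over_se(self):
        s1 = _stats("a", ["v1"], [0.2], [0.1])
        s2 = _stats("b", ["v1"], [0.3], [0.1])
        tm = ps.assemble_t([s1, s2])
        assert tm.t[0, 0] == pytest.approx(2.0)
        assert tm.t[0, 1] == pytest.approx(3.0)

    def test_swapped_alleles_flip_sign(self):
        s1 = _stats("a", ["v1"], [0.2], [0.1], ea="C", oa="A")
        s2 = _stats("b", ["v1"], [-0.2], [0.1], ea="A", oa="C")
        tm = ps.assemble_t([s1, s2])
        assert tm.t[0, 1] == pytest.approx(2.0)  # harmonised to +2

    def test_intersection_of_variants(self):
        ids1 = [f"v{i}" for i in range(100)]
        ids2 = [f"v{i}" for i in range(40, 120)]
        s1 = _stats("a", ids1, np.ones(100), np.ones(100),
                    pos=np.arange(1, 101) * 1000)
        s2 = _stats("b", ids2, np.ones(80), np.ones(80),
                    pos=np.arange(41, 121) * 1000)
        tm = ps.assemble_t([s1, s2])
        assert tm.n_variants == 60

    def test_irreconcilable_alleles_dropped(self):
        s1 = _stats("a", ["v1", "v2"], [0.1, 0.1], [0.1, 0.1], ea="C", oa="A")
        s2 = _stats("b", ["v1", "v2"], [0.1, 0.1], [0.1, 0.1],
                    ea=["C", "G"], oa=["A", "T"])
        tm = ps.assemble_t([s1, s2])
        assert tm.n_variants == 1
        assert tm.n_dropped_allele_mismatch == 1

    def test_heterogeneous_sample_sizes_carried(self):
        s1 = _stats("a", ["v1"], [0.2], [0.1], n=100)
        s2 = _stats("b", ["v1"], [0.2], [0.1], n=80)
        tm = ps.assemble_t([s1, s2])
        assert tm.source_n[0, 0] == 100 and tm.source_n[0, 1] == 80


class TestEstimateV:
    def test_independent_null_traits_near_identity(self, rng):
        m = 5000
        t = rng.standard_normal((m, 2))
        tm = TMatrix(
            variants=pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1),
                                   "variant_id": [f"v{i}" for i in range(m)],
                                   "effect_allele": "C", "other_allele": "A"}),
            traits=["a", "b"], t=t, source_n=np.full((m, 2), 100),
        )
        v = ps.estimate_v(tm)
        assert abs(v.V[0, 1]) < 0.03

    def test_duplicated_trait_column_rejected(self, rng):
        m = 200
        t1 = rng.standard_normal(m)
        tm = TMatrix(
            variants=pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1),
                                   "variant_id": [f"v{i}" for i in range(m)],
                                   "effect_allele": "C", "other_allele": "A"}),
            traits=["a", "b"], t=np.column_stack([t1, t1]),
            source_n=np.full((m, 2), 100),
        )
        with pytest.raises(ValueError, match="singular"):
            ps.estimate_v(tm)

    def test_null_marker_mode_excludes_large_t(self, rng):
        m = 1000
        t = rng.standard_normal((m, 2))
        t[:50, :] = 8.0  # strong shared QTL signal inflates the correlation
        tm = TMatrix(
            variants=pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1),
                                   "variant_id": [f"v{i}" for i in range(m)],
                                   "effect_allele": "C", "other_allele": "A"}),
            traits=["a", "b"], t=t, source_n=np.full((m, 2), 100),
        )
        v_all = ps.estimate_v(tm, mode="all_markers")
        v_null = ps.estimate_v(tm, mode="null_markers")
        assert v_all.V[0, 1] > 0.2
        assert abs(v_null.V[0, 1]) < 0.1

    def test_too_few_markers_rejected(self, rng):
        tm = TMatrix(
            variants=pd.DataFrame({"chrom": "1", "pos": np.arange(1, 11),
                                   "variant_id": [f"v{i}" for i in range(10)],
                                   "effect_allele": "C", "other_allele": "A"}),
            traits=["a", "b"], t=rng.standard_normal((10, 2)),
            source_n=np.full((10, 2), 100),
        )
        with pytest.raises(ValueError, match="at least"):
            ps.estimate_v(tm)


def _tmatrix(t):
    m, d = t.shape
    return TMatrix(
        variants=pd.DataFrame({"chrom": "1", "pos": np.arange(1, m + 1),
                               "variant_id": [f"v{i}" for i in range(m)],
                               "effect_allele": "C", "other_allele": "A"}),
        traits=[f"t{k}" for k in range(d)], t=t, source_n=np.full((m, d), 100),
    )


def _vmatrix(V, traits):
    return VMatrix(traits=traits, V=V, estimation_mode="all_markers",
                   condition_number=float(np.linalg.cond(V)))


class TestMetaChi2:
    def test_single_trait_reduction(self):
        tm = _tmatrix(np.array([[2.0]]))
        mr = ps.meta_chi2(tm, _vmatrix(np.eye(1), tm.traits), df_mode="d")
        assert mr.records.at[0, "chi2"] == pytest.approx(4.0)
        assert mr.records.at[0, "p"] == pytest.approx(sstats.chi2.sf(4.0, 1), rel=1e-12)

    def test_identity_v_is_euclidean_norm(self):
        tm = _tmatrix(np.array([[3.0, 4.0]]))
        mr = ps.meta_chi2(tm, _vmatrix(np.eye(2), tm.traits), df_mode="d")
        assert mr.records.at[0, "chi2"] == pytest.approx(25.0)

    def test_correlated_v_hand_solved(self):
        # t = (2,2), V = [[1,.5],[.5,1]] -> chi2 = 16/3
        tm = _tmatrix(np.array([[2.0, 2.0]]))
        V = np.array([[1.0, 0.5], [0.5, 1.0]])
        mr = ps.meta_chi2(tm, _vmatrix(V, tm.traits), df_mode="d")
        assert mr.records.at[0, "chi2"] == pytest.approx(16.0 / 3.0, rel=1e-12)

    def test_df_modes(self):
        tm = _tmatrix(np.ones((1, 3)))
        v = _vmatrix(np.eye(3), tm.traits)
        assert ps.meta_chi2(tm, v, df_mode="d").records.at[0, "df"] == 3
        assert ps.meta_chi2(tm, v, df_mode="d_minus_1").records.at[0, "df"] == 2

    def test_identity_v_df_d_equals_independent_sum(self, rng):
        d = 4
        t = rng.standard_normal((200, d))
        tm = _tmatrix(t)
        mr = ps.meta_chi2(tm, _vmatrix(np.eye(d), tm.traits), df_mode="d")
        direct = sstats.chi2.sf(np.sum(t**2, axis=1), df=d)
        assert np.allclose(mr.records["p"], direct, rtol=1e-10)

    def test_sign_flip_invariance(self, rng):
        d = 3
        t = rng.standard_normal((50, d))
        A = rng.standard_normal((d, d))
        V = A @ A.T + d * np.eye(d)
        Dn = np.sqrt(np.outer(np.diag(V), np.diag(V)))
        V = V / Dn
        base = ps.meta_chi2(_tmatrix(t), _vmatrix(V, [f"t{k}" for k in range(d)]),
                            df_mode="d")
        flip = np.diag([1.0, -1.0, 1.0])
        t2 = t @ flip
        V2 = flip @ V @ flip
        out = ps.meta_chi2(_tmatrix(t2), _vmatrix(V2, [f"t{k}" for k in range(d)]),
                           df_mode="d")
        assert np.allclose(base.records["chi2"], out.records["chi2"], atol=1e-12)
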