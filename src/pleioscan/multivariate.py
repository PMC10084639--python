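"""Complete-case multivariate mixed-model association scan (mtGWAS).

Per variant the d-vector of trait effects is estimated by generalized
least squares under vec(Y') ~ N(.., G (x) Vg + I (x) Ve), and tested with
a Wald chi-square on d degrees of freedom.  Rotating samples into the
GRM eigenbasis and traits into the basis that jointly diagonalises
(Vg, Ve) decouples the problem into d independent weighted regressions
per variant, so the scan is O(n d) per variant after one matmul.

Vg and Ve are estimated once under the global null (see
``varcomp.estimate_mt_vc``) and held fixed across variants, consistent
with the score-test convention of the single-trait scan.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .assoc import _impute_and_af
from .containers import GenotypeMatrix
from .qc import GRM
from .varcomp import MultiTraitVC

logger = logging.getLogger(__name__)

_CHUNK = 2048
MAX_TRAITS = 24


def mv_scan(
    Y: np.ndarray,
    geno: GenotypeMatrix,
    grm: GRM,
    vc: MultiTraitVC,
    maf_min: float = 0.05,
    traits: list[str] | None = None,
) -> pd.DataFrame:
    """Wald scan of every variant against d traits jointly.

    Returns a DataFrame with one row per tested variant: variant columns,
    per-trait GLS effects ``beta_<trait>``, ``wald_chi2``, ``df`` (= d)
    and ``p``.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, d = Y.shape
    if np.isnan(Y).any():
        raise ValueError("mv_scan requires complete cases (no NaN)")
    if n != grm.n_samples:
        raise ValueError("Y not aligned to the GRM")
    if d > MAX_TRAITS:
        raise ValueError(f"at most {MAX_TRAITS} traits supported, got {d}")
    if d > 10:
        logger.warning(
            "scanning %d traits jointly; multivariate models can be "
            "over-parameterised beyond ~10 traits", d,
        )
    names = traits if traits is not None else (
        vc.traits if len(vc.traits) == d else [f"trait{i}" for i in range(d)]
    )

    Vg, Ve = np.asarray(vc.Vg, float), np.asarray(vc.Ve, float)
    if np.linalg.eigvalsh(Vg).min() < -1e-8 * max(np.trace(Vg), 1.0):
        raise ValueError("Vg is not positive semi-definite")
    ve_floor = 1e-10 * max(np.trace(Ve) / d, 1e-300)
    if np.linalg.eigvalsh(Ve).min() < ve_floor:
        Ve = Ve + ve_floor * np.eye(d)

    pos_of = {s: i for i, s in enumerate(geno.samples)}
    try:
        rows = np.array([pos_of[s] for s in grm.sample_ids], dtype=int)
    except KeyError as e:
        raise ValueError(f"scan genotypes lack sample {e.args[0]!r}") from None

    S, U = np.linalg.eigh(grm.matrix)
    S = np.clip(S, 0.0, None)
    lam, Phi = linalg.eigh(Vg, Ve)          # Phi' Ve Phi = I, Phi' Vg Phi = diag(lam)
    lam = np.clip(lam, 0.0, None)
    back = Ve @ Phi                          # maps transformed betas to trait scale
    Ys = (U.T @ Y) @ Phi
    wt = U.T @ np.ones(n)

    inv_h = 1.0 / (S[:, None] * lam[None, :] + 1.0)   # n x d
    a11 = np.sum(wt[:, None] ** 2 * inv_h, axis=0)     # per transformed trait
    b1 = np.sum(wt[:, None] * Ys * inv_h, axis=0)

    v = geno.variants
    out: list[dict] = []
    for start in range(0, geno.n_variants, _CHUNK):
        stop = min(start + _CHUNK, geno.n_variants)
        X, af = _impute_and_af(geno.dosages[rows, start:stop].copy())
        Xt = U.T @ X                                   # n x k
        maf = np.minimum(af, 1.0 - af)

        betas_s = np.empty((stop - start, d))
        var_s = np.empty((stop - start, d))
        for k in range(d):
            wk = inv_h[:, k]
            a12 = Xt.T @ (wt * wk)
            a22 = np.einsum("ik,i,ik->k", Xt, wk, Xt)
            b2 = Xt.T @ (Ys[:, k] * wk)
            det = a11[k] * a22 - a12**2
            det = np.where(det <= 0, np.nan, det)
            betas_s[:, k] = (a11[k] * b2 - a12 * b1[k]) / det
            var_s[:, k] = a11[k] / det

        with np.errstate(invalid="ignore"):
            chi2 = np.nansum(betas_s**2 / var_s, axis=1)
        betas = betas_s @ back.T

        for j in range(stop - start):
            if maf[j] < maf_min or not (maf[j] > 0) or np.isnan(var_s[j]).any():
                continue
            col = start + j
            rec = dict(
                variant_id=v.at[col, "id"], chrom=v.at[col, "chrom"],
                pos=int(v.at[col, "pos"]), effect_allele=v.at[col, "alt"],
                other_allele=v.at[col, "ref"], af=float(af[j]),
            )
            for t, b in zip(names, betas[j]):
                rec[f"beta_{t}"] = float(b)
            rec["wald_chi2"] = float(chi2[j])
            rec["df"] = d
            rec["p"] = max(float(stats.chi2.sf(chi2[j], df=d)), np.finfo(float).tiny)
            out.append(rec)
    return pd.DataFrame(out)
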