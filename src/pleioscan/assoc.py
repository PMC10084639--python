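"""Single-trait linear mixed-model association scan (stGWAS).

Model per variant:  y = W a + x b + u + e,  u ~ N(0, G sa2), e ~ N(0, I se2).

The GRM is eigendecomposed once per null fit; the variance ratio
lambda = sa2/se2 is estimated by REML under the global null and held
fixed across variants (score-test convention), so each variant costs
O(n) after rotation.  Each variant's p-value comes from the score
statistic against a chi-square with 1 df; the reported beta and SE are
the generalized-least-squares fit at the null variance parameters, so
t = beta/se is directly usable by the meta-analysis.

Conditional scans refit the null with lead-variant dosages appended to
the fixed-effect design and exclude those variants from the scan.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, SummaryStats
from .qc import GRM
from .varcomp import profile_reml

logger = logging.getLogger(__name__)

_CHUNK = 4096


@dataclass
class LMMNullModel:
    """Fitted null model: rotated data plus the REML variance ratio."""

    trait: str
    sample_ids: list[str]
    lam: float                  # sa2 / se2 at the REML optimum
    sigma_e2: float
    alpha: np.ndarray           # fixed-effect estimates (intercept first)
    eigvals: np.ndarray
    U: np.ndarray               # GRM eigenvectors (columns)
    rotated_y: np.ndarray
    rotated_X0: np.ndarray      # rotated fixed-effect design
    n_used: int
    converged: bool
    grm: GRM
    y: np.ndarray               # phenotype on the used samples
    covariates: np.ndarray | None = None
    fixed_variant_ids: list[str] = field(default_factory=list)

    @property
    def mu_hat(self) -> float:
        return float(self.alpha[0])


def _check_full_rank(W: np.ndarray, names: list[str]) -> None:
    _, Rmat = np.linalg.qr(W)
    diag = np.abs(np.diag(Rmat))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        culprits = [names[i] for i in np.flatnonzero(bad)]
        raise ValueError(f"fixed-effect design is rank deficient; collinear columns: {culprits}")


def fit_null(
    y: np.ndarray,
    grm: GRM,
    covariates: np.ndarray | None = None,
    trait: str = "trait",
    fixed_variant_ids: list[str] | None = None,
) -> LMMNullModel:
    """Eigendecompose the GRM and estimate lambda by REML under the null.

    NaN phenotypes are dropped together with the matching GRM rows.
    ``covariates`` (if given) are extra fixed-effect columns beyond the
    intercept; a rank-deficient design raises with the offending columns.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != grm.n_samples:
        raise ValueError("phenotype vector not aligned to the GRM")
    keep = np.flatnonzero(~np.isnan(y))
    yk = y[keep]
    n = len(yk)
    W = np.ones((n, 1))
    names = ["intercept"]
    cov_used = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        cov_used = cov[keep]
        W = np.column_stack([W, cov_used])
        names += [f"covariate{i}" for i in range(cov_used.shape[1])]
    _check_full_rank(W, names)

    K = grm.matrix[np.ix_(keep, keep)]
    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    yt = U.T @ yk
    Wt = U.T @ W
    lam, se2, alpha, _, converged = profile_reml(yt, Wt, S)
    return LMMNullModel(
        trait=trait,
        sample_ids=[grm.sample_ids[i] for i in keep],
        lam=lam, sigma_e2=se2, alpha=alpha,
        eigvals=S, U=U, rotated_y=yt, rotated_X0=Wt,
        n_used=n, converged=converged,
        grm=grm, y=yk, covariates=cov_used,
        fixed_variant_ids=list(fixed_variant_ids or []),
    )


def _impute_and_af(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing dosages per column; return (X, alt-allele freq)."""
    nanmask = np.isnan(X)
    if nanmask.any():
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(X, axis=0)
        mean = np.where(np.isnan(mean), 0.0, mean)
        X = np.where(nanmask, mean[None, :], X)
        af = mean / 2.0
    else:
        af = X.mean(axis=0) / 2.0
    return X, af


def score_scan(
    null: LMMNullModel, geno: GenotypeMatrix, maf_min: float = 0.05
) -> SummaryStats:
    """Score-test scan of every variant against the fitted null.

    Variants with MAF below ``maf_min`` on the scan samples, zero
    variance, or listed as conditioning covariates in the null are
    skipped.  beta/se come from GLS at the null variance parameters.
    """
    pos_of = {s: i for i, s in enumerate(geno.samples)}
    try:
        rows = np.array([pos_of[s] for s in null.sample_ids], dtype=int)
    except KeyError as e:
        raise ValueError(f"scan genotypes lack sample {e.args[0]!r}") from None

    h = null.lam * null.eigvals + 1.0
    d_inv = 1.0 / h
    Wt = null.rotated_X0
    Wd = Wt * d_inv[:, None]
    Qi = np.linalg.inv(Wt.T @ Wd)
    yt = null.rotated_y
    wy = Wd.T @ yt
    y_perp_quad = float(yt @ (d_inv * yt) - wy @ Qi @ wy)  # y' P y (se2-free)
    nc = null.n_used - Wt.shape[1]
    sigma2 = y_perp_quad / nc  # REML residual scale at the null

    exclude = set(null.fixed_variant_ids)
    records: list[dict] = []
    v = geno.variants
    skipped = 0
    for start in range(0, geno.n_variants, _CHUNK):
        stop = min(start + _CHUNK, geno.n_variants)
        X, af = _impute_and_af(geno.dosages[rows, start:stop].copy())
        Xt = null.U.T @ X
        wx = Wd.T @ Xt                               # c x k
        xPy = Xt.T @ (d_inv * yt) - wx.T @ (Qi @ wy)
        xPx = np.einsum("ik,ik->k", Xt, d_inv[:, None] * Xt) - np.einsum(
            "ck,cd,dk->k", wx, Qi, wx
        )
        maf = np.minimum(af, 1.0 - af)
        for j in range(stop - start):
            col = start + j
            vid = v.at[col, "id"]
            if vid in exclude:
                continue
            if maf[j] < maf_min or not (maf[j] > 0):
                skipped += 1
                continue
            if xPx[j] <= 1e-12:
                skipped += 1
                continue
            beta = xPy[j] / xPx[j]
            se = float(np.sqrt(sigma2 / xPx[j]))
            chi2 = xPy[j] ** 2 / (xPx[j] * sigma2)
            p = max(float(stats.chi2.sf(chi2, df=1)), np.finfo(float).tiny)
            records.append(
                dict(
                    variant_id=vid, chrom=v.at[col, "chrom"], pos=int(v.at[col, "pos"]),
                    effect_allele=v.at[col, "alt"], other_allele=v.at[col, "ref"],
                    af=float(af[j]), beta=float(beta), se=se, p=p, n=null.n_used,
                )
            )
    if skipped:
        logger.info("%s: skipped %d variants (MAF/zero-variance)", null.trait, skipped)
    return SummaryStats(trait=null.trait, records=pd.DataFrame(records))


def conditional_scan(
    null: LMMNullModel,
    geno: GenotypeMatrix,
    fixed_variants: list[str],
    maf_min: float = 0.05,
) -> SummaryStats:
    """Rescan with lead-variant dosages fitted as fixed effects.

    The null is refitted with the conditioning dosages appended to the
    covariates (collinear ones dropped with a warning); the conditioned
    variants themselves are excluded from the output.
    """
    if not fixed_variants:
        return score_scan(null, geno, maf_min=maf_min)

    pos_of = {s: i for i, s in enumerate(geno.samples)}
    rows = np.array([pos_of[s] for s in null.sample_ids], dtype=int)

    cols = []
    kept_ids = []
    base = [np.ones(null.n_used)]
    if null.covariates is not None:
        base.append(null.covariates)
    current = np.column_stack(base)
    for vid in fixed_variants:
        j = geno.column_of(vid)
        x, _ = _impute_and_af(geno.dosages[rows, j][:, None])
        candidate = np.column_stack([current, x])
        if np.linalg.matrix_rank(candidate) <= current.shape[1]:
            logger.warning("conditioning variant %s is collinear; dropped", vid)
            continue
        current = candidate
        cols.append(x[:, 0])
        kept_ids.append(vid)

    cov = np.column_stack(cols) if cols else None
    if null.covariates is not None and cov is not None:
        cov = np.column_stack([null.covariates, cov])
    elif null.covariates is not None:
        cov = null.covariates

    # refit on the null's sample subset; build a GRM view over those samples
    sub = null.grm.subset(null.sample_ids)
    refit = fit_null(
        null.y, sub, covariates=cov, trait=null.trait,
        fixed_variant_ids=list(null.fixed_variant_ids) + kept_ids,
    )
    return score_scan(refit, geno, maf_min=maf_min)
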