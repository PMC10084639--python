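"""Variance-component estimation on the GRM eigenspectrum.

Single-trait genomic heritability is estimated by restricted maximum
likelihood (REML) for the model

    y = W alpha + u + e,   u ~ N(0, G sa2),   e ~ N(0, D se2)

with D = diag(1/w_i) for record weights w (identity when unweighted).
The weighted problem is whitened by D^{-1/2} and the GRM is
eigendecomposed once, reducing each likelihood evaluation to O(n);
the variance ratio lambda = sa2/se2 is then profiled by a 1-D search.

Multi-trait genetic/environmental covariances (Vg, Ve) for the
multivariate scan are estimated by an EM algorithm on the same
eigen-rotated data, with a PSD projection after every update.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

from .qc import GRM

logger = logging.getLogger(__name__)

_LOG_LAMBDA_RANGE = (-5.0, 5.0)


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    h2_se: float
    n_used: int
    converged: bool
    loglik: float = np.nan


@dataclass
class MultiTraitVC:
    traits: list[str]
    Vg: np.ndarray
    Ve: np.ndarray
    converged: bool
    n_iter: int
    loglik: float = np.nan
    degenerate: bool = False


# ---------------------------------------------------------------------------
# profile REML on the eigen-rotated single-trait model
# ---------------------------------------------------------------------------

def _neg_restricted_ll(log10_lam: float, yt: np.ndarray, Wt: np.ndarray,
                       S: np.ndarray) -> float:
    lam = 10.0 ** log10_lam
    h = lam * S + 1.0
    Wh = Wt / h[:, None]
    Q = Wt.T @ Wh
    alpha = np.linalg.solve(Q, Wh.T @ yt)
    r = yt - Wt @ alpha
    rss = float(np.sum(r * r / h))
    nc = len(yt) - Wt.shape[1]
    sign, logdetQ = np.linalg.slogdet(Q)
    if sign <= 0 or rss <= 0:
        return np.inf
    return 0.5 * (nc * np.log(rss / nc) + np.sum(np.log(h)) + logdetQ)


def profile_reml(yt: np.ndarray, Wt: np.ndarray, S: np.ndarray,
                 n_grid: int = 60) -> tuple[float, float, np.ndarray, float, bool]:
    """Profile the REML criterion over lambda = sa2/se2.

    Operates on eigen-rotated data (yt = U'y, Wt = U'W, S = GRM
    eigenvalues).  Returns (lambda, se2, alpha, restricted_ll, converged);
    lambda is clamped to 0 when the optimum sits at the lower search
    bound or the spectrum carries no information.
    """
    lo, hi = _LOG_LAMBDA_RANGE
    span = S.max() - S.min()
    if span < 1e-9 * max(S.max(), 1.0):
        # flat spectrum: sa2 and se2 are not separately identifiable
        lam, converged = 0.0, False
    else:
        grid = np.linspace(lo, hi, n_grid)
        vals = np.array([_neg_restricted_ll(g, yt, Wt, S) for g in grid])
        best = int(np.argmin(vals))
        a = grid[max(best - 1, 0)]
        b = grid[min(best + 1, n_grid - 1)]
        res = optimize.minimize_scalar(
            _neg_restricted_ll, bounds=(a, b), args=(yt, Wt, S), method="bounded",
            options={"xatol": 1e-8},
        )
        x = res.x if res.fun <= vals[best] else grid[best]
        lam = 10.0 ** float(x)
        converged = True
        if x <= lo + 1e-6:
            lam = 0.0
        boundary_val = _neg_restricted_ll(-12.0, yt, Wt, S)
        if boundary_val < _neg_restricted_ll(np.log10(max(lam, 1e-12)), yt, Wt, S):
            lam = 0.0

    h = lam * S + 1.0
    Wh = Wt / h[:, None]
    Q = Wt.T @ Wh
    alpha = np.linalg.solve(Q, Wh.T @ yt)
    r = yt - Wt @ alpha
    nc = len(yt) - Wt.shape[1]
    se2 = float(np.sum(r * r / h)) / nc
    ll = -_neg_restricted_ll(np.log10(max(lam, 1e-300)), yt, Wt, S) if lam > 0 else \
        -0.5 * (nc * np.log(se2) + float(np.linalg.slogdet(Wt.T @ Wt)[1]))
    return lam, se2, alpha, ll, converged


def _expected_information(S: np.ndarray, Wt: np.ndarray, sa2: float,
                          se2: float) -> np.ndarray:
    """Expected REML information for (sa2, se2) on the rotated model.

    Uses the diagonal structure V = sa2*S + se2*I and the low-rank form
    P = V^-1 - A Q^-1 A' with A = V^-1 Wt, so every trace costs O(n c^2).
    """
    v = sa2 * S + se2
    A = Wt / v[:, None]
    Q = Wt.T @ A
    Qi = np.linalg.inv(Q)
    r = np.einsum("ic,cd,id->i", A, Qi, A)  # diag(A Q^-1 A')

    def tr_PP(sa: np.ndarray, sb: np.ndarray) -> float:
        t1 = np.sum(sa * sb / v**2)
        t2 = np.sum(sa * sb / v * r)
        Ma = A.T @ (sa[:, None] * A)
        Mb = A.T @ (sb[:, None] * A)
        t3 = np.trace(Qi @ Ma @ Qi @ Mb)
        return t1 - 2.0 * t2 + t3

    ones = np.ones_like(S)
    return 0.5 * np.array(
        [[tr_PP(S, S), tr_PP(S, ones)], [tr_PP(S, ones), tr_PP(ones, ones)]]
    )


def reml_single(
    y: np.ndarray,
    grm: GRM,
    weights: np.ndarray | None = None,
    covariates: np.ndarray | None = None,
) -> VarianceComponents:
    """Weighted single-trait REML estimate of (sa2, se2) and h2.

    ``y`` is aligned to ``grm.sample_ids``; entries that are NaN are
    dropped (with the matching GRM rows/columns).  ``weights`` gives the
    per-record weight w_i entering the residual as D = diag(1/w_i).
    """
    y = np.asarray(y, dtype=float)
    if len(y) != grm.n_samples:
        raise ValueError("phenotype vector not aligned to the GRM")
    keep = ~np.isnan(y)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        keep &= ~np.isnan(weights)
    idx = np.flatnonzero(keep)
    yk = y[idx]
    n = len(yk)
    if n < 3:
        raise ValueError("need at least 3 non-missing records")
    K = grm.matrix[np.ix_(idx, idx)]
    W = np.ones((n, 1))
    if covariates is not None:
        W = np.column_stack([W, np.asarray(covariates, dtype=float)[idx]])

    # the centred GRM is not unit-diagonal (mean diag = average 2p(1-p)),
    # so the average genetic variance per individual is sa2 * tr(K)/n
    t_g = float(np.trace(K)) / n
    if t_g <= 0:
        raise ValueError("GRM has non-positive trace on the used samples")
    c_w = 1.0  # mean per-record residual variance per unit of sigma_e2
    if weights is not None:
        s = np.sqrt(weights[idx])
        yk = yk * s
        W = W * s[:, None]
        K = K * np.outer(s, s)
        c_w = float(np.mean(1.0 / weights[idx]))

    S, U = np.linalg.eigh(K)
    S = np.clip(S, 0.0, None)
    yt = U.T @ yk
    Wt = U.T @ W

    lam, se2, _, ll, converged = profile_reml(yt, Wt, S)
    floor = 1e-8 * max(np.var(yk), 1e-300)
    sa2 = max(lam * se2, 0.0)
    if sa2 < floor:
        sa2 = 0.0
    se2 = max(se2, floor)
    # report both components on the phenotype scale: genetic variance is
    # the fitted GRM coefficient times the mean GRM diagonal, and with
    # D = diag(1/w) the mean residual variance is se2 * mean(1/w)
    sa2_eff = sa2 * t_g
    se2_eff = se2 * c_w
    h2 = sa2_eff / (sa2_eff + se2_eff)

    try:
        info = _expected_information(S, Wt, sa2, se2)
        cov = np.linalg.inv(info)
        den = (t_g * sa2 + c_w * se2) ** 2
        grad = np.array([t_g * c_w * se2, -t_g * c_w * sa2]) / den
        h2_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    except np.linalg.LinAlgError:
        h2_se = np.nan
    return VarianceComponents(
        sigma_a2=sa2_eff, sigma_e2=se2_eff, h2=h2, h2_se=h2_se,
        n_used=n, converged=converged, loglik=ll,
    )


# ---------------------------------------------------------------------------
# multi-trait EM on the eigen-rotated model
# ---------------------------------------------------------------------------

def _mt_loglik(R: np.ndarray, S: np.ndarray, lam: np.ndarray, Ve: np.ndarray) -> float:
    # R: residuals in the (Vg, Ve)-diagonalising basis, per-sample variance
    # of component k is s_i lam_k + 1 (times Ve through the basis change)
    h = S[:, None] * lam[None, :] + 1.0
    sign, logdet_ve = np.linalg.slogdet(Ve)
    if sign <= 0:
        return -np.inf
    quad = np.sum(R * R / h)
    return -0.5 * (R.size * np.log(2 * np.pi) + len(S) * logdet_ve
                   + np.sum(np.log(h)) + quad)


def _psd_project(M: np.ndarray, floor: float = 0.0) -> np.ndarray:
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    return (vecs * np.clip(vals, floor, None)) @ vecs.T


def estimate_mt_vc(
    Y: np.ndarray,
    grm: GRM,
    traits: list[str] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> MultiTraitVC:
    """EM estimates of the d x d genetic and residual covariance matrices.

    ``Y`` must be complete-case (no NaN) and row-aligned to the GRM.  The
    model is vec(Y') ~ N(mu, G (x) Vg + I (x) Ve); after rotating samples
    into the GRM eigenbasis and traits into the basis that jointly
    diagonalises (Vg, Ve), the E-step is elementwise.  Updates are
    projected to the PSD cone; the likelihood is monitored and must not
    decrease.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be 2-D (samples x traits)")
    if np.isnan(Y).any():
        raise ValueError("estimate_mt_vc requires complete cases (no NaN)")
    n, d = Y.shape
    if n != grm.n_samples:
        raise ValueError("Y not aligned to the GRM")
    names = traits if traits is not None else [f"trait{i}" for i in range(d)]

    if d == 1:
        vc = reml_single(Y[:, 0], grm)
        # Vg/Ve are coefficients of G and I in the scan's covariance, so
        # undo the mean-diagonal normalisation of the reported variance
        t_g = float(np.trace(grm.matrix)) / n
        return MultiTraitVC(
            traits=names, Vg=np.array([[vc.sigma_a2 / t_g]]),
            Ve=np.array([[vc.sigma_e2]]),
            converged=vc.converged, n_iter=0, loglik=vc.loglik,
        )

    S, U = np.linalg.eigh(grm.matrix)
    S = np.clip(S, 0.0, None)
    Yt = U.T @ Y
    wt = U.T @ np.ones(n)

    C = np.cov(Y, rowvar=False)
    scale = np.trace(C) / d
    Vg = 0.5 * C + 1e-4 * scale * np.eye(d)
    Ve = 0.5 * C + 1e-4 * scale * np.eye(d)
    ve_floor = 1e-8 * scale
    degenerate = np.linalg.matrix_rank(C, tol=1e-10 * scale) < d
    if degenerate:
        logger.warning("phenotype matrix is rank-deficient; Vg/Ve estimates degenerate")

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # basis that diagonalises Vg against Ve: Phi' Ve Phi = I
        lam, Phi = linalg.eigh(Vg, Ve + ve_floor * np.eye(d))
        lam = np.clip(lam, 0.0, None)
        Ys = Yt @ Phi                       # transformed traits
        h = S[:, None] * lam[None, :] + 1.0

        # GLS intercept, separable per transformed trait
        wh = wt[:, None] / h
        mu_s = np.sum(wh * Ys, axis=0) / np.sum(wh * wt[:, None], axis=0)
        R = Ys - np.outer(wt, mu_s)

        ll = _mt_loglik(R, S, lam, Ve + ve_floor * np.eye(d))
        if ll < ll_old - 1e-6 * abs(ll_old):
            logger.debug("EM likelihood decreased at iteration %d", it)
        if np.isfinite(ll) and np.isfinite(ll_old):
            if abs(ll - ll_old) < tol * (abs(ll_old) + 1.0):
                converged = True
                ll_old = ll
                break
        ll_old = ll

        # E-step (elementwise in the transformed basis)
        g = (S[:, None] * lam[None, :]) / h     # shrinkage factor
        M = g * R                               # posterior mean of u*
        V = S[:, None] * lam[None, :] / h       # posterior variance of u*

        # M-step, conjugated back: u = Phi^{-T} u*, Phi^{-T} = Ve Phi
        B = (Ve + ve_floor * np.eye(d)) @ Phi
        pos = S > 1e-12 * max(S.max(), 1.0)
        n_pos = int(np.sum(pos))
        Ms, Vs, Ss = M[pos], V[pos], S[pos]
        Eu = (Ms / Ss[:, None]).T @ Ms + np.diag(np.sum(Vs / Ss[:, None], axis=0))
        Vg_new = B @ (Eu / n_pos) @ B.T
        Res = R - M
        Ee = Res.T @ Res + np.diag(np.sum(V, axis=0))
        Ve_new = B @ (Ee / n) @ B.T

        Vg = _psd_project(Vg_new)
        Ve = _psd_project(Ve_new, floor=ve_floor)

    return MultiTraitVC(
        traits=names, Vg=_psd_project(Vg), Ve=_psd_project(Ve, floor=ve_floor),
        converged=converged, n_iter=it, loglik=ll_old, degenerate=degenerate,
    )
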