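"""Multi-trait meta-analysis of single-trait summary statistics (metaGWAS).

Per-trait signed t-values (beta/se) are assembled into an m x d matrix
over the variants common to all traits, alleles harmonised to the first
trait's effect allele.  The d x d correlation matrix V of the t-values
over markers absorbs both the genetic correlation between traits and
any sample overlap between the contributing scans; the per-variant
multi-trait statistic is

    chi2_j = t_j' V^{-1} t_j

referred to a chi-square distribution.  Both d and d-1 degrees of
freedom are supported: the source methodology displays the statistic
with d df, while published applications commonly evaluate it with d-1,
and the two conventions give materially different tails for small d.
Neither is silently preferred -- the caller picks ``df_mode``.

Because the t-values of each trait may come from scans on different
(overlapping) subsets of animals, per-cell sample counts are carried
along; nothing in the assembly requires equal n across traits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SummaryStats

logger = logging.getLogger(__name__)

VARIANT_KEY = ["chrom", "pos", "variant_id", "effect_allele", "other_allele"]


@dataclass
class TMatrix:
    """Signed t-values per variant (rows) and trait (columns)."""

    variants: pd.DataFrame          # chrom, pos, variant_id, effect/other allele
    traits: list[str]
    t: np.ndarray                   # m x d
    source_n: np.ndarray            # m x d per-cell sample counts
    n_dropped_allele_mismatch: int = 0

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_traits(self) -> int:
        return len(self.traits)


@dataclass
class VMatrix:
    traits: list[str]
    V: np.ndarray
    estimation_mode: str            # "all_markers" | "null_markers"
    condition_number: float
    n_markers_used: int = 0


@dataclass
class MetaResult:
    """Per-variant multi-trait chi-square, df and p."""

    records: pd.DataFrame           # variant columns + chi2, df, p
    df_mode: str

    @property
    def n_variants(self) -> int:
        return len(self.records)


def assemble_t(stats_list: list[SummaryStats]) -> TMatrix:
    """Assemble per-trait t = beta/se into one matrix over shared variants.

    Variants are restricted to the intersection across traits (a variant
    missing from any trait would otherwise need a fabricated zero).  The
    first trait defines the reference effect allele per variant; other
    traits' t-values flip sign when their effect allele is the reference
    variant's other allele, and variants whose allele pair cannot be
    reconciled by a swap are dropped and counted.
    """
    if len(stats_list) < 2:
        raise ValueError("meta-analysis needs at least two traits")
    traits = [s.trait for s in stats_list]
    if len(set(traits)) != len(traits):
        raise ValueError("duplicate trait names in summary statistics")

    ref = stats_list[0].records.set_index("variant_id")
    common = set(ref.index)
    for s in stats_list[1:]:
        common &= set(s.records["variant_id"])
    ids = [vid for vid in ref.index if vid in common]   # keep (chrom,pos) order

    m, d = len(ids), len(traits)
    t = np.empty((m, d))
    n = np.empty((m, d), dtype=int)
    drop = np.zeros(m, dtype=bool)
    ref_sub = ref.loc[ids]
    ref_ea = ref_sub["effect_allele"].to_numpy()
    ref_oa = ref_sub["other_allele"].to_numpy()

    for k, s in enumerate(stats_list):
        rec = s.records.set_index("variant_id").loc[ids]
        tk = (rec["beta"] / rec["se"]).to_numpy()
        ea = rec["effect_allele"].to_numpy()
        oa = rec["other_allele"].to_numpy()
        same = (ea == ref_ea) & (oa == ref_oa)
        swapped = (ea == ref_oa) & (oa == ref_ea) & ~same
        bad = ~(same | swapped)
        tk = np.where(swapped, -tk, tk)
        drop |= bad
        t[:, k] = tk
        n[:, k] = rec["n"].to_numpy()

    if drop.any():
        logger.warning("dropping %d variants with irreconcilable alleles", int(drop.sum()))
    keep = ~drop
    variants = pd.DataFrame(
        {
            "chrom": ref_sub["chrom"].to_numpy()[keep],
            "pos": ref_sub["pos"].to_numpy()[keep],
            "variant_id": np.asarray(ids)[keep],
            "effect_allele": ref_ea[keep],
            "other_allele": ref_oa[keep],
        }
    )
    return TMatrix(
        variants=variants, traits=traits, t=t[keep], source_n=n[keep],
        n_dropped_allele_mismatch=int(drop.sum()),
    )


def estimate_v(
    tm: TMatrix,
    mode: str = "all_markers",
    null_t_max: float = 2.0,
    ridge: float | None = None,
    condition_cap: float = 1e8,
) -> VMatrix:
    """Correlation matrix of the t-columns over markers.

    ``null_markers`` mode restricts to variants with all per-trait
    |t| < ``null_t_max`` before correlating, guarding V against inflation
    by strong QTL.  A near-singular V raises unless an explicit ``ridge``
    is supplied (added to the diagonal).
    """
    if mode not in ("all_markers", "null_markers"):
        raise ValueError(f"unknown V estimation mode {mode!r}")
    d = tm.n_traits
    if d == 1:
        return VMatrix(traits=list(tm.traits), V=np.eye(1), estimation_mode=mode,
                       condition_number=1.0, n_markers_used=tm.n_variants)
    if tm.n_variants < 10 * d:
        raise ValueError(
            f"need at least {10 * d} markers to estimate a {d} x {d} V, "
            f"have {tm.n_variants}"
        )
    t = tm.t
    if mode == "null_markers":
        sel = np.all(np.abs(t) < null_t_max, axis=1)
        if sel.sum() < 10 * d:
            logger.warning(
                "only %d null markers for V; falling back to all markers", int(sel.sum())
            )
        else:
            t = t[sel]
    V = np.corrcoef(t, rowvar=False)
    if ridge:
        V = V + ridge * np.eye(d)
        V = V / np.sqrt(np.outer(np.diag(V), np.diag(V)))
    cond = float(np.linalg.cond(V))
    if cond > condition_cap:
        raise ValueError(
            f"V is near-singular (condition number {cond:.3g}); prune "
            "duplicated/collinear traits or enable a diagonal ridge"
        )
    return VMatrix(traits=list(tm.traits), V=V, estimation_mode=mode,
                   condition_number=cond, n_markers_used=len(t))


def meta_chi2(tm: TMatrix, v: VMatrix, df_mode: str = "d_minus_1") -> MetaResult:
    """Per-variant chi2 = t' V^{-1} t with p from chi-square(df).

    ``df_mode`` is ``"d"`` or ``"d_minus_1"``; with a single trait the df
    is 1 under either convention.
    """
    if df_mode not in ("d", "d_minus_1"):
        raise ValueError(f"unknown df_mode {df_mode!r}")
    if list(v.traits) != list(tm.traits):
        raise ValueError("V matrix traits do not match the t-matrix")
    d = tm.n_traits
    sol = np.linalg.solve(v.V, tm.t.T)            # d x m
    chi2 = np.einsum("md,dm->m", tm.t, sol)
    chi2 = np.clip(chi2, 0.0, None)
    df = d if (df_mode == "d" or d == 1) else d - 1
    p = np.maximum(stats.chi2.sf(chi2, df=df), np.finfo(float).tiny)
    records = tm.variants.copy()
    records["chi2"] = chi2
    records["df"] = df
    records["p"] = p
    return MetaResult(records=records, df_mode=df_mode)
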