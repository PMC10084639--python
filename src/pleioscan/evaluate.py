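"""Significance thresholds, calibration diagnostics, analytic FDR,
cross-method comparison and imputation-accuracy metrics.

The analytic false discovery rate follows the summary-statistic
meta-analysis literature:

    FDR = P (1 - A/T) / [ (A/T) (1 - P) ]

with P the significance threshold, A the number of significant variants
and T the number of tests; it is reported in percent.  The genomic
inflation factor is the median observed chi-square(1 df) statistic over
its null median (~0.4549).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix
from .finemap import QTLRegion, call_qtl

logger = logging.getLogger(__name__)

CHI2_1DF_MEDIAN = float(stats.chi2.ppf(0.5, df=1))   # 0.45493642...


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return alpha / n_tests


def fdr_analytic(P: float, A: int, T: int) -> float:
    """Analytic FDR in percent; NaN when nothing is significant (A = 0)."""
    if not (0.0 < P < 1.0):
        raise ValueError("P must lie strictly between 0 and 1")
    if A < 0 or T <= 0 or A > T:
        raise ValueError("need 0 <= A <= T with T > 0")
    if A == 0:
        return np.nan
    frac = A / T
    return 100.0 * P * (1.0 - frac) / (frac * (1.0 - P))


def inflation_factor(pvalues: np.ndarray) -> float:
    """Genomic inflation: median chi2(1) quantile of the p-values over the
    null chi2(1) median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[~np.isnan(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable estimate")
    tiny = np.finfo(float).tiny
    if np.any(p <= 0):
        logger.warning("clamping %d non-positive p-values", int(np.sum(p <= 0)))
        p = np.maximum(p, tiny)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


# ---------------------------------------------------------------------------
# cross-method comparison
# ---------------------------------------------------------------------------

@dataclass
class MethodComparison:
    methods: list[str]
    significant: dict[str, set[str]]
    overlap: dict[frozenset, int]            # exact overlap decomposition
    qtl: dict[str, list[QTLRegion]] = field(default_factory=dict)
    lead_log10p: pd.DataFrame | None = None   # paired -log10 p at shared variants
    lead_correlation: float = np.nan

    def n_significant(self, method: str) -> int:
        return len(self.significant[method])


def compare_methods(
    results: dict[str, pd.DataFrame],
    threshold: float | dict[str, float],
    call_qtl_regions: bool = True,
    merge_adjacent: bool = True,
) -> MethodComparison:
    """Overlap decomposition of significant variants across methods.

    ``results`` maps a method name to a per-variant table with columns
    ``variant_id, chrom, pos, p``.  All tables must share a variant
    universe (pairwise non-empty intersection).  The exact decomposition
    counts, for every non-empty subset of methods, the variants
    significant in exactly that subset; paired -log10 p at the union of
    significant variants feeds QQ-style comparisons, with their Pearson
    correlation reported.
    """
    if len(results) < 2:
        raise ValueError("need at least two methods to compare")
    methods = list(results)
    universes = {m: set(df["variant_id"]) for m, df in results.items()}
    for a, b in combinations(methods, 2):
        if not (universes[a] & universes[b]):
            raise ValueError(f"methods {a!r} and {b!r} share no variants")

    def thr(m: str) -> float:
        return threshold[m] if isinstance(threshold, dict) else threshold

    significant = {
        m: set(df.loc[df["p"] < thr(m), "variant_id"]) for m, df in results.items()
    }
    union = set().union(*significant.values())
    overlap: dict[frozenset, int] = {}
    for r in range(1, len(methods) + 1):
        for subset in combinations(methods, r):
            key = frozenset(subset)
            exact = set(union)
            for m in methods:
                exact = exact & significant[m] if m in key else exact - significant[m]
            overlap[key] = len(exact)

    qtl = {}
    if call_qtl_regions:
        for m, df in results.items():
            qtl[m] = call_qtl(df, thr(m), merge_adjacent=merge_adjacent)

    lead_df = None
    corr = np.nan
    if union:
        cols = {}
        for m, df in results.items():
            sub = df.set_index("variant_id")["p"]
            cols[m] = -np.log10(sub.reindex(sorted(union)).to_numpy(dtype=float))
        lead_df = pd.DataFrame(cols, index=sorted(union))
        complete = lead_df.dropna()
        if len(complete) >= 2 and len(methods) == 2:
            corr = float(np.corrcoef(complete.iloc[:, 0], complete.iloc[:, 1])[0, 1])
        elif len(complete) >= 2:
            corr = float(
                np.corrcoef(complete.T.to_numpy())[np.triu_indices(len(methods), 1)].mean()
            )
    return MethodComparison(
        methods=methods, significant=significant, overlap=overlap, qtl=qtl,
        lead_log10p=lead_df, lead_correlation=corr,
    )


# ---------------------------------------------------------------------------
# imputation accuracy
# ---------------------------------------------------------------------------

@dataclass
class ImputationAccuracy:
    bins: pd.DataFrame          # maf_lo, maf_hi, concordance, dosage_r2, n_genotypes
    overall_concordance: float
    overall_r2: float
    n_genotypes: int


def _best_guess(dosage: np.ndarray) -> np.ndarray:
    """Round dosages to hard calls; ties (0.5, 1.5) go to the heterozygote."""
    g = np.rint(dosage)
    ties = np.isclose(np.abs(dosage - np.trunc(dosage)), 0.5)
    g = np.where(ties, 1.0, g)
    return np.clip(g, 0, 2)


def imputation_accuracy(
    truth: GenotypeMatrix,
    imputed: GenotypeMatrix,
    maf_bins: list[float] | np.ndarray = (0.0, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5),
) -> ImputationAccuracy:
    """Concordance ratio and dosage r2 of imputed against true genotypes.

    CR is the share of entries whose best-guess hard call matches the
    truth; dosage r2 is the squared Pearson correlation between imputed
    dosage and true dosage.  Both are reported overall and in bins of the
    truth-panel MAF; entirely-missing bins report NaN.
    """
    if truth.samples != imputed.samples:
        raise ValueError("truth and imputed panels must share samples (in order)")
    if not truth.variants["id"].equals(imputed.variants["id"]):
        raise ValueError("truth and imputed panels must share variants (in order)")

    maf = truth.maf()
    edges = np.asarray(maf_bins, dtype=float)
    t = truth.dosages
    x = imputed.dosages
    ok = ~(np.isnan(t) | np.isnan(x))

    def score(mask_cols: np.ndarray) -> tuple[float, float, int]:
        sel = ok[:, mask_cols]
        tv = t[:, mask_cols][sel]
        xv = x[:, mask_cols][sel]
        if tv.size == 0:
            return np.nan, np.nan, 0
        cr = float(np.mean(_best_guess(xv) == np.rint(tv)))
        if tv.std() == 0 or xv.std() == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(tv, xv)[0, 1] ** 2)
        return cr, r2, int(tv.size)

    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        in_bin = (maf > lo) & (maf <= hi) if lo > 0 else (maf >= lo) & (maf <= hi)
        cr, r2, n = score(np.flatnonzero(in_bin))
        rows.append(dict(maf_lo=lo, maf_hi=hi, concordance=cr, dosage_r2=r2,
                         n_genotypes=n))
    cr_all, r2_all, n_all = score(np.arange(truth.n_variants))
    return ImputationAccuracy(
        bins=pd.DataFrame(rows), overall_concordance=cr_all,
        overall_r2=r2_all, n_genotypes=n_all,
    )
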