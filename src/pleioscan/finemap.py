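"""QTL calling, lead variants, LD neighbourhoods and variance explained.

A QTL is a run of 1-Mb genome windows (fixed grid anchored at bp 1) each
containing at least one variant below the significance threshold;
adjacent significant windows merge into a single region, which is how a
QTL can span several megabases under a 1-Mb window definition.  The lead
variant is the smallest p in the region (ties broken by position, then
id).

The share of phenotypic variance a lead variant explains is
2p(1-p)beta^2 / sigma^2 with p its minor allele frequency and sigma^2
the phenotypic variance; to avoid double-counting overlapping signals
the regression coefficients of all leads are estimated jointly in one
multiple regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

WINDOW_BP = 1_000_000


@dataclass
class QTLRegion:
    chrom: str
    start_bp: int                   # min position of significant variants
    stop_bp: int                    # max position of significant variants
    windows: list[int]              # contiguous 1-Mb window indices
    lead_variant: str
    lead_p: float
    n_significant: int
    variance_explained_pct: dict[str, float] = field(default_factory=dict)

    @property
    def traits_affected(self) -> list[str]:
        return sorted(self.variance_explained_pct)


def call_qtl(
    results: pd.DataFrame,
    threshold: float,
    merge_adjacent: bool = True,
) -> list[QTLRegion]:
    """Group significant variants into 1-Mb-window QTL regions.

    ``results`` needs columns ``variant_id, chrom, pos, p`` sorted by
    (chrom, pos).  A variant at position pos belongs to window
    floor((pos - 1) / 1e6) of its chromosome; each significant window is
    a QTL and, with ``merge_adjacent``, runs of consecutive significant
    windows merge into one region.
    """
    needed = {"variant_id", "chrom", "pos", "p"}
    if not needed.issubset(results.columns):
        raise ValueError(f"results must have columns {sorted(needed)}")
    sig = results.loc[results["p"] < threshold].copy()
    if sig.empty:
        return []
    sig["window"] = (sig["pos"].astype(int) - 1) // WINDOW_BP

    regions: list[QTLRegion] = []
    for chrom, sub in sig.groupby("chrom", sort=False):
        sub = sub.sort_values(["pos", "variant_id"], kind="mergesort")
        windows = np.sort(sub["window"].unique())
        if merge_adjacent:
            breaks = np.flatnonzero(np.diff(windows) > 1)
            runs = np.split(windows, breaks + 1)
        else:
            runs = [np.array([w]) for w in windows]
        for run in runs:
            block = sub[sub["window"].isin(run)]
            lead = block.sort_values(
                ["p", "pos", "variant_id"], kind="mergesort"
            ).iloc[0]
            regions.append(
                QTLRegion(
                    chrom=chrom,
                    start_bp=int(block["pos"].min()),
                    stop_bp=int(block["pos"].max()),
                    windows=[int(w) for w in run],
                    lead_variant=str(lead["variant_id"]),
                    lead_p=float(lead["p"]),
                    n_significant=len(block),
                )
            )
    return regions


def ld_r2(
    geno: GenotypeMatrix, anchor: str, others: list[str]
) -> dict[str, float]:
    """Squared Pearson correlation of dosages between anchor and each other
    variant, over samples non-missing at both; NaN when either variant has
    zero variance on the shared samples."""
    a = geno.dosages[:, geno.column_of(anchor)]
    out: dict[str, float] = {}
    for vid in others:
        b = geno.dosages[:, geno.column_of(vid)]
        ok = ~(np.isnan(a) | np.isnan(b))
        if ok.sum() < 2:
            out[vid] = np.nan
            continue
        x, y = a[ok], b[ok]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            out[vid] = np.nan
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        out[vid] = r * r
    return out


def variance_explained(
    y: np.ndarray,
    geno: GenotypeMatrix,
    lead_variants: list[str],
    collinear_r2: float = 0.99,
) -> dict[str, float]:
    """Percent of phenotypic variance explained per lead variant.

    All lead dosages enter one multiple regression (with intercept) so
    that overlapping signals are not double-counted; per lead the share
    is 2p(1-p)beta^2/sigma^2 * 100 with p the lead's minor allele
    frequency and sigma^2 the variance of y.  Of a pair of near-duplicate
    leads (pairwise r2 above ``collinear_r2``) the later one is dropped.
    """
    y = np.asarray(y, dtype=float)
    keep_samples = ~np.isnan(y)
    yk = y[keep_samples]
    if yk.size < 3 or yk.var(ddof=1) == 0:
        raise ValueError("phenotype has no usable variance")

    kept: list[str] = []
    cols: list[np.ndarray] = []
    for vid in lead_variants:
        x = geno.dosages[keep_samples, geno.column_of(vid)]
        mean = np.nanmean(x)
        x = np.where(np.isnan(x), mean, x)
        drop = False
        for prev_id, prev in zip(kept, cols):
            if prev.std() > 0 and x.std() > 0:
                r = np.corrcoef(prev, x)[0, 1]
                if r * r > collinear_r2:
                    logger.warning(
                        "lead %s collinear with %s (r2=%.3f); dropped",
                        vid, prev_id, r * r,
                    )
                    drop = True
                    break
        if not drop:
            kept.append(vid)
            cols.append(x)

    out: dict[str, float] = {}
    if not kept:
        return out
    X = np.column_stack([np.ones(len(yk))] + cols)
    beta, *_ = np.linalg.lstsq(X, yk, rcond=None)
    sigma2 = yk.var(ddof=1)
    for i, vid in enumerate(kept):
        p = cols[i].mean() / 2.0
        p = min(p, 1.0 - p)
        out[vid] = float(100.0 * 2.0 * p * (1.0 - p) * beta[i + 1] ** 2 / sigma2)
    for vid in lead_variants:
        out.setdefault(vid, np.nan)   # dropped collinear leads
    return out


def qtl_table(regions: list[QTLRegion], geno: GenotypeMatrix | None = None) -> pd.DataFrame:
    """Tabulate QTL regions (one row each) for reporting or TSV export."""
    rows = []
    for i, r in enumerate(regions, start=1):
        row = dict(
            qtl=i, chrom=r.chrom, start_bp=r.start_bp, stop_bp=r.stop_bp,
            lead_variant=r.lead_variant, lead_p=r.lead_p,
            n_significant=r.n_significant,
            n_traits=len(r.variance_explained_pct),
        )
        if geno is not None:
            col = geno.column_of(r.lead_variant)
            af = np.nanmean(geno.dosages[:, col]) / 2.0
            row["lead_maf"] = float(min(af, 1.0 - af))
            row["alleles"] = f"{geno.variants.at[col, 'ref']}|{geno.variants.at[col, 'alt']}"
        rows.append(row)
    return pd.DataFrame(rows)


def regions_to_bed(regions: list[QTLRegion]) -> pd.DataFrame:
    """QTL regions as BED intervals (0-based half-open)."""
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start_bp - 1 for r in regions],
            "end": [r.stop_bp for r in regions],
            "name": [r.lead_variant for r in regions],
        }
    )
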