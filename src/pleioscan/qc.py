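"""Genotype merging, quality control, GRM construction and GRM PCA.

The QC cascade mirrors standard array practice: per-sample call rate,
per-variant call rate, an exact Hardy-Weinberg test, then a minor-allele
frequency cut (plus an imputation-accuracy cut for imputed panels).
Removals are attributed to the first failing filter so the report's
counts add up.

The genomic relationship matrix uses the centred construction
G = Xc Xc' / m, where Xc holds per-variant mean-centred dosages and
missing entries are centred to zero (mean imputation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class QCReport:
    n_input_variants: int
    n_removed_by: dict[str, int] = field(default_factory=dict)
    n_output_variants: int = 0
    n_removed_samples: int = 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        parts = [f"variants in: {self.n_input_variants}"]
        parts += [f"removed by {k}: {v}" for k, v in self.n_removed_by.items()]
        parts += [
            f"variants out: {self.n_output_variants}",
            f"samples removed: {self.n_removed_samples}",
        ]
        return "; ".join(parts)


@dataclass
class GRM:
    """Centred genomic relationship matrix over a fixed sample set."""

    sample_ids: list[str]
    matrix: np.ndarray
    n_variants_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ValueError(f"GRM must be {n} x {n}, got {self.matrix.shape}")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset(self, samples: list[str]) -> "GRM":
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([lookup[s] for s in samples], dtype=int)
        return GRM(list(samples), self.matrix[np.ix_(idx, idx)], self.n_variants_used)


# ---------------------------------------------------------------------------
# panel merging
# ---------------------------------------------------------------------------

def _chrom_sort_key(chrom: str):
    try:
        return (0, int(chrom), "")
    except (TypeError, ValueError):
        return (1, 0, str(chrom))


def merge_panels(panels: list[GenotypeMatrix]) -> GenotypeMatrix:
    """Merge genotype panels on physical position.

    Variants are matched on (chromosome, position).  Identical allele
    pairs merge directly; a ref/alt swap flips the dosage (x -> 2 - x);
    any other allele conflict, and positions carrying more than one
    variant inside a single panel, are dropped as non-unique.  The output
    holds the union of samples with genotypes missing wherever a sample's
    panels did not type the variant.
    """
    if not panels:
        raise ValueError("need at least one panel")

    # first panel to mention a position defines the reference allele pair
    alleles: dict[tuple[str, int], tuple[str, str]] = {}
    bad: set[tuple[str, int]] = set()
    for panel in panels:
        v = panel.variants
        dup = v.duplicated(subset=["chrom", "pos"], keep=False)
        for key in zip(v.loc[dup, "chrom"], v.loc[dup, "pos"]):
            bad.add(key)
        for chrom, pos, ref, alt in zip(v["chrom"], v["pos"], v["ref"], v["alt"]):
            key = (chrom, int(pos))
            if key in bad:
                continue
            pair = (ref, alt)
            if key not in alleles:
                alleles[key] = pair
            elif pair != alleles[key] and pair != alleles[key][::-1]:
                bad.add(key)
    if bad:
        logger.warning("dropping %d non-unique/conflicting positions", len(bad))
        for key in bad:
            alleles.pop(key, None)

    keys = sorted(alleles, key=lambda k: (_chrom_sort_key(k[0]), k[1]))
    col = {k: j for j, k in enumerate(keys)}

    samples: list[str] = []
    seen: dict[str, int] = {}
    for panel in panels:
        for s in panel.samples:
            if s not in seen:
                seen[s] = len(samples)
                samples.append(s)

    out = np.full((len(samples), len(keys)), np.nan)
    for panel in panels:
        rows = np.array([seen[s] for s in panel.samples], dtype=int)
        v = panel.variants
        for j, (chrom, pos, ref, alt) in enumerate(
            zip(v["chrom"], v["pos"], v["ref"], v["alt"])
        ):
            key = (chrom, int(pos))
            if key not in col:
                continue
            x = panel.dosages[:, j]
            if (ref, alt) == alleles[key][::-1] and (ref, alt) != alleles[key]:
                x = 2.0 - x
            dest = out[rows, col[key]]
            fill = np.isnan(dest)
            dest[fill] = x[fill]
            out[rows, col[key]] = dest

    variants = pd.DataFrame(
        {
            "chrom": [k[0] for k in keys],
            "pos": [k[1] for k in keys],
            "id": [f"{k[0]}_{k[1]}" for k in keys],
            "ref": [alleles[k][0] for k in keys],
            "alt": [alleles[k][1] for k in keys],
        }
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosages=out)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test (probability ordering).

    Enumerates all heterozygote counts compatible with the observed
    allele counts and returns the summed probability of tables no more
    probable than the observed one.  No mid-p correction.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("no genotypes")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0  # monomorphic: a single possible table

    # heterozygote counts share the parity of the rare-allele count
    het_obs = n_Aa
    mid = n_rare * (2 * n - n_rare) / (2.0 * n - 1.0)
    het_mode = int(mid)
    if het_mode % 2 != n_rare % 2:
        het_mode += 1
    het_mode = min(het_mode, n_rare)

    # unnormalised probabilities by the standard two-sided recurrence
    probs = {het_mode: 1.0}
    het = het_mode
    while het >= 2:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        probs[het - 2] = probs[het] * het * (het - 1.0) / (
            4.0 * (rare_hom + 1.0) * (common_hom + 1.0)
        )
        het -= 2
    het = het_mode
    while het <= n_rare - 2:
        rare_hom = (n_rare - het) // 2
        common_hom = n - het - rare_hom
        probs[het + 2] = probs[het] * 4.0 * rare_hom * common_hom / (
            (het + 2.0) * (het + 1.0)
        )
        het += 2

    total = sum(probs.values())
    p_obs = probs[het_obs]
    p = sum(v for v in probs.values() if v <= p_obs * (1.0 + 1e-12)) / total
    return min(1.0, p)


def hwe_pvalues(geno: GenotypeMatrix) -> np.ndarray:
    """Exact HWE p-value per variant, computed on rounded hard calls."""
    out = np.empty(geno.n_variants)
    d = geno.dosages
    for j in range(geno.n_variants):
        x = d[:, j]
        x = x[~np.isnan(x)]
        g = np.rint(x).astype(int)
        n_aa = int(np.sum(g == 0))
        n_het = int(np.sum(g == 1))
        n_AA = int(np.sum(g == 2))
        out[j] = hwe_exact_p(n_AA, n_het, n_aa) if (n_aa + n_het + n_AA) else np.nan
    return out


# ---------------------------------------------------------------------------
# QC cascade
# ---------------------------------------------------------------------------

#: threshold presets: (maf_min, hwe_p_min, var_call_min, sample_call_min, dr2_min)
PRESETS = {
    "array": dict(maf_min=0.005, hwe_p_min=1e-5, var_call_min=0.8, sample_call_min=0.8),
    "gwas": dict(maf_min=0.05, hwe_p_min=1e-5, var_call_min=0.8, sample_call_min=0.8),
    "post_imputation": dict(
        maf_min=0.05, hwe_p_min=1e-8, var_call_min=0.0, sample_call_min=0.0, dr2_min=0.6
    ),
}


def qc_filter(
    geno: GenotypeMatrix,
    maf_min: float = 0.0,
    hwe_p_min: float = 0.0,
    var_call_min: float = 0.0,
    sample_call_min: float = 0.0,
    dr2_min: float | None = None,
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the QC cascade and return the filtered matrix with a report.

    Filter order is fixed: sample call rate, variant call rate, HWE, MAF,
    then imputation DR2 when requested; each removed variant is counted
    under the first filter that fails it.  MAF is computed on non-missing
    dosages of the retained samples.
    """
    report = QCReport(n_input_variants=geno.n_variants)

    keep_samples = geno.call_rate_samples() >= sample_call_min
    report.n_removed_samples = int(np.sum(~keep_samples))
    g = geno.subset_samples(keep_samples) if report.n_removed_samples else geno

    alive = np.ones(g.n_variants, dtype=bool)

    fail = g.call_rate_variants() < var_call_min
    report.n_removed_by["call_rate"] = int(np.sum(fail & alive))
    alive &= ~fail

    if hwe_p_min > 0:
        with np.errstate(invalid="ignore"):
            hwe = hwe_pvalues(g)
        fail = ~(hwe >= hwe_p_min)
    else:
        fail = np.zeros(g.n_variants, dtype=bool)
    report.n_removed_by["hwe"] = int(np.sum(fail & alive))
    alive &= ~fail

    with np.errstate(invalid="ignore"):
        maf = g.maf()
    fail = ~(maf >= maf_min) if maf_min > 0 else np.isnan(maf)
    report.n_removed_by["maf"] = int(np.sum(fail & alive))
    alive &= ~fail

    if dr2_min is not None and "dr2" in g.variants.columns:
        dr2 = g.variants["dr2"].to_numpy(dtype=float)
        fail = ~(dr2 >= dr2_min)
        report.n_removed_by["dr2"] = int(np.sum(fail & alive))
        alive &= ~fail

    out = g.subset_variants(alive)
    report.n_output_variants = out.n_variants
    if out.n_variants == 0:
        logger.warning("QC removed every variant")
    return out, report


# ---------------------------------------------------------------------------
# GRM and its PCA
# ---------------------------------------------------------------------------

def compute_grm_centered(geno: GenotypeMatrix) -> GRM:
    """Centred GRM: G = Xc Xc' / m with missing dosages centred to zero.

    Variants that are entirely missing carry no information and are
    excluded from m.
    """
    d = geno.dosages
    informative = ~np.all(np.isnan(d), axis=0)
    if not informative.all():
        logger.warning("excluding %d all-missing variants from the GRM",
                       int(np.sum(~informative)))
    d = d[:, informative]
    if d.shape[1] == 0:
        raise ValueError("no informative variants for the GRM")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(d, axis=0)
    Xc = d - mean
    Xc[np.isnan(Xc)] = 0.0
    G = (Xc @ Xc.T) / Xc.shape[1]
    return GRM(sample_ids=list(geno.samples), matrix=G, n_variants_used=Xc.shape[1])


def pca_grm(grm: GRM, k: int = 10) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k principal components of the GRM.

    Returns per-sample coordinates (eigenvector * sqrt(eigenvalue)) and
    the fraction of total variance captured by each component
    (eigenvalue / trace).
    """
    n = grm.n_samples
    if k > n:
        raise ValueError(f"k = {k} exceeds the number of samples ({n})")
    vals, vecs = np.linalg.eigh(grm.matrix)
    order = np.argsort(vals)[::-1][:k]
    vals_k = np.clip(vals[order], 0.0, None)
    coords = vecs[:, order] * np.sqrt(vals_k)
    trace = max(np.sum(np.clip(vals, 0.0, None)), np.finfo(float).tiny)
    fractions = vals_k / trace
    df = pd.DataFrame(coords, columns=[f"PC{i + 1}" for i in range(len(order))])
    df.insert(0, "sample_id", grm.sample_ids)
    return df, fractions
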