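"""Synthetic genotype/phenotype cohort generation with known truth.

The generator emulates a livestock GWAS cohort built on deregressed
breeding values (drEBV): a few thousand animals genotyped at tens of
thousands of array SNPs with MAF > 5%, up to 24 traits organised into
trait groups, per-trait heritabilities spanning roughly 0.04-0.67,
modest within-group genetic correlations, a handful of pleiotropic QTL
each explaining ~0.2-11% of a trait's variance, per-trait missingness up
to ~37% of animals, and reliability-derived record weights.

Linkage disequilibrium is produced by a founder-haplotype block model:
variants inside a block segregate on a small set of founder haplotypes
(default 8), so neighbouring variants are correlated while blocks are
independent.  This is deliberately cheap and fully controlled -- enough
LD structure for lead-SNP/neighbour fine-mapping, without a coalescent
simulator.

Phenotypes are built as

    y_t = sum_q x_q * beta_qt  +  u_t  +  e_t

with QTL effects sized as beta = sqrt(f * sigma_y^2 / (2p(1-p))) for a
target variance fraction f (random sign), a polygenic term spread over
all non-QTL variants so that its per-trait variance equals h2 - f_total
and its across-trait covariance follows the requested genetic
correlation matrix, and heteroscedastic residuals whose variance is
inversely proportional to each record's weight w = r2/(1 - r2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, PhenotypeSet, TruthRecord

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class QTL:
    """A causal variant: chromosome, 1-based position and the fraction of
    phenotypic variance it explains in each affected trait."""

    chrom: str
    pos: int
    fractions: dict[str, float]  # trait -> variance fraction in (0, 1)


@dataclass
class SimConfig:
    n_samples: int = 2000
    n_variants: int = 10000
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {str(c): 100_000_000 for c in range(1, 6)}
    )
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 25
    n_founders: int = 8
    trait_groups: dict[str, list[str]] = field(
        default_factory=lambda: {"production": ["T1", "T2", "T3"]}
    )
    h2: dict[str, float] = field(
        default_factory=lambda: {"T1": 0.4, "T2": 0.3, "T3": 0.2}
    )
    genetic_corr: np.ndarray | None = None  # d x d, identity when None
    qtl: list[QTL] = field(default_factory=list)
    reliability_range: tuple[float, float] = (0.4, 0.95)
    missing_rate: float | dict[str, float] = 0.0
    seed: int = 0

    @property
    def traits(self) -> list[str]:
        return [t for group in self.trait_groups.values() for t in group]

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def group_of(self) -> dict[str, str]:
        return {t: g for g, ts in self.trait_groups.items() for t in ts}

    def missing_rate_of(self, trait: str) -> float:
        if isinstance(self.missing_rate, dict):
            return float(self.missing_rate.get(trait, 0.0))
        return float(self.missing_rate)

    def corr_matrix(self) -> np.ndarray:
        d = self.n_traits
        if self.genetic_corr is None:
            return np.eye(d)
        R = np.asarray(self.genetic_corr, dtype=float)
        if R.shape != (d, d):
            raise ConfigError(f"genetic_corr must be {d} x {d}, got {R.shape}")
        if not np.allclose(R, R.T, atol=1e-10):
            raise ConfigError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise ConfigError("genetic_corr must have a unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ConfigError("genetic_corr must be positive semi-definite")
        return R

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}")
        if self.ld_block_size < 1 or self.ld_block_size > self.n_variants:
            raise ConfigError("ld_block_size must be in [1, n_variants]")
        if self.n_founders < 2:
            raise ConfigError("need at least 2 founder haplotypes per block")
        traits = self.traits
        if len(set(traits)) != len(traits):
            raise ConfigError("trait names must be unique across groups")
        if set(self.h2) != set(traits):
            raise ConfigError("h2 must provide one value per trait")
        for t, v in self.h2.items():
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"h2[{t!r}] = {v} outside [0, 1]")
        self.corr_matrix()
        qtl_total = {t: 0.0 for t in traits}
        for q in self.qtl:
            if q.chrom not in self.chrom_lengths:
                raise ConfigError(f"QTL chromosome {q.chrom!r} not in chrom_lengths")
            if not (1 <= q.pos <= self.chrom_lengths[q.chrom]):
                raise ConfigError(f"QTL position {q.pos} outside chromosome {q.chrom}")
            for t, f in q.fractions.items():
                if t not in qtl_total:
                    raise ConfigError(f"QTL references unknown trait {t!r}")
                if f <= 0:
                    raise ConfigError("QTL variance fractions must be positive")
                qtl_total[t] += f
        for t in traits:
            if qtl_total[t] > self.h2[t] + 1e-12:
                raise ConfigError(
                    f"trait {t!r}: QTL fractions sum to {qtl_total[t]:.3f} "
                    f"> h2 = {self.h2[t]}"
                )
        lo, hi = self.reliability_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigError("reliability_range must lie in (0, 1]")
        for t in traits:
            if not (0.0 <= self.missing_rate_of(t) < 1.0):
                raise ConfigError(f"missing_rate for {t!r} outside [0, 1)")


def _substreams(seed: int, n: int) -> list[np.random.Generator]:
    """Expand one integer seed into independent per-stage generators."""
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def reliability_to_weight(r2: np.ndarray) -> np.ndarray:
    """Deregression-style record weight w = r2 / (1 - r2)."""
    r2 = np.clip(np.asarray(r2, dtype=float), 0.0, 0.999)
    return r2 / (1.0 - r2)


def _allocate_positions(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Distribute variants over chromosomes proportionally to length and draw
    sorted unique positions; QTL positions are forced into the map."""
    chroms = list(cfg.chrom_lengths)
    lengths = np.array([cfg.chrom_lengths[c] for c in chroms], dtype=float)
    counts = np.maximum(1, np.round(cfg.n_variants * lengths / lengths.sum()).astype(int))
    # fix rounding drift so the total is exactly n_variants
    while counts.sum() > cfg.n_variants:
        counts[np.argmax(counts)] -= 1
    while counts.sum() < cfg.n_variants:
        counts[np.argmax(lengths)] += 1

    qtl_by_chrom: dict[str, list[int]] = {}
    for q in cfg.qtl:
        qtl_by_chrom.setdefault(q.chrom, []).append(q.pos)

    rows = []
    for chrom, m_c in zip(chroms, counts):
        length = cfg.chrom_lengths[chrom]
        forced = set(qtl_by_chrom.get(chrom, []))
        m_c = max(int(m_c), len(forced))
        pool = set(forced)
        while len(pool) < m_c:
            draw = rng.integers(1, length + 1, size=2 * (m_c - len(pool)) + 8)
            pool.update(int(p) for p in draw)
        extras = np.array(sorted(pool - forced))
        n_extra = m_c - len(forced)
        if n_extra < len(extras):
            extras = rng.choice(extras, size=n_extra, replace=False)
        rows.extend((chrom, int(p)) for p in sorted(forced | set(extras.tolist())))
    df = pd.DataFrame(rows, columns=["chrom", "pos"])
    df["id"] = [f"{c}_{p}" for c, p in zip(df["chrom"], df["pos"])]
    df["ref"] = "A"
    df["alt"] = "C"
    return df


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Generate hard-call genotypes under the founder-haplotype LD model.

    Within each block of ``cfg.ld_block_size`` consecutive variants every
    individual draws two of ``cfg.n_founders`` founder haplotypes, so
    variants in a block are in LD and different blocks are independent.
    Each variant's alt-allele frequency targets a uniform draw from
    ``maf_range``, realised as the nearest founder-count fraction (always
    polymorphic among the founders).  Deterministic for a fixed seed.
    """
    cfg.validate()
    rng_pos, rng_geno = _substreams(cfg.seed, 5)[:2]
    variants = _allocate_positions(cfg, rng_pos)
    n, m, k = cfg.n_samples, len(variants), cfg.n_founders
    lo, hi = cfg.maf_range

    dosages = np.empty((n, m), dtype=float)
    for start in range(0, m, cfg.ld_block_size):
        stop = min(start + cfg.ld_block_size, m)
        width = stop - start
        target = rng_geno.uniform(lo, hi, size=width)
        n_alt = np.clip(np.rint(target * k).astype(int), 1, k - 1)
        founders = np.zeros((k, width), dtype=np.int8)
        for j in range(width):
            carriers = rng_geno.choice(k, size=n_alt[j], replace=False)
            founders[carriers, j] = 1
        pick = rng_geno.integers(0, k, size=(n, 2))
        dosages[:, start:stop] = founders[pick[:, 0], :] + founders[pick[:, 1], :]

    return GenotypeMatrix(
        samples=[f"S{i:05d}" for i in range(n)], variants=variants, dosages=dosages
    )


def _psd_sqrt(S: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def simulate_phenotypes(
    geno: GenotypeMatrix, cfg: SimConfig
) -> tuple[PhenotypeSet, TruthRecord]:
    """Simulate drEBV-like phenotypes on an existing genotype matrix.

    Every trait has unit target phenotypic variance, partitioned into the
    configured QTL fractions, a correlated polygenic part of size
    ``h2 - sum(QTL fractions)`` spread over all non-QTL variants, and a
    residual whose per-record variance scales with the inverse record
    weight (normalised so the mean residual variance equals ``1 - h2``).
    """
    cfg.validate()
    _, _, rng_eff, rng_noise, rng_meta = _substreams(cfg.seed, 5)
    traits = cfg.traits
    n, d = geno.n_samples, len(traits)
    h2 = np.array([cfg.h2[t] for t in traits])
    R = cfg.corr_matrix()

    # --- locate causal variants ------------------------------------------------
    key = list(zip(geno.variants["chrom"], geno.variants["pos"]))
    col_of = {kp: j for j, kp in enumerate(key)}
    qtl_cols = []
    for q in cfg.qtl:
        try:
            qtl_cols.append(col_of[(q.chrom, q.pos)])
        except KeyError:
            raise ConfigError(
                f"QTL at {q.chrom}:{q.pos} has no matching variant in the genotype matrix"
            ) from None

    X = geno.dosages
    af = geno.allele_frequency()

    # --- QTL effects -----------------------------------------------------------
    g = np.zeros((n, d))
    effects: dict[str, dict[str, float]] = {t: {} for t in traits}
    qtl_frac_target = np.zeros(d)
    for q, col in zip(cfg.qtl, qtl_cols):
        p = af[col]
        var_x = 2.0 * p * (1.0 - p)
        vid = geno.variants.at[col, "id"]
        x = X[:, col]
        for t, f in q.fractions.items():
            ti = traits.index(t)
            beta = np.sqrt(f / var_x) * (1.0 if rng_eff.random() < 0.5 else -1.0)
            g[:, ti] += x * beta
            effects[t][vid] = float(beta)
            qtl_frac_target[ti] += f

    # --- polygenic background --------------------------------------------------
    poly_var = h2 - qtl_frac_target
    bg = np.setdiff1d(np.arange(geno.n_variants), np.array(qtl_cols, dtype=int))
    if np.any(poly_var > 1e-12) and bg.size:
        Xc = X[:, bg] - 2.0 * af[bg]
        c = float(np.sum(2.0 * af[bg] * (1.0 - af[bg])))
        Sg = np.sqrt(poly_var)[:, None] * R * np.sqrt(poly_var)[None, :]
        A = rng_eff.standard_normal((bg.size, d)) @ _psd_sqrt(Sg).T / np.sqrt(c)
        g += Xc @ A

    # --- reliabilities, weights, residuals -------------------------------------
    rel = rng_meta.uniform(*cfg.reliability_range, size=(n, d))
    w = reliability_to_weight(rel)
    resid_var = (1.0 - h2)[None, :] / w / np.mean(1.0 / w, axis=0, keepdims=True)
    y = g + rng_noise.standard_normal((n, d)) * np.sqrt(resid_var)

    # --- realized truth (computed before masking) ------------------------------
    var_y = y.var(axis=0, ddof=1)
    realized_h2 = {t: float(g[:, i].var(ddof=1) / var_y[i]) for i, t in enumerate(traits)}
    realized_qtl = {}
    for q, col in zip(cfg.qtl, qtl_cols):
        p = af[col]
        vid = geno.variants.at[col, "id"]
        for t in q.fractions:
            ti = traits.index(t)
            beta = effects[t][vid]
            realized_qtl[(vid, t)] = float(2.0 * p * (1.0 - p) * beta**2 / var_y[ti])

    # --- missingness (completely at random, per trait) -------------------------
    values = y.copy()
    for i, t in enumerate(traits):
        rate = cfg.missing_rate_of(t)
        if rate > 0:
            mask = rng_meta.random(n) < rate
            values[mask, i] = np.nan

    phen = PhenotypeSet(
        samples=list(geno.samples),
        traits=list(traits),
        values=values,
        reliability=rel,
        weight=w,
        group_of=cfg.group_of(),
    )
    truth = TruthRecord(
        causal_variant_ids=[geno.variants.at[c, "id"] for c in qtl_cols],
        effects=effects,
        realized_h2=realized_h2,
        realized_qtl_variance_fraction=realized_qtl,
    )
    return phen, truth


def apply_drebv_filters(
    phen: PhenotypeSet,
    min_reliability: float = 0.3,
    sd_limit: float = 5.0,
    min_records: int = 2000,
) -> PhenotypeSet:
    """Eligibility filtering of drEBV records.

    Records with reliability <= ``min_reliability`` are set missing; then
    records farther than ``sd_limit`` trait standard deviations from the
    trait mean (computed on the reliability-passing records) are set
    missing; finally traits with fewer than ``min_records`` remaining
    records are dropped entirely (and logged).
    """
    values = phen.values.copy()
    values[phen.reliability <= min_reliability] = np.nan
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(values, axis=0)
        sd = np.nanstd(values, axis=0, ddof=1)
        outlier = np.abs(values - mean) > sd_limit * sd
    values[outlier] = np.nan

    counts = np.sum(~np.isnan(values), axis=0)
    keep = counts >= min_records
    dropped = [t for t, k in zip(phen.traits, keep) if not k]
    if dropped:
        logger.warning(
            "dropping traits with < %d records: %s", min_records, ", ".join(dropped)
        )
    kept = [t for t, k in zip(phen.traits, keep) if k]
    out = phen.subset_traits(kept)
    out.values = values[:, np.flatnonzero(keep)]
    return out


def complete_case_subset(phen: PhenotypeSet, group: str) -> PhenotypeSet:
    """Samples with non-missing records for every trait of ``group``.

    This is the input contract of the multivariate scan and of the
    complete-case meta-analysis design: both operate on the same animals.
    """
    traits = phen.traits_in_group(group)
    sub = phen.subset_traits(traits)
    complete = ~np.isnan(sub.values).any(axis=1)
    if not complete.any():
        raise ValueError(
            f"no sample has complete records for group {group!r}; "
            "consider a smaller trait group"
        )
    return sub.subset_samples(complete)


def mask_for_imputation_cv(
    geno: GenotypeMatrix,
    keep_sites: set[str] | list[str],
    holdout_samples: set[str] | list[str],
) -> tuple[GenotypeMatrix, GenotypeMatrix]:
    """Build a masked panel for imputation cross-validation.

    For the holdout samples every variant not in ``keep_sites`` is set
    missing (emulating a density-reduced target panel); the returned
    truth matrix holds the original genotypes at exactly the masked
    entries (holdout samples x masked variants) so an external imputer's
    output can be scored with concordance and dosage-r2 metrics.
    """
    ids = set(geno.variants["id"])
    unknown = set(keep_sites) - ids
    if unknown:
        raise KeyError(f"keep_sites not in the panel: {sorted(unknown)[:5]}")
    missing_samples = set(holdout_samples) - set(geno.samples)
    if missing_samples:
        raise KeyError(f"holdout samples not in the panel: {sorted(missing_samples)[:5]}")

    keep_mask = geno.variants["id"].isin(set(keep_sites)).to_numpy()
    hold_idx = np.array([geno.samples.index(s) for s in holdout_samples], dtype=int)

    masked = GenotypeMatrix(
        samples=list(geno.samples),
        variants=geno.variants.copy(),
        dosages=geno.dosages.copy(),
    )
    masked.dosages[np.ix_(hold_idx, np.flatnonzero(~keep_mask))] = np.nan

    truth = GenotypeMatrix(
        samples=[geno.samples[i] for i in hold_idx],
        variants=geno.variants.iloc[~keep_mask].reset_index(drop=True),
        dosages=geno.dosages[np.ix_(hold_idx, np.flatnonzero(~keep_mask))].copy(),
    )
    return masked, truth
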