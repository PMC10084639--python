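"""Core in-memory containers shared across the pipeline.

Genotypes are held as an n x m allele-dosage matrix (samples by variants)
with a variant map, phenotypes as an n x d matrix of deregressed
breeding values (drEBV) with per-record reliabilities and weights, and
per-trait association results as tidy pandas DataFrames.

Missing values use ``numpy.nan`` throughout; hard genotype calls are the
floats 0.0/1.0/2.0, imputed dosages anything in [0, 2].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "id", "ref", "alt"]

SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "af", "beta", "se", "p", "n",
]


@dataclass
class GenotypeMatrix:
    """Allele-dosage matrix with its variant map.

    Parameters
    ----------
    samples
        Sample identifiers, length n.
    variants
        DataFrame with columns ``chrom, pos, id, ref, alt`` (and
        optionally ``dr2``, the model-based imputation accuracy), one row
        per variant, positions 1-based and strictly increasing within
        each chromosome.
    dosages
        n x m float array; entries in [0, 2] or NaN for missing.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant map lacks columns {missing}")
        self.variants = self.variants.reset_index(drop=True)
        for _, sub in self.variants.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within a chromosome")
        with np.errstate(invalid="ignore"):
            if np.any((self.dosages < 0) | (self.dosages > 2)):
                raise ValueError("dosages must lie in [0, 2] or be NaN")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> np.ndarray:
        return self.variants["id"].to_numpy()

    def column_of(self, variant_id: str) -> int:
        idx = np.flatnonzero(self.variants["id"].to_numpy() == variant_id)
        if idx.size == 0:
            raise KeyError(f"variant {variant_id!r} not present")
        return int(idx[0])

    def allele_frequency(self) -> np.ndarray:
        """Alt-allele frequency per variant, ignoring missing entries."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        af = self.allele_frequency()
        return np.minimum(af, 1.0 - af)

    def call_rate_variants(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def call_rate_samples(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def subset_samples(self, keep: np.ndarray | list) -> "GenotypeMatrix":
        keep = _as_index(keep, self.samples)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in keep],
            variants=self.variants.copy(),
            dosages=self.dosages[keep, :].copy(),
        )

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[keep].reset_index(drop=True),
            dosages=self.dosages[:, keep].copy(),
        )


@dataclass
class PhenotypeSet:
    """drEBV phenotypes with reliabilities, weights and trait groups."""

    samples: list[str]
    traits: list[str]
    values: np.ndarray      # n x d, NaN = missing record
    reliability: np.ndarray  # n x d, r2 of the drEBV in [0, 1]
    weight: np.ndarray       # n x d, positive where value present
    group_of: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n, d = len(self.samples), len(self.traits)
        for name in ("values", "reliability", "weight"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n, d):
                raise ValueError(f"{name} must be {n} x {d}, got {arr.shape}")
            setattr(self, name, arr)
        present = ~np.isnan(self.values)
        if np.any(present & ~(self.weight > 0)):
            raise ValueError("every non-missing value needs a positive weight")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise KeyError(f"trait {trait!r} not present") from None

    def traits_in_group(self, group: str) -> list[str]:
        names = [t for t in self.traits if self.group_of.get(t) == group]
        if not names:
            raise KeyError(f"trait group {group!r} is empty or unknown")
        return names

    def subset_samples(self, keep: np.ndarray | list) -> "PhenotypeSet":
        keep = _as_index(keep, self.samples)
        return PhenotypeSet(
            samples=[self.samples[i] for i in keep],
            traits=list(self.traits),
            values=self.values[keep, :].copy(),
            reliability=self.reliability[keep, :].copy(),
            weight=self.weight[keep, :].copy(),
            group_of=dict(self.group_of),
        )

    def subset_traits(self, traits: list[str]) -> "PhenotypeSet":
        cols = [self.trait_index(t) for t in traits]
        return PhenotypeSet(
            samples=list(self.samples),
            traits=list(traits),
            values=self.values[:, cols].copy(),
            reliability=self.reliability[:, cols].copy(),
            weight=self.weight[:, cols].copy(),
            group_of={t: self.group_of.get(t, "all") for t in traits},
        )


@dataclass
class TruthRecord:
    """Ground truth emitted by the simulator for parameter-recovery tests."""

    causal_variant_ids: list[str]
    # trait -> {variant_id -> allele substitution effect}
    effects: dict[str, dict[str, float]]
    realized_h2: dict[str, float]
    # (variant_id, trait) -> realized fraction of phenotypic variance
    realized_qtl_variance_fraction: dict[tuple[str, str], float]


@dataclass
class SummaryStats:
    """Per-trait association summary statistics (the stGWAS output)."""

    trait: str
    records: pd.DataFrame
    threshold_used: float | None = None

    def __post_init__(self) -> None:
        missing = [c for c in SUMMARY_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValueError(f"summary statistics lack columns {missing}")
        rec = self.records.sort_values(["chrom", "pos"], kind="mergesort")
        if rec["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids in summary statistics")
        self.records = rec.reset_index(drop=True)[SUMMARY_COLUMNS]

    @property
    def n_variants(self) -> int:
        return len(self.records)


def _as_index(keep, universe: list[str]) -> np.ndarray:
    """Normalise a boolean mask / index array / id list into positions."""
    keep = np.asarray(keep)
    if keep.dtype == bool:
        return np.flatnonzero(keep)
    if keep.dtype.kind in "iu":
        return keep
    lookup = {s: i for i, s in enumerate(universe)}
    try:
        return np.array([lookup[s] for s in keep], dtype=int)
    except KeyError as e:
        raise KeyError(f"sample {e.args[0]!r} not present") from None
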