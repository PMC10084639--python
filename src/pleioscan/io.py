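"""Readers and writers for the on-disk formats.

Genotypes travel either as VCF (GT for hard calls, DS for dosages, DR2
in INFO when present) or as a pair of TSVs (dosage matrix + variant
map); phenotypes as a long-format TSV (sample_id, trait, group, value,
reliability, weight); the GRM as a symmetric TSV with sample ids; and
summary statistics in a fixed column order that round-trips losslessly
into the meta-analysis.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import SUMMARY_COLUMNS, GenotypeMatrix, PhenotypeSet, SummaryStats
from .qc import GRM
from .sim import QTL, SimConfig

# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def write_vcf(geno: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as VCF: GT when every dosage is a hard call, DS
    otherwise; a dr2 variant column is emitted as INFO/DR2."""
    d = geno.dosages
    hard = bool(np.all(np.isnan(d) | (d == np.rint(d))))
    has_dr2 = "dr2" in geno.variants.columns
    gt_code = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(geno.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        if has_dr2:
            fh.write('##INFO=<ID=DR2,Number=1,Type=Float,'
                     'Description="Estimated imputation accuracy">\n')
        if hard:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                     'Description="Estimated alt allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        v = geno.variants
        for j in range(geno.n_variants):
            info = f"DR2={v.at[j, 'dr2']:.4g}" if has_dr2 else "."
            if hard:
                calls = [
                    "./." if np.isnan(x) else gt_code[int(round(x))]
                    for x in d[:, j]
                ]
                fmt = "GT"
            else:
                calls = ["." if np.isnan(x) else f"{x:.4g}" for x in d[:, j]]
                fmt = "DS"
            fh.write(
                f"{v.at[j, 'chrom']}\t{v.at[j, 'pos']}\t{v.at[j, 'id']}\t"
                f"{v.at[j, 'ref']}\t{v.at[j, 'alt']}\t.\t.\t{info}\t{fmt}\t"
                + "\t".join(calls) + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (DS preferred over GT; INFO/DR2
    captured when present).  Requires cyvcf2."""
    from cyvcf2 import VCF   # deferred: optional dependency

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rec = dict(chrom=var.CHROM, pos=var.POS,
                   id=var.ID or f"{var.CHROM}_{var.POS}", ref=var.REF, alt=alt)
        dr2 = var.INFO.get("DR2")
        if dr2 is not None:
            rec["dr2"] = float(dr2)
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            x = np.asarray(ds, dtype=float).reshape(-1)
            x[x < 0] = np.nan
        else:
            g = np.asarray(var.gt_types, dtype=float)
            g[g == 3] = np.nan
            x = g
        rows.append(rec)
        cols.append(x)
    variants = pd.DataFrame(rows)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(samples=samples, variants=variants, dosages=dosages)


def write_dosage_tsv(geno: GenotypeMatrix, matrix_path: str | Path,
                     map_path: str | Path) -> None:
    geno.variants.to_csv(map_path, sep="\t", index=False)
    df = pd.DataFrame(geno.dosages, index=geno.samples,
                      columns=geno.variants["id"])
    df.to_csv(matrix_path, sep="\t", index_label="sample_id")


def read_dosage_tsv(matrix_path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    variants = pd.read_csv(map_path, sep="\t", dtype={"chrom": str})
    df = pd.read_csv(matrix_path, sep="\t", index_col="sample_id")
    if list(df.columns) != list(variants["id"].astype(str)):
        raise ValueError("dosage matrix columns do not match the variant map")
    return GenotypeMatrix(samples=[str(s) for s in df.index],
                          variants=variants, dosages=df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# phenotypes / truth
# ---------------------------------------------------------------------------

def write_phenotypes_tsv(phen: PhenotypeSet, path: str | Path) -> None:
    rows = []
    for i, s in enumerate(phen.samples):
        for j, t in enumerate(phen.traits):
            rows.append(
                dict(sample_id=s, trait=t, group=phen.group_of.get(t, "all"),
                     value=phen.values[i, j], reliability=phen.reliability[i, j],
                     weight=phen.weight[i, j])
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, na_rep="NA")


def read_phenotypes_tsv(path: str | Path) -> PhenotypeSet:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    samples = list(dict.fromkeys(df["sample_id"].astype(str)))
    traits = list(dict.fromkeys(df["trait"].astype(str)))
    si = {s: i for i, s in enumerate(samples)}
    ti = {t: j for j, t in enumerate(traits)}
    n, d = len(samples), len(traits)
    values = np.full((n, d), np.nan)
    rel = np.full((n, d), np.nan)
    wt = np.full((n, d), np.nan)
    for row in df.itertuples(index=False):
        i, j = si[str(row.sample_id)], ti[str(row.trait)]
        values[i, j] = row.value
        rel[i, j] = row.reliability
        wt[i, j] = row.weight
    group_of = dict(zip(df["trait"].astype(str), df["group"].astype(str)))
    return PhenotypeSet(samples=samples, traits=traits, values=values,
                        reliability=rel, weight=wt, group_of=group_of)


# ---------------------------------------------------------------------------
# GRM and summary statistics
# ---------------------------------------------------------------------------

def write_grm_tsv(grm: GRM, path: str | Path) -> None:
    df = pd.DataFrame(grm.matrix, index=grm.sample_ids, columns=grm.sample_ids)
    df.attrs["n_variants_used"] = grm.n_variants_used
    with open(path, "w") as fh:
        fh.write(f"# n_variants_used={grm.n_variants_used}\n")
        df.to_csv(fh, sep="\t", index_label="sample_id")


def read_grm_tsv(path: str | Path) -> GRM:
    with open(path) as fh:
        first = fh.readline().strip()
        n_used = 0
        if first.startswith("#"):
            n_used = int(first.split("=", 1)[1])
            df = pd.read_csv(fh, sep="\t", index_col="sample_id")
        else:
            fh.seek(0)
            df = pd.read_csv(fh, sep="\t", index_col="sample_id")
    return GRM(sample_ids=[str(s) for s in df.index],
               matrix=df.to_numpy(dtype=float), n_variants_used=n_used)


def write_summary_tsv(stats: SummaryStats, path: str | Path) -> None:
    out = stats.records.copy()
    out.insert(0, "trait", stats.trait)
    out.to_csv(path, sep="\t", index=False)


def read_summary_tsv(path: str | Path) -> SummaryStats:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    traits = df["trait"].unique()
    if len(traits) != 1:
        raise ValueError("one summary-statistics file must hold exactly one trait")
    return SummaryStats(trait=str(traits[0]), records=df[SUMMARY_COLUMNS])


# ---------------------------------------------------------------------------
# simulation config
# ---------------------------------------------------------------------------

def load_sim_config(path: str | Path) -> SimConfig:
    """Build a SimConfig from a YAML file (keys mirror the dataclass)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return sim_config_from_dict(raw)


def sim_config_from_dict(raw: dict) -> SimConfig:
    kwargs = dict(raw)
    if "qtl" in kwargs:
        kwargs["qtl"] = [
            QTL(chrom=str(q["chrom"]), pos=int(q["pos"]),
                fractions={str(t): float(f) for t, f in q["fractions"].items()})
            for q in kwargs["qtl"]
        ]
    if "genetic_corr" in kwargs and kwargs["genetic_corr"] is not None:
        kwargs["genetic_corr"] = np.asarray(kwargs["genetic_corr"], dtype=float)
    if "chrom_lengths" in kwargs:
        kwargs["chrom_lengths"] = {
            str(c): int(v) for c, v in kwargs["chrom_lengths"].items()
        }
    for key in ("maf_range", "reliability_range"):
        if key in kwargs:
            kwargs[key] = tuple(float(x) for x in kwargs[key])
    cfg = SimConfig(**kwargs)
    cfg.validate()
    return cfg
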