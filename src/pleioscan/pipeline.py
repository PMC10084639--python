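"""End-to-end experiment orchestration from a single config.

Stage order: simulate -> drEBV eligibility filters -> genotype QC -> GRM
-> per-trait heritability -> single-trait scans (all available animals)
-> per trait group: complete-case multivariate scan, complete-case
meta-analysis (metaGWAS1) and all-available meta-analysis (metaGWAS2)
-> QTL calling and variance decomposition -> cross-method comparison ->
optional conditional rescan on the lead variants.

Every output file is digested into a run manifest so deterministic
stages can be verified to reproduce byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__, io
from .assoc import conditional_scan, fit_null, score_scan
from .containers import PhenotypeSet, SummaryStats
from .evaluate import bonferroni_threshold, compare_methods, fdr_analytic, inflation_factor
from .finemap import call_qtl, ld_r2, qtl_table, variance_explained
from .meta import assemble_t, estimate_v, meta_chi2
from .multivariate import mv_scan
from .qc import compute_grm_centered, qc_filter
from .sim import complete_case_subset, apply_drebv_filters, simulate_genotypes, simulate_phenotypes
from .varcomp import estimate_mt_vc, reml_single

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config: dict
    version: str
    seed: int
    started: float = field(default_factory=time.time)
    finished: float = 0.0
    file_digests: dict[str, str] = field(default_factory=dict)
    stage_log: list[dict] = field(default_factory=list)

    def digest(self, path: Path, root: Path) -> None:
        h = hashlib.sha256(path.read_bytes()).hexdigest()
        self.file_digests[str(path.relative_to(root))] = h

    def log_stage(self, stage: str, **info) -> None:
        entry = {"stage": stage, "wall_time": round(time.time() - self.started, 2), **info}
        self.stage_log.append(entry)
        logger.info("stage %-14s %s", stage, info)

    def write(self, path: Path) -> None:
        self.finished = time.time()
        payload = {
            "config": self.config, "version": self.version, "seed": self.seed,
            "started": self.started, "finished": self.finished,
            "file_digests": self.file_digests, "stage_log": self.stage_log,
        }
        path.write_text(json.dumps(payload, indent=2, default=str))


DEFAULTS = {
    "drebv_filters": {"min_reliability": 0.3, "sd_limit": 5.0, "min_records": 100},
    "qc": {"maf_min": 0.05, "hwe_p_min": 1e-5, "var_call_min": 0.8,
           "sample_call_min": 0.8},
    "scan": {"maf_min": 0.05, "alpha": 0.05, "df_mode": "d_minus_1",
             "v_mode": "all_markers", "merge_adjacent": True},
    "conditional_finemap": False,
}


def _load_config(config: dict | str | Path) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = {k: dict(v) if isinstance(v, dict) else v for k, v in DEFAULTS.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    if "simulation" not in cfg:
        raise ValueError("config must contain a 'simulation' section")
    return cfg


def _st_scan_group(phen: PhenotypeSet, grm, geno, traits, samples, maf_min
                   ) -> list[SummaryStats]:
    """Single-trait scans restricted to a fixed sample subset."""
    keep = set(samples)
    out = []
    for t in traits:
        ti = phen.trait_index(t)
        y = np.where(
            [s in keep for s in phen.samples], phen.values[:, ti], np.nan
        )
        null = fit_null(y, grm, trait=t)
        out.append(score_scan(null, geno, maf_min=maf_min))
    return out


def run_pipeline(config: dict | str | Path, outdir: str | Path) -> RunManifest:
    cfg = _load_config(config)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim_cfg = io.sim_config_from_dict(dict(cfg["simulation"]))
    if "seed" in cfg:
        sim_cfg.seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, version=__version__, seed=sim_cfg.seed)
    scan_cfg = cfg["scan"]
    report: list[str] = ["# pleioscan run report", ""]

    # --- simulate -------------------------------------------------------------
    geno = simulate_genotypes(sim_cfg)
    phen, truth = simulate_phenotypes(geno, sim_cfg)
    io.write_dosage_tsv(geno, out / "genotypes.tsv", out / "variants.tsv")
    io.write_phenotypes_tsv(phen, out / "phenotypes.tsv")
    pd.DataFrame(
        [(t, vid, b) for t, d_ in truth.effects.items() for vid, b in d_.items()],
        columns=["trait", "variant_id", "effect"],
    ).to_csv(out / "truth_effects.tsv", sep="\t", index=False)
    manifest.log_stage("simulate", n=geno.n_samples, m=geno.n_variants,
                       d=phen.n_traits)

    # --- phenotype eligibility + genotype QC -----------------------------------
    phen = apply_drebv_filters(phen, **cfg["drebv_filters"])
    geno, qc_report = qc_filter(geno, **cfg["qc"])
    pd.DataFrame([{
        "n_input_variants": qc_report.n_input_variants,
        **{f"removed_{k}": v for k, v in qc_report.n_removed_by.items()},
        "n_output_variants": qc_report.n_output_variants,
        "n_removed_samples": qc_report.n_removed_samples,
    }]).to_csv(out / "qc_report.tsv", sep="\t", index=False)
    manifest.log_stage("qc", variants_out=qc_report.n_output_variants,
                       traits_kept=phen.n_traits)

    # --- GRM and heritability ---------------------------------------------------
    grm = compute_grm_centered(geno)
    io.write_grm_tsv(grm, out / "grm.tsv")
    h2_rows = []
    for j, t in enumerate(phen.traits):
        vc = reml_single(phen.values[:, j], grm, weights=phen.weight[:, j])
        h2_rows.append(dict(trait=t, sigma_a2=vc.sigma_a2, sigma_e2=vc.sigma_e2,
                            h2=vc.h2, h2_se=vc.h2_se, n=vc.n_used,
                            converged=vc.converged,
                            h2_true=truth.realized_h2.get(t, np.nan)))
    h2_df = pd.DataFrame(h2_rows)
    h2_df.to_csv(out / "heritability.tsv", sep="\t", index=False)
    manifest.log_stage("reml", traits=len(h2_rows))

    # --- single-trait scans on all available animals ----------------------------
    st_all: dict[str, SummaryStats] = {}
    for j, t in enumerate(phen.traits):
        null = fit_null(phen.values[:, j], grm, trait=t)
        st_all[t] = score_scan(null, geno, maf_min=scan_cfg["maf_min"])
        io.write_summary_tsv(st_all[t], out / f"stgwas_{t}.tsv")
    manifest.log_stage("stgwas", traits=len(st_all))

    # --- per-group multi-trait analyses -----------------------------------------
    alpha = scan_cfg["alpha"]
    groups = cfg.get("groups") or sorted(set(phen.group_of.values()))
    all_regions: dict[str, list] = {}
    for group in groups:
        traits = phen.traits_in_group(group)
        cc = complete_case_subset(phen, group)
        report.append(f"## group {group}: {len(traits)} traits, "
                      f"{cc.n_samples} complete-case animals")

        # per-method per-variant p-value tables for the comparison layer;
        # calibration_p holds p-values referred to the df of the statistic's
        # construction so lambda_GC reads ~1 under the null regardless of
        # the df convention used for significance calls
        method_results: dict[str, pd.DataFrame] = {}
        calibration_p: dict[str, np.ndarray] = {}

        if len(traits) == 1:
            logger.info("group %s has one trait; multivariate scan reduces to "
                        "the single-trait scan", group)
            st = st_all[traits[0]]
            mv_df = st.records.rename(columns={"variant_id": "variant_id"})[
                ["variant_id", "chrom", "pos", "p"]]
            method_results["mtGWAS"] = mv_df
        else:
            grm_cc = grm.subset(cc.samples)
            vc = estimate_mt_vc(cc.values, grm_cc, traits=traits)
            mv = mv_scan(cc.values, geno, grm_cc, vc,
                         maf_min=scan_cfg["maf_min"], traits=traits)
            mv.to_csv(out / f"mtgwas_{group}.tsv", sep="\t", index=False)
            method_results["mtGWAS"] = mv[["variant_id", "chrom", "pos", "p"]]

            st_cc = _st_scan_group(phen, grm, geno, traits, cc.samples,
                                   scan_cfg["maf_min"])
            tm1 = assemble_t(st_cc)
            v1 = estimate_v(tm1, mode=scan_cfg["v_mode"])
            meta1 = meta_chi2(tm1, v1, df_mode=scan_cfg["df_mode"])
            meta1.records.to_csv(out / f"metagwas1_{group}.tsv", sep="\t", index=False)
            method_results["metaGWAS1"] = meta1.records[
                ["variant_id", "chrom", "pos", "p"]]
            calibration_p["metaGWAS1"] = stats.chi2.sf(
                meta1.records["chi2"], df=len(traits))

            tm2 = assemble_t([st_all[t] for t in traits])
            v2 = estimate_v(tm2, mode=scan_cfg["v_mode"])
            meta2 = meta_chi2(tm2, v2, df_mode=scan_cfg["df_mode"])
            meta2.records.to_csv(out / f"metagwas2_{group}.tsv", sep="\t", index=False)
            method_results["metaGWAS2"] = meta2.records[
                ["variant_id", "chrom", "pos", "p"]]
            calibration_p["metaGWAS2"] = stats.chi2.sf(
                meta2.records["chi2"], df=len(traits))

        thresholds = {m: bonferroni_threshold(alpha, len(df))
                      for m, df in method_results.items()}
        if len(method_results) > 1:
            comp = compare_methods(method_results, thresholds,
                                   merge_adjacent=scan_cfg["merge_adjacent"])
            report.append("")
            report.append("| method | significant variants | QTL | lambda_GC |")
            report.append("|---|---|---|---|")
            for m, df in method_results.items():
                p_cal = calibration_p.get(m, df["p"])
                lam = inflation_factor(p_cal) if len(df) >= 100 else np.nan
                report.append(f"| {m} | {comp.n_significant(m)} | "
                              f"{len(comp.qtl.get(m, []))} | {lam:.3f} |")
            report.append("")
            for key, count in sorted(comp.overlap.items(), key=lambda kv: -len(kv[0])):
                if count:
                    report.append(f"- exactly {{{', '.join(sorted(key))}}}: {count}")

        # QTL calling + fine-mapping on the best-powered meta design
        basis = method_results.get("metaGWAS2", next(iter(method_results.values())))
        regions = call_qtl(basis, thresholds.get("metaGWAS2",
                                                 list(thresholds.values())[0]),
                           merge_adjacent=scan_cfg["merge_adjacent"])
        for region in regions:
            st_thr = bonferroni_threshold(alpha, len(next(iter(st_all.values())).records))
            for t in traits:
                rec = st_all[t].records
                in_region = rec[(rec["chrom"] == region.chrom)
                                & (rec["pos"] >= region.start_bp)
                                & (rec["pos"] <= region.stop_bp)]
                if (in_region["p"] < st_thr).any():
                    ti = phen.trait_index(t)
                    ve = variance_explained(phen.values[:, ti], geno,
                                            [region.lead_variant])
                    region.variance_explained_pct[t] = ve[region.lead_variant]
        all_regions[group] = regions
        if regions:
            qtl_table(regions, geno).to_csv(out / f"qtl_{group}.tsv", sep="\t",
                                            index=False)
            report.append("")
            report.append(f"QTL ({group}): " + "; ".join(
                f"{r.chrom}:{r.start_bp}-{r.stop_bp} lead {r.lead_variant} "
                f"p={r.lead_p:.2e}" for r in regions))
        manifest.log_stage(f"group:{group}", qtl=len(regions),
                           complete_cases=cc.n_samples)

    # --- optional conditional rescan on the union of lead variants --------------
    if cfg["conditional_finemap"]:
        leads = sorted({r.lead_variant for rs in all_regions.values() for r in rs})
        if leads:
            for j, t in enumerate(phen.traits):
                null = fit_null(phen.values[:, j], grm, trait=t)
                cond = conditional_scan(null, geno, leads,
                                        maf_min=scan_cfg["maf_min"])
                io.write_summary_tsv(cond, out / f"stgwas_conditional_{t}.tsv")
            manifest.log_stage("conditional", leads=len(leads))

    # --- FDR summary -------------------------------------------------------------
    fdr_rows = []
    for t, st in st_all.items():
        thr = bonferroni_threshold(alpha, st.n_variants)
        a = int((st.records["p"] < thr).sum())
        fdr_rows.append(dict(trait=t, threshold=thr, n_significant=a,
                             fdr_pct=fdr_analytic(thr, a, st.n_variants)
                             if a else np.nan))
    pd.DataFrame(fdr_rows).to_csv(out / "fdr.tsv", sep="\t", index=False)

    (out / "report.md").write_text("\n".join(report) + "\n")
    for path in sorted(out.glob("*.tsv")) + [out / "report.md"]:
        manifest.digest(path, out)
    manifest.write(out / "manifest.json")
    return manifest
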