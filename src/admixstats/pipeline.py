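"""End-to-end demo pipeline: simulate -> catalog -> project -> share -> burden -> sexbias.

Every statistical output is a TSV or JSON-lines file stamped with the config
hash and seed; stage timings and record counts go to a separate plain-text log
(excluded from byte-identity comparisons, since timings are not deterministic).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import burden as burden_mod
from . import catalog, discovery, doubletons, sexbias
from .io import (
    RunConfig,
    write_annotations,
    write_local_ancestry,
    write_truth,
    write_vcf,
)
from .simulate import DemographicSpec, simulate_cohort, simulate_panel

__all__ = ["run_pipeline"]


def _stamp(df: pd.DataFrame, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df.attrs["config"] = cfg.digest()
    return df


def run_pipeline(cfg: RunConfig) -> dict[str, Path]:
    """Run the configured stages; returns a mapping of output name -> path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    log = open(log_path, "w")
    stats_path = out / "stats.jsonl"
    stats_fh = open(stats_path, "w")
    paths: dict[str, Path] = {"log": log_path, "stats": stats_path}
    header = f"# config={cfg.digest()} seed={cfg.seed}\n"

    def log_stage(name, t0, **counts):
        log.write(f"{name}\t{time.perf_counter() - t0:.2f}s\t"
                  + json.dumps(counts) + "\n")
        log.flush()

    def emit(**record):
        record["config"] = cfg.digest()
        record["seed"] = cfg.seed
        stats_fh.write(json.dumps(record) + "\n")

    def save(name, df, index=False):
        p = out / f"{name}.tsv"
        with open(p, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=index)
        paths[name] = p

    cfg.to_yaml(out / "config_used.yaml")
    paths["config"] = out / "config_used.yaml"

    spec = DemographicSpec(**{"seed": cfg.seed, **cfg.demographic})
    if spec.seed != cfg.seed:
        spec = spec.with_(seed=cfg.seed)

    t0 = time.perf_counter()
    panel = simulate_panel(cfg.n_sites, spec)
    cohort = simulate_cohort(spec, panel)
    gm, lac = cohort.genotypes, cohort.true_local
    ann = panel.table
    if cfg.subgroup is not None:
        keep = (cohort.populations == cfg.subgroup).to_numpy()
        gm = gm.subset_individuals(keep)
        lac = type(lac)(lac.codes[keep], lac.site_ids, lac.individual_ids[keep])
    if "simulate" in cfg.stages:
        write_vcf(gm, out / "cohort.vcf")
        write_local_ancestry(lac, out / "local_ancestry.tsv")
        write_annotations(panel, out / "annotations.tsv")
        write_truth(cohort, out / "truth.tsv")
        paths.update({
            "vcf": out / "cohort.vcf", "lac": out / "local_ancestry.tsv",
            "annotations": out / "annotations.tsv", "truth": out / "truth.tsv",
        })
        log_stage("simulate", t0, individuals=gm.n_individuals, sites=gm.n_sites)

    sfs = None
    if "catalog" in cfg.stages:
        t0 = time.perf_counter()
        counts = catalog.allele_counts(gm)
        save("site_counts", counts)
        novelty = catalog.novelty_accounting(gm, ann)
        save("novelty", novelty, index=True)
        called = counts["called"].to_numpy()
        n_project = int(np.percentile(called[~gm.is_x], 5)) if gm.n_sites else 0
        sfs = catalog.build_sfs(gm, ann, n_project=n_project, label="all")
        save("sfs", sfs.to_frame())
        nb_df, nb_test = catalog.novelty_by_background(gm, ann, lac)
        save("novelty_background", nb_df, index=True)
        emit(test="novelty_by_background_paired_t", statistic=nb_test.statistic,
             df=nb_test.df, pvalue=nb_test.pvalue, n=nb_test.n_used)
        log_stage("catalog", t0, segregating=int(counts["segregating"].sum()))

    if "project" in cfg.stages:
        t0 = time.perf_counter()
        if sfs is None:
            raise RuntimeError("project stage requires the catalog stage")
        save("discovery_curve", discovery.discovery_curve(sfs))
        M = int(round(cfg.projection_factor * sfs.n_chromosomes))
        res = discovery.jackknife_project(sfs, M)
        proj = pd.DataFrame(
            [{"M": M, "order": k, "projection": v,
              "stability": res.stability.get(k, np.nan), "selected": k == res.order}
             for k, v in res.projections.items()]
        )
        save("projection", proj)
        emit(test="discovery_gain_pct",
             statistic=100.0 * (res.value - sfs.segregating) / sfs.segregating,
             pvalue=None, n=sfs.n_chromosomes)
        log_stage("project", t0, M=M, order=res.order)

    if "share" in cfg.stages:
        t0 = time.perf_counter()
        dbl = doubletons.find_doubletons(gm, ann, cfg.missingness_max)
        share = doubletons.sharing_matrix(gm, dbl)
        save("sharing_individual", share.individual_counts, index=True)
        save("sharing_population", share.pop_normalized, index=True)
        emit(test="doubleton_totals", statistic=share.total_doubletons,
             pvalue=None, n=share.n_pair_doubletons,
             excluded_homozygous=share.excluded_homozygous)
        log_stage("share", t0, doubletons=share.total_doubletons)

    if "burden" in cfg.stages:
        t0 = time.perf_counter()
        scores = ann["conservation"].to_numpy()
        cutoff, flags = burden_mod.deleterious_threshold(scores, cfg.percentile)
        flags, n_dropped = burden_mod.robust_filter(
            flags, ann["cadd"].to_numpy(), cfg.robust_mode
        )
        q_afr = cohort.true_global_auto.loc[gm.individuals.index, "q_AFR"]
        prof = burden_mod.burden_profiles(gm, flags, ann, q_afr)
        save("burden_profiles", prof, index=True)
        for comp in ("het", "homder", "derived"):
            rho, p = burden_mod.burden_ancestry_correlation(prof, comp, "all")
            emit(test=f"spearman_{comp}_vs_afr", statistic=rho, pvalue=p,
                 n=len(prof))
        strat, mw = burden_mod.stratified_proportions(gm, flags, lac, ann, "all")
        save("stratified_proportions", strat, index=True)
        emit(test="stratified_mannwhitney", statistic=mw.u, pvalue=mw.pvalue,
             n=mw.n1 + mw.n2)
        cmp_res = burden_mod.score_distribution_compare(flags, ann)
        emit(test="score_coding_vs_noncoding", **cmp_res)
        emit(test="deleterious_cutoff", statistic=cutoff, pvalue=None,
             n=int(flags.sum()), dropped_missing_cadd=n_dropped)
        log_stage("burden", t0, flagged=int(flags.sum()))

    if "sexbias" in cfg.stages:
        t0 = time.perf_counter()
        females = cohort.sex.loc[gm.individuals.index].to_numpy() == "female"
        gmf = gm.subset_individuals(females)
        freqs = panel.freqs
        q_auto, _ = sexbias.estimate_q_supervised(gmf, freqs, site_mask=~gm.is_x)
        q_x, _ = sexbias.estimate_q_supervised(gmf, freqs, site_mask=gm.is_x)
        prof = q_auto.add_suffix("_auto").join(q_x.add_suffix("_x"))
        save("ancestry_profiles", prof, index=True)
        results = {}
        for pop, grp in gmf.individuals.groupby("population", sort=True):
            idx = grp.index
            if len(idx) < 2:
                continue
            results[pop] = sexbias.compare_x_autosome(
                q_auto.loc[idx], q_x.loc[idx], m_tests=cfg.bonferroni_m,
                alpha=cfg.alpha,
            )
        report = sexbias.bias_report(results)
        save("sexbias", report)
        for _, row in report.iterrows():
            emit(test=f"sexbias_{row['population']}_{row['component']}",
                 statistic=row["t"], pvalue=row["pvalue"],
                 adjusted=row["pvalue_bonferroni"], direction=row["direction"],
                 n=int(row["n"]))
        log_stage("sexbias", t0, populations=len(results))

    stats_fh.close()
    log.close()
    return paths
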