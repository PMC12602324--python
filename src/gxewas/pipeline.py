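"""End-to-end orchestration: per-cohort analysis and cross-cohort meta.

`run_cohort` turns one cohort's raw tables into METAL-ready summary
statistics for the three models; `run_meta_and_followup` combines cohorts,
applies Bonferroni/suggestive flags, annotates cis/trans, runs the
model-overlap enrichment and, for significant hits, the stress-domain
decomposition and mediation follow-ups.  `run_study` drives the whole thing
on a simulated multi-cohort dataset from one config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, followup, genoqc, io, meta, methprep, scan, stress
from .simulate import CohortData, SimulationConfig, item_domain_mapping, simulate_study


@dataclass
class PipelineOptions:
    """Knobs for the analysis stages (defaults follow the pipeline's QC and
    multiple-testing conventions)."""

    alpha: float = 0.05
    chunk_size: int | None = None
    emission_threshold_pairs: float | None = None  # None = emit all pair records
    prune: bool = False
    impute_iterations: int = 60
    suggestive_p_pair: float = meta.SUGGESTIVE_P_GXE
    suggestive_p_e: float = meta.SUGGESTIVE_P_E
    require_all_cohorts: bool = False
    seed: int = 0


def _identity_rules(items: pd.DataFrame, mapping: dict[str, str]) -> dict[str, stress.ItemRule]:
    return {c: stress.ItemRule(domain=mapping[c]) for c in items.columns}


def score_stress(cohort: CohortData, mapping: dict[str, str], opts: PipelineOptions) -> pd.DataFrame:
    rules = _identity_rules(cohort.stress_items, mapping)
    cohort_labels = pd.Series(cohort.name, index=cohort.stress_items.index)
    return stress.score_cohorts(
        cohort.stress_items, rules, cohort_labels,
        n_iter=opts.impute_iterations, seed=opts.seed,
    )


def run_cohort(cohort: CohortData, mapping: dict[str, str], opts: PipelineOptions,
               out_dir: Path | None = None, reference_geno=None) -> dict:
    """QC, scoring, prep and the three scans for one cohort.

    ``reference_geno`` designates the cohort whose allele frequencies define
    the minor allele (defaults to this cohort).  Returns a dict with the
    scores, QC'd matrices and the three scan tables; writes TSVs when
    ``out_dir`` is given.
    """
    scores = score_stress(cohort, mapping, opts)

    geno, snp_log = genoqc.snp_filter(cohort.genotypes)
    if opts.prune:
        kept = genoqc.vif_prune(geno)
        geno = geno.subset(snp_mask=geno.snps["snp"].isin(kept).to_numpy())

    ref = reference_geno if reference_geno is not None else geno
    ref_af1 = np.nanmean(ref.calls, axis=0) / 2.0
    ref_minor1 = pd.Series(ref_af1 <= 0.5, index=ref.snps["snp"])
    minor_is_a1 = ref_minor1.reindex(geno.snps["snp"]).fillna(True).to_numpy()
    dom, mono = genoqc.dominant_code(geno.calls, minor_is_a1)

    meth, probe_counts = methprep.probe_filter(cohort.methylation)
    meth = methprep.winsorize_betas(meth)

    subjects = scores.index.intersection(geno.subjects).intersection(meth.subjects)
    srow = {s: i for i, s in enumerate(geno.subjects)}
    rows = np.array([srow[s] for s in subjects])
    mrow = {s: i for i, s in enumerate(meth.subjects)}
    mrows = np.array([mrow[s] for s in subjects])
    C = cohort.covariates.loc[subjects]
    design = scan.ScanDesign(
        M=meth.betas[mrows], cpg_ids=list(meth.probes["cpg"]),
        C=C.to_numpy(), E=scores.loc[subjects, "z_winsorized"].to_numpy(),
        G=dom[rows], snp_ids=list(geno.snps["snp"]),
        covariate_names=list(C.columns),
    )
    res_e = scan.emodel_scan(design)
    res_g = scan.gmodel_scan(design, opts.chunk_size)
    res_gxe = scan.gxe_scan(design, opts.chunk_size)
    if opts.emission_threshold_pairs is not None:
        keep_g = (res_g["p"] < opts.emission_threshold_pairs) | res_g["p"].isna()
        keep_x = (res_gxe["p"] < opts.emission_threshold_pairs) | res_gxe["p"].isna()
        res_g, res_gxe = res_g[keep_g], res_gxe[keep_x]

    out = {
        "scores": scores, "genotypes": geno, "dominant": dom, "monomorphic": mono,
        "methylation": meth, "snp_drop_log": snp_log, "probe_counts": probe_counts,
        "subjects": subjects, "E": res_e, "G": res_g, "GxE": res_gxe,
    }
    if out_dir is not None:
        d = Path(out_dir) / cohort.name
        d.mkdir(parents=True, exist_ok=True)
        scores.to_csv(d / "stress_scores.tsv", sep="\t", index_label="subject")
        snp_log.to_csv(d / "snp_drop_log.tsv", sep="\t", index=False)
        with open(d / "probe_counts.json", "w") as fh:
            json.dump(probe_counts, fh, indent=1)
        coded = pd.Series(
            np.where(minor_is_a1, geno.snps["allele1"], geno.snps["allele2"]),
            index=geno.snps["snp"])
        for model, table in (("E", res_e), ("G", res_g), ("GxE", res_gxe)):
            io.write_summary_stats(table, d / f"summary_{model}.tsv",
                                   coded_allele=None if model == "E" else coded,
                                   header_comment=f"cohort={cohort.name} model={model}")
    return out


def run_meta_and_followup(cohort_results: dict[str, dict], cohorts: list[CohortData],
                          opts: PipelineOptions, out_dir: Path | None = None) -> dict:
    """Meta-analysis, thresholds, annotation, enrichment and follow-ups."""
    order = list(cohort_results)
    metas = {}
    for model in ("E", "G", "GxE"):
        metas[model] = meta.meta_analyze(
            {name: res[model] for name, res in cohort_results.items()},
            cohort_order=order, require_all=opts.require_all_cohorts)

    snp_meta = pd.concat([r["genotypes"].snps for r in cohort_results.values()]) \
        .drop_duplicates("snp").reset_index(drop=True)
    probe_meta = pd.concat([r["methylation"].probes for r in cohort_results.values()]) \
        .drop_duplicates("cpg").reset_index(drop=True)
    n_snps = len(snp_meta)
    n_cpgs = len(probe_meta)
    thr_pair = meta.bonferroni_threshold(opts.alpha, n_snps * n_cpgs)
    thr_e = meta.bonferroni_threshold(opts.alpha, n_cpgs)
    for model, thr in (("E", thr_e), ("G", thr_pair), ("GxE", thr_pair)):
        metas[model]["significant"] = metas[model]["p"] < thr
        sugg = opts.suggestive_p_e if model == "E" else opts.suggestive_p_pair
        metas[model]["suggestive"] = metas[model]["p"] < sugg

    for model in ("G", "GxE"):
        metas[model] = annotate.annotate_pairs(metas[model], snp_meta, probe_meta)

    # model-overlap enrichment on unique entities (universe = all scanned)
    overlaps = {}
    for entity, universe in (("snp", set(snp_meta["snp"])), ("cpg", set(probe_meta["cpg"]))):
        tables = {}
        for model in (("G", "GxE") if entity == "snp" else ("G", "GxE", "E")):
            m = metas[model]
            if entity == "snp" and model == "E":
                continue
            tables[model] = set(m.loc[m["suggestive"], entity].dropna())
        sa, sb = tables["G"], tables["GxE"]
        a = len(sa & sb); b = len(sa - sb); c = len(sb - sa); d = len(universe - sa - sb)
        try:
            overlaps[entity] = annotate.fisher_2x2(a, b, c, d)
        except ValueError:
            overlaps[entity] = {"table": (a, b, c, d), "odds_ratio": np.nan,
                                "ci95": (np.nan, np.nan), "p": np.nan}

    followups = _followup_hits(metas, cohort_results, cohorts, opts)

    out = {"meta": metas, "thresholds": {"pair": thr_pair, "e": thr_e},
           "overlap": overlaps, "followup": followups}
    if out_dir is not None:
        d = Path(out_dir) / "meta"
        d.mkdir(parents=True, exist_ok=True)
        for model, table in metas.items():
            table.to_csv(d / f"meta_{model}.tsv", sep="\t", index=False, na_rep="NA")
        followups["domains"].to_csv(d / "followup_domains.tsv", sep="\t", index=False, na_rep="NA")
        followups["mediation"].to_csv(d / "followup_mediation.tsv", sep="\t", index=False, na_rep="NA")
        with open(d / "overlap_enrichment.json", "w") as fh:
            json.dump({k: {kk: (list(vv) if isinstance(vv, tuple) else vv)
                           for kk, vv in v.items()} for k, v in overlaps.items()}, fh, indent=1)
    return out


def _pooled_arrays(cohort_results, cohorts, cpg, snp=None):
    """Stack subject-level outcome/exposure/genotype/covariates over cohorts,
    with cohort indicator columns appended to the covariates."""
    ys, es, gs, Cs, Ds, Ms = [], [], [], [], [], []
    names = list(cohort_results)
    for ci, (name, res) in enumerate(cohort_results.items()):
        cd = next(c for c in cohorts if c.name == name)
        subjects = res["subjects"]
        meth = res["methylation"]
        if cpg not in set(meth.probes["cpg"]):
            continue
        k = list(meth.probes["cpg"]).index(cpg)
        rows = np.array([list(meth.subjects).index(s) for s in subjects])
        ys.append(meth.betas[rows, k])
        es.append(res["scores"].loc[subjects, "z_winsorized"].to_numpy())
        C = cd.covariates.loc[subjects].to_numpy()
        pad = np.zeros((len(subjects), len(names) - 1))
        if ci > 0:
            pad[:, ci - 1] = 1.0
        # batch dummies are cohort-specific: keep sex/PCs/cells, add cohort dummies
        base_cols = [c for c in cd.covariates.columns if not c.startswith("batch")]
        Cs.append(np.column_stack([cd.covariates.loc[subjects, base_cols].to_numpy(), pad]))
        Ds.append(res["scores"].loc[subjects, list(stress.DOMAINS)].to_numpy())
        Ms.append(cd.mediators.loc[subjects].to_numpy())
        if snp is not None:
            j = list(res["genotypes"].snps["snp"]).index(snp)
            grow = np.array([list(res["genotypes"].subjects).index(s) for s in subjects])
            gs.append(res["dominant"][grow, j])
    mednames = list(cohorts[0].mediators.columns)
    return (np.concatenate(ys), np.concatenate(es),
            np.concatenate(gs) if gs else None,
            np.vstack(Cs), np.vstack(Ds),
            pd.DataFrame(np.vstack(Ms), columns=mednames))


def _followup_hits(metas, cohort_results, cohorts, opts) -> dict:
    """Domain decomposition and mediation for every significant E/GxE hit."""
    dom_rows, med_rows = [], []
    hits = []
    e_hits = metas["E"].loc[metas["E"]["significant"]]
    hits += [("E", None, r.cpg) for r in e_hits.itertuples()]
    x_hits = metas["GxE"].loc[metas["GxE"]["significant"]]
    hits += [("GxE", r.snp, r.cpg) for r in x_hits.itertuples()]
    for model, snp, cpg in hits:
        y, e, g, C, D, M = _pooled_arrays(cohort_results, cohorts, cpg, snp)
        Dd = pd.DataFrame(D, columns=list(stress.DOMAINS))
        dd = followup.domain_decomposition(y, Dd, C, g=g if model == "GxE" else None)
        dd.insert(0, "cpg", cpg)
        dd.insert(0, "snp", snp)
        dd.insert(0, "model", model)
        dom_rows.append(dd)
        if model == "GxE":
            x = (g - g.mean()) * (e - e.mean())
            Cmed = np.column_stack([C, g, e])
        else:
            x = e
            Cmed = C
        mm = followup.mediate_all(x, M, y, Cmed, seed=opts.seed)
        mm.insert(0, "cpg", cpg)
        mm.insert(0, "snp", snp)
        mm.insert(0, "model", model)
        med_rows.append(mm)
    dom_cols = ["model", "snp", "cpg", "domain", "term", "beta", "se", "p", "unique_contribution"]
    med_cols = ["model", "snp", "cpg", "mediator", "a", "se_a", "b", "se_b", "indirect",
                "se_indirect", "p_indirect", "direct", "total", "significant", "ci95"]
    return {
        "domains": pd.concat(dom_rows, ignore_index=True) if dom_rows else pd.DataFrame(columns=dom_cols),
        "mediation": pd.concat(med_rows, ignore_index=True) if med_rows else pd.DataFrame(columns=med_cols),
    }


def run_study(sim_cfg: SimulationConfig, opts: PipelineOptions | None = None,
              out_dir=None) -> dict:
    """Simulate a multi-cohort study and run the full analysis on it."""
    opts = opts or PipelineOptions(seed=sim_cfg.seed)
    cohorts, registry = simulate_study(sim_cfg)
    mapping = item_domain_mapping(sim_cfg)
    ref = max(cohorts, key=lambda c: c.genotypes.n_subjects).genotypes
    results = {}
    for cohort in cohorts:
        results[cohort.name] = run_cohort(cohort, mapping, opts, out_dir, reference_geno=ref)
    summary = run_meta_and_followup(results, cohorts, opts, out_dir)
    summary["registry"] = registry
    summary["cohort_results"] = results
    if out_dir is not None:
        io.write_registry(registry, Path(out_dir) / "truth_registry.json")
    return summary
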