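"""End-to-end orchestration: simulate (or load) -> call mCs -> DMRs ->
annotate -> integrate expression -> smRNA/TE analysis, with a summary
JSON mirroring the figure-level tallies (mC context shares, DMR counts
by context and direction, DEG/dmDEG counts, direction cross-tabs, TE
frequencies, smRNA enrichment) and a run manifest for reproducibility.

Stage outputs are pure functions of (inputs, config, seed): re-running
with the same seed reproduces a byte-identical summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotate, dmr, evaluate, integrate, methylome, smrna
from .config import GENOTYPES, SAMPLES, AnalysisConfig, SimulationConfig, config_to_dict
from .simulate import SimulatedDataset, simulate_dataset

log = logging.getLogger("methylscape")

COMPARISONS = {"SSc/s": ("SS-C", "SS-S"), "STc/s": ("ST-C", "ST-S")}


def _round_floats(obj, ndigits: int = 6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def run_all(
    sim_config: SimulationConfig | None = None,
    analysis_config: AnalysisConfig | None = None,
    outdir: str | Path | None = None,
    seed: int = 0,
    contexts: tuple[str, ...] = ("CG", "CHG", "CHH"),
    dataset: SimulatedDataset | None = None,
    write_outputs: bool = True,
) -> dict:
    """Run every stage on a simulated dataset and return the summary dict.

    When ``outdir`` is given, writes ``summary.json``, ``run_manifest.json``
    and per-stage TSV tables there.
    """
    cfg = analysis_config or AnalysisConfig()
    sim_cfg = sim_config or SimulationConfig()
    t0 = time.time()
    timings: dict[str, float] = {}
    summary: dict = {"seed": seed, "contexts": list(contexts)}

    if dataset is None:
        log.info("simulating dataset (seed=%d)", seed)
        dataset = simulate_dataset(sim_cfg, seed)
    timings["simulate"] = time.time() - t0
    genome, manifest = dataset.genome, dataset.manifest
    genes, tes = dataset.genes, dataset.tes

    # ---- stage: mC calling -------------------------------------------
    t = time.time()
    calls, conv = {}, {}
    for sample in SAMPLES:
        report = dataset.reports[sample]
        control = report[report["chrom"] == genome.control_chrom]
        est = methylome.estimate_conversion_error(control)
        conv[sample] = est
        body = report[report["chrom"] != genome.control_chrom]
        calls[sample] = methylome.call_methylcytosines(body, est.error_rate, cfg)
        log.info("%s: conversion error %.5f, %d mCs", sample, est.error_rate,
                 int(calls[sample]["is_mc"].sum()))
    summary["conversion_error"] = {
        s: {"rate": conv[s].error_rate, "efficiency": conv[s].efficiency,
            "ci": [conv[s].ci_low, conv[s].ci_high]} for s in SAMPLES
    }
    summary["mc_composition"] = {s: methylome.context_composition(calls[s]) for s in SAMPLES}
    timings["call_mc"] = time.time() - t

    # ---- stage: DMRs --------------------------------------------------
    t = time.time()
    dmr_tables: dict[str, pd.DataFrame] = {}
    summary["dmrs"] = {}
    for comp_name, (ctrl, stress) in COMPARISONS.items():
        per_context = []
        for context in contexts:
            bins = dmr.aggregate_bins(dataset.reports[ctrl][
                dataset.reports[ctrl]["chrom"] != genome.control_chrom
            ], dataset.reports[stress][
                dataset.reports[stress]["chrom"] != genome.control_chrom
            ], context, cfg)
            called = dmr.call_dmrs(dmr.test_bins(bins), cfg)
            per_context.append(called)
            log.info("%s %s: %d tested bins, %d DMRs", comp_name, context,
                     int(bins["tested"].sum()), int(called["is_dmr"].sum()))
        table = pd.concat(per_context, ignore_index=True)
        dmr_tables[comp_name] = table
        counts = dmr.dmr_counts(table)
        summary["dmrs"][comp_name] = {
            "n_tested": int(table.shape[0]),
            "counts": {f"{r.context}:{r.direction}": int(r.n_dmrs) for r in counts.itertuples()},
            "recovery": {
                ctx: evaluate.dmr_recovery(table, manifest, ctx) for ctx in contexts
            } if len(manifest.planted_dmrs) else {},
        }
    timings["dmr"] = time.time() - t

    # ---- stage: annotation / profiles ---------------------------------
    t = time.time()
    assoc: dict[str, pd.DataFrame] = {}
    summary["associations"] = {}
    for comp_name, table in dmr_tables.items():
        called = table[table["is_dmr"]]
        assoc[comp_name] = annotate.associate_dmrs(called, dataset.features, config=cfg)
        counts = annotate.association_counts(assoc[comp_name])
        summary["associations"][comp_name] = {
            f"{r.kind}:{r.context}:{r.region}:{r.direction}": int(r.n_dmrs)
            for r in counts.itertuples()
        }
    ref_calls = calls["SS-C"]
    profiles = {}
    for context in contexts:
        for kind, feats in (("gene", genes), ("TE", tes)):
            prof = annotate.metagene_profile(ref_calls, feats, context, cfg)
            profiles[f"{kind}:{context}"] = prof
    summary["metagene"] = {
        key: {"body_density": p.body_density_mean, "flank_density": p.flank_density_mean,
              "n_features": p.n_features}
        for key, p in profiles.items()
    }
    if "CG" in contexts and len(genes):
        class_profiles = annotate.expression_class_profiles(
            dataset.expression, ref_calls, genes, "CG", cfg
        )
        summary["expression_classes"] = {
            "body_cg_density": {int(k): p.body_density_mean for k, p in class_profiles.items()},
            "spearman": annotate.class_trend_spearman(class_profiles),
        }
    timings["annotate"] = time.time() - t

    # ---- stage: expression integration --------------------------------
    t = time.time()
    summary["expression"] = {}
    deg_tables = {}
    all_deg_ids: set[str] = set()
    for genotype in GENOTYPES:
        degs = integrate.call_degs(dataset.expression, genotype, cfg)
        deg_tables[genotype] = degs
        called = degs[degs["is_deg"]]
        all_deg_ids |= set(called.index)
        comp_name = f"{genotype}c/s"
        links = integrate.identify_dmdegs(degs, assoc[comp_name])
        crosstab = integrate.direction_crosstab(links)
        entry = {
            "n_degs": int(len(called)),
            "n_up": int((called["direction"] == "up").sum()),
            "n_down": int((called["direction"] == "down").sum()),
            "n_dmdegs": int(links["feature_id"].nunique()) if len(links) else 0,
            "crosstab": {
                f"{r.context}:{r.region}:{r.direction}:{r.deg_direction}": int(r.n)
                for r in crosstab.itertuples()
            },
        }
        if len(manifest.planted_degs):
            entry["recovery"] = evaluate.deg_recovery(degs, manifest, genotype)
        summary["expression"][genotype] = entry
    if len(all_deg_ids) >= cfg.kmeans_k:
        assignment, _ = integrate.kmeans_clusters(
            dataset.expression, sorted(all_deg_ids), cfg.kmeans_k, seed, cfg
        )
        summary["kmeans_cluster_sizes"] = {
            int(k): int(v) for k, v in assignment.value_counts().sort_index().items()
        }
    timings["integrate"] = time.time() - t

    # ---- stage: smRNA / TE --------------------------------------------
    t = time.time()
    summary["smrna"] = {}
    chh_hyper_by_comp = {}
    for comp_name, table in dmr_tables.items():
        chh_hyper = table[(table["is_dmr"]) & (table["context"] == "CHH")
                          & (table["direction"] == "hyper")]
        hyper_assoc = annotate.associate_dmrs(chh_hyper, tes, config=cfg)
        hyper_ids = set(hyper_assoc.loc[hyper_assoc["region"] == "te_body", "feature_id"])
        chh_hyper_by_comp[comp_name] = tes[tes["id"].isin(hyper_ids)]
    for sample in SAMPLES:
        reads = dataset.smrnas[sample]
        entry = {"size_distribution": {
            int(k): float(v) for k, v in smrna.size_distribution(reads).items()
        }}
        comp_name = "SSc/s" if sample.startswith("SS") else "STc/s"
        hyper_tes = chh_hyper_by_comp[comp_name]
        if len(hyper_tes) and len(tes):
            cmp = smrna.compare_density(hyper_tes, tes, reads, 24, cfg)
            entry["chh_hyper_density"] = cmp
            reads24 = reads[(reads["length"] == 24)]
            assoc_ids = smrna.smrna_associated_tes(reads24, hyper_tes, 24)
            if assoc_ids:
                mat = smrna.base_frequency_matrix(smrna.reads_on_tes(reads24, hyper_tes), 24)
                entry["ct_3prime_freq"] = float(mat.loc["C", 24] + mat.loc["T", 24])
        if manifest.smrna_target_tes:
            target = tes[tes["id"].isin(manifest.smrna_target_tes)]
            rest = tes[~tes["id"].isin(manifest.smrna_target_tes)]
            if len(target) and len(rest):
                entry["target_enrichment"] = smrna.compare_density(target, rest, reads, 24, cfg)
                on_target = smrna.reads_on_tes(reads[reads["length"] == 24], target)
                if len(on_target):
                    mat = smrna.base_frequency_matrix(on_target, 24)
                    entry["target_ct_3prime_freq"] = float(mat.loc["C", 24] + mat.loc["T", 24])
        summary["smrna"][sample] = entry
    # TE-frequency enrichment in gene sets (representative SS comparison)
    degs_ss = deg_tables["SS"]
    dmdeg_ids = set(integrate.identify_dmdegs(degs_ss, assoc["SSc/s"])["feature_id"])
    gene_sets = {
        "PCGs": genes,
        "DEGs": genes[genes["id"].isin(degs_ss.index[degs_ss["is_deg"]])],
        "dmDEGs": genes[genes["id"].isin(dmdeg_ids)],
    }
    freqs, pairs = smrna.te_frequency_enrichment(gene_sets, tes, calls["SS-S"], config=cfg)
    summary["te_frequency"] = {
        "frequencies": {r.set: {"n_genes": int(r.n_genes), "frequency": float(r.frequency)}
                        for r in freqs.itertuples()},
        "fisher": {f"{r.set_a}|{r.set_b}": {"odds_ratio": float(r.odds_ratio),
                                            "p": float(r.p_value)}
                   for r in pairs.itertuples()},
    }
    timings["smrna"] = time.time() - t

    summary = _round_floats(summary)
    if outdir is not None and write_outputs:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        manifest.to_json(outdir / "truth_manifest.json")
        for comp_name, table in dmr_tables.items():
            safe = comp_name.replace("/", "_")
            table[table["is_dmr"]].to_csv(outdir / f"dmrs_{safe}.tsv", sep="\t", index=False)
            assoc[comp_name].to_csv(outdir / f"dmr_associations_{safe}.tsv", sep="\t", index=False)
        for genotype, degs in deg_tables.items():
            degs[degs["is_deg"]].to_csv(outdir / f"degs_{genotype}.tsv", sep="\t")
        run_manifest = {
            "seed": seed,
            "analysis_config": config_to_dict(cfg),
            "simulation_config": config_to_dict(sim_cfg),
            "timings_s": {k: round(v, 2) for k, v in timings.items()},
            "outputs": sorted(p.name for p in outdir.iterdir()),
            "summary_sha256": hashlib.sha256(
                (outdir / "summary.json").read_bytes()
            ).hexdigest(),
        }
        (outdir / "run_manifest.json").write_text(json.dumps(run_manifest, indent=1))
    return summary

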