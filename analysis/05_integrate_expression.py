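"""DEG calling, k-means clustering, dmDEG intersection (Fig-3-style).

Calls DEGs per genotype (|FC| >= 1.5, p <= 0.05 on log2(x+1) replicate
values), clusters the DEG union into five k-means expression clusters,
intersects DEGs with DMR associations into dmDEGs, and tabulates the
direction cross-tab (context x region x DMR direction x DEG direction)
plus the CG/CHG/CHH level-difference correlations.
"""

from pathlib import Path

import pandas as pd

from methylscape import annotate, dmr, integrate
from methylscape import io as msio
from methylscape.config import GENOTYPES, AnalysisConfig
from methylscape.simulate import CONTROL_CHROM

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"


def main() -> None:
    if not SIM.exists():
        raise SystemExit("scratch/sim not found - run analysis/01_simulate.py first")
    cfg = AnalysisConfig()
    expression = msio.read_expression_table(SIM / "expression.tsv")
    features = msio.read_features(SIM / "features.gff3")
    genes = features[features["kind"] == "gene"]
    all_deg_ids: set[str] = set()
    for genotype in GENOTYPES:
        ctrl, stress = f"{genotype}-C", f"{genotype}-S"
        reports = {
            s: msio.read_cytosine_report(SIM / f"cx_report_{s}.tsv.gz") for s in (ctrl, stress)
        }
        reports = {s: r[r["chrom"] != CONTROL_CHROM] for s, r in reports.items()}
        degs = integrate.call_degs(expression, genotype, cfg)
        called = degs[degs["is_deg"]]
        all_deg_ids |= set(called.index)
        dmr_table = pd.read_csv(
            ROOT / "scratch" / "derived" / f"dmrs_{genotype}c_s.tsv", sep="\t"
        )
        assoc = annotate.associate_dmrs(dmr_table, features, config=cfg)
        links = integrate.identify_dmdegs(degs, assoc)
        n_dmdeg = links["feature_id"].nunique() if len(links) else 0
        print(f"{genotype}: {len(called)} DEGs ({(called['direction'] == 'up').sum()} up, "
              f"{(called['direction'] == 'down').sum()} down); {n_dmdeg} dmDEGs")
        crosstab = integrate.direction_crosstab(links)
        crosstab.to_csv(ROOT / "results" / f"dmdeg_crosstab_{genotype}.tsv",
                        sep="\t", index=False)
        corr = integrate.context_correlation(reports[ctrl], reports[stress], genes, cfg)
        corr.to_csv(ROOT / "results" / f"context_correlation_{genotype}.tsv",
                    sep="\t", index=False)
        body = corr[corr["compartment"] == "gene_body"]
        print("  gene-body context correlations: "
              + ", ".join(f"r({r.context_a},{r.context_b})={r.r:.2f}"
                          for r in body.itertuples()))
    assignment, profiles = integrate.kmeans_clusters(expression, sorted(all_deg_ids),
                                                     cfg.kmeans_k, seed=11)
    print("k-means cluster sizes:", assignment.value_counts().sort_index().to_dict())
    profiles.to_csv(ROOT / "results" / "deg_cluster_profiles.tsv", sep="\t")
    print("wrote dmDEG cross-tabs, context correlations, cluster profiles under results/")


if __name__ == "__main__":
    main()
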