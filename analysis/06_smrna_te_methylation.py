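"""Small-RNA-directed TE hypermethylation analysis (Fig-4-style).

Quantifies 24-nt smRNA size distributions and per-kb densities over
CHH-hypermethylated TEs vs all TEs (Wilcoxon), the CWA/non-CWA CHH
sub-context density split by smRNA association, methylated-TE frequency
in PCG/DEG/dmDEG gene sets (Fisher), and the 3'-end base composition of
24-nt reads on hypermethylated TEs.
"""

from pathlib import Path

import pandas as pd

from methylscape import annotate, dmr, integrate, methylome, smrna
from methylscape import io as msio
from methylscape.config import SAMPLES, AnalysisConfig
from methylscape.simulate import CONTROL_CHROM

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"


def main() -> None:
    if not SIM.exists():
        raise SystemExit("scratch/sim not found - run analysis/01_simulate.py first")
    cfg = AnalysisConfig()
    features = msio.read_features(SIM / "features.gff3")
    genes = features[features["kind"] == "gene"]
    tes = features[features["kind"] == "TE"]
    calls = {}
    for sample in SAMPLES:
        rep = msio.read_cytosine_report(SIM / f"cx_report_{sample}.tsv.gz")
        est = methylome.estimate_conversion_error(rep[rep["chrom"] == CONTROL_CHROM])
        calls[sample] = methylome.call_methylcytosines(
            rep[rep["chrom"] != CONTROL_CHROM], est.error_rate, cfg
        )
    dmr_ss = pd.read_csv(ROOT / "scratch" / "derived" / "dmrs_SSc_s.tsv", sep="\t")
    chh_hyper = dmr_ss[(dmr_ss["context"] == "CHH") & (dmr_ss["direction"] == "hyper")]
    hyper_assoc = annotate.associate_dmrs(chh_hyper, tes, config=cfg)
    hyper_ids = set(hyper_assoc.loc[hyper_assoc["region"] == "te_body", "feature_id"])
    hyper_tes = tes[tes["id"].isin(hyper_ids)]
    print(f"{len(hyper_tes)} CHH-hypermethylated TEs (SSc/s) of {len(tes)} total")

    for sample in ("SS-C", "SS-S"):
        reads = msio.read_smrna_bed(SIM / f"smrna_{sample}.bed")
        dist = smrna.size_distribution(reads)
        print(f"{sample}: 24-nt fraction {dist.get(24, 0):.2f} "
              f"(argmax length {int(dist.idxmax())})")
        cmp = smrna.compare_density(hyper_tes, tes, reads, 24, cfg)
        print(f"  24-nt density: CHH-hyper TEs {cmp['aggregate_focus']:.2f}/kb vs all TEs "
              f"{cmp['aggregate_reference']:.2f}/kb (Wilcoxon p = {cmp['p_value']:.2e})")

    reads_s = msio.read_smrna_bed(SIM / "smrna_SS-S.bed")
    assoc_ids = smrna.smrna_associated_tes(reads_s[reads_s["length"] == 24], hyper_tes, 24)
    te_sets = {
        "associated": hyper_tes[hyper_tes["id"].isin(assoc_ids)],
        "not_associated": hyper_tes[~hyper_tes["id"].isin(assoc_ids)],
    }
    split = smrna.cwa_split_density(te_sets, {s: calls[s] for s in ("SS-C", "SS-S")})
    split.to_csv(ROOT / "results" / "cwa_split_density.tsv", sep="\t", index=False)
    noncwa = split[split["stratum"] == "CHH:non-CWA"].set_index(["group", "sample"])["density"]
    print("non-CWA CHH density (stress): associated "
          f"{noncwa.get(('associated', 'SS-S'), float('nan')):.3f} vs not associated "
          f"{noncwa.get(('not_associated', 'SS-S'), float('nan')):.3f}")

    expression = msio.read_expression_table(SIM / "expression.tsv")
    degs = integrate.call_degs(expression, "SS", cfg)
    assoc_all = annotate.associate_dmrs(dmr_ss, features, config=cfg)
    dmdeg_ids = set(integrate.identify_dmdegs(degs, assoc_all)["feature_id"])
    gene_sets = {
        "PCGs": genes,
        "DEGs": genes[genes["id"].isin(degs.index[degs["is_deg"]])],
        "dmDEGs": genes[genes["id"].isin(dmdeg_ids)],
    }
    freqs, pairs = smrna.te_frequency_enrichment(gene_sets, tes, calls["SS-S"], config=cfg)
    print("methylated-TE frequency per gene set:")
    print(freqs.to_string(index=False))
    print("pairwise Fisher tests:")
    print(pairs.to_string(index=False))
    freqs.to_csv(ROOT / "results" / "te_frequency.tsv", sep="\t", index=False)

    on_hyper = smrna.reads_on_tes(reads_s[reads_s["length"] == 24], hyper_tes)
    if len(on_hyper):
        mat = smrna.base_frequency_matrix(on_hyper, 24)
        ct = float(mat.loc["C", 24] + mat.loc["T", 24])
        print(f"C+T frequency at 3' position 24 on hyper-TE reads: {ct:.3f}")
        mat.to_csv(ROOT / "results" / "base_frequency_24nt.tsv", sep="\t")
    print("wrote results/cwa_split_density.tsv, te_frequency.tsv, base_frequency_24nt.tsv")


if __name__ == "__main__":
    main()
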