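"""Call methylcytosines and summarize the global methylome (Fig-1-style).

Reads the simulated cytosine reports from scratch/sim (run
01_simulate.py first), estimates each library's bisulfite conversion
error on the control chromosome, calls mCs by the binomial test
(p <= 1e-4, coverage >= 3), and reports the per-context mC shares and
level distributions plus 100-kb chromosomal density tracks.
"""

from pathlib import Path

import pandas as pd

from methylscape import io as msio
from methylscape import methylome
from methylscape.config import SAMPLES, AnalysisConfig
from methylscape.simulate import CONTROL_CHROM

ROOT = Path(__file__).resolve().parents[1]
SIM = ROOT / "scratch" / "sim"


def main() -> None:
    if not SIM.exists():
        raise SystemExit("scratch/sim not found - run analysis/01_simulate.py first")
    cfg = AnalysisConfig()
    genome = msio.read_fasta(SIM / "genome.fa", control_chrom=CONTROL_CHROM)
    rows = []
    density_frames = []
    for sample in SAMPLES:
        report = msio.read_cytosine_report(SIM / f"cx_report_{sample}.tsv.gz")
        control = report[report["chrom"] == CONTROL_CHROM]
        est = methylome.estimate_conversion_error(control)
        calls = methylome.call_methylcytosines(
            report[report["chrom"] != CONTROL_CHROM], est.error_rate, cfg
        )
        comp = methylome.context_composition(calls)
        print(f"{sample}: conversion error {est.error_rate:.5f} "
              f"(efficiency {100 * est.efficiency:.2f}%), {comp['n_mc']} mCs; "
              f"shares CG/CHG/CHH = "
              + "/".join(f"{100 * comp['shares'][c]:.1f}%" for c in ("CG", "CHG", "CHH")))
        for ctx, lv in comp["levels"].items():
            rows.append((sample, ctx, comp["shares"][ctx], lv["mean"], lv["median"], lv["n"]))
        dens = methylome.chromosomal_density(calls, genome, cfg.density_window)
        dens.insert(0, "sample", sample)
        density_frames.append(dens)
    out = pd.DataFrame(rows, columns=["sample", "context", "mc_share", "level_mean",
                                      "level_median", "n_mc"])
    out.to_csv(ROOT / "results" / "mc_composition.tsv", sep="\t", index=False)
    pd.concat(density_frames).to_csv(
        ROOT / "results" / "mc_density_100kb.tsv", sep="\t", index=False
    )
    print("wrote results/mc_composition.tsv and results/mc_density_100kb.tsv")


if __name__ == "__main__":
    main()
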