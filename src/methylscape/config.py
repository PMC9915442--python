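"""Analysis and simulation configuration.

`AnalysisConfig` carries every threshold the pipeline applies; the
defaults are the study's stated cutoffs (mC call p <= 1e-4 at coverage
>= 3 against the conversion-error rate; 100-bp bins with >= 3 cytosines
at >= 5 reads; 25% CG/CHG and 15% CHH level difference at q <= 0.01;
DEGs at |FC| >= 1.5 and p <= 0.05; 2-kb flanks; 100-kb density windows;
five k-means clusters).

`SimulationConfig` defines the synthetic four-sample study (two genotypes
x control/stress at ~30x coverage) that every recovery test runs on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    mc_pvalue_max: float = 1e-4
    min_coverage: int = 3
    bin_size: int = 100
    min_cytosines_per_bin: int = 3
    min_reads_per_cytosine: int = 5
    diff_min_cg_chg: float = 0.25
    diff_min_chh: float = 0.15
    q_max: float = 0.01
    deg_fold_change_min: float = 1.5
    deg_p_max: float = 0.05
    flank: int = 2000
    density_window: int = 100_000
    kmeans_k: int = 5
    n_body_bins: int = 40
    flank_bin_size: int = 100
    wilcoxon_exact_max: int = 12

    def __post_init__(self) -> None:
        for name in ("mc_pvalue_max", "min_coverage", "bin_size", "min_cytosines_per_bin",
                     "min_reads_per_cytosine", "q_max", "deg_fold_change_min", "deg_p_max",
                     "flank", "density_window", "kmeans_k"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("diff_min_cg_chg", "diff_min_chh"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in (0, 1)")

    def diff_min(self, context: str) -> float:
        return self.diff_min_chh if context == "CHH" else self.diff_min_cg_chg


@dataclass
class SimulationConfig:
    # genome
    n_chrom: int = 2
    chrom_length: int = 1_000_000
    control_chrom_length: int = 100_000
    # features
    n_genes: int = 200
    n_tes: int = 200
    te_in_gene_frac: float = 0.3
    gene_length_range: tuple[int, int] = (1000, 5000)
    te_length_range: tuple[int, int] = (300, 1500)
    # in-gene TEs pick their host gene with this weight for planted-DEG
    # genes (vs 1 otherwise): couples methylated-TE hosting to dmDEG status
    te_deg_host_weight: float = 40.0
    # methylome
    coverage: float = 30.0
    conversion_error: float = 0.005
    # (fraction of sites methylated, level when methylated): plant methylomes
    # are mosaics of essentially-on and essentially-off cytosines, so density
    # (mC / covered C) carries the compartment signal while per-mC levels
    # stay characteristic of the context (CG high, CHG mid, CHH low).
    p_background: dict = field(
        default_factory=lambda: {"CG": (0.30, 0.85), "CHG": (0.25, 0.75), "CHH": (0.01, 0.45)}
    )
    p_gene_body: dict = field(
        default_factory=lambda: {"CHG": (0.05, 0.75), "CHH": (0.005, 0.45)}
    )
    cg_gene_frac_range: tuple[float, float] = (0.20, 0.80)  # scaled by expression rank
    cg_level: float = 0.85
    p_te_body: dict = field(
        default_factory=lambda: {"CG": (0.45, 0.85), "CHG": (0.50, 0.75), "CHH": (0.55, 0.45)}
    )
    # planted DMRs
    n_dmrs_per_class: int = 60  # per context per direction, background plants
    dmr_levels: dict = field(
        default_factory=lambda: {"CG": (0.25, 0.65), "CHG": (0.25, 0.65), "CHH": (0.10, 0.35)}
    )
    n_target_tes: int = 50       # smRNA-targeted CHH-hypermethylated TEs
    n_hyper_only_tes: int = 30   # CHH-hypermethylated TEs with no smRNA targeting
    te_chh_shift: float = 0.25
    cwa_shift_frac: float = 0.4  # fraction of the CHH shift applied at CWA sites of target TEs
    # expression
    n_degs_per_genotype: int = 20  # half up, half down
    deg_fold_change: float = 3.0
    expression_cv: float = 0.1
    n_replicates: int = 2
    log_expr_mean: float = 3.0
    log_expr_sd: float = 1.0
    couple_promoter_chh: bool = True  # plant a CHH-hyper bin in up-DEG promoters
    # shared latent factor coupling CG/CHG gene-body stress shifts (off by default)
    gene_shift_sd: float = 0.0
    gene_shift_loading: float = 0.8
    # small RNA
    smrna_reads_per_kb: float = 1.0  # total unique-read background density per sample
    smrna_te_enrichment: float = 5.0
    smrna_stress_boost: float = 1.5
    smrna_length_probs: dict = field(
        default_factory=lambda: {20: 0.03, 21: 0.25, 22: 0.04, 23: 0.04, 24: 0.60, 25: 0.04}
    )
    smrna_3p_ct_bias: float = 0.8


SAMPLES = ("SS-C", "SS-S", "ST-C", "ST-S")
GENOTYPES = ("SS", "ST")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, tuple):
        return list(obj)
    return obj


def config_to_dict(cfg) -> dict:
    return _to_plain(cfg)


def load_config(path) -> tuple[AnalysisConfig, SimulationConfig]:
    """Load a YAML file with optional ``analysis:`` and ``simulation:`` sections."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    ana = raw.get("analysis", {})
    sim = raw.get("simulation", {})
    for key in ("gene_length_range", "te_length_range", "cg_gene_frac_range", "dmr_levels"):
        if key in sim:
            if key == "dmr_levels":
                sim[key] = {k: tuple(v) for k, v in sim[key].items()}
            else:
                sim[key] = tuple(sim[key])
    if "smrna_length_probs" in sim:
        sim["smrna_length_probs"] = {int(k): v for k, v in sim["smrna_length_probs"].items()}
    return AnalysisConfig(**ana), SimulationConfig(**sim)
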