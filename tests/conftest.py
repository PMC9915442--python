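"""Shared fixtures: the default synthetic study (used by the recovery
tests) is generated once per session, as is the SS stress-vs-control DMR
call set on it."""

import numpy as np
import pandas as pd
import pytest

from methylscape import dmr, methylome
from methylscape.config import AnalysisConfig, SimulationConfig
from methylscape.simulate import simulate_dataset

DEFAULT_SEED = 101
SMALL_SEED = 7

SMALL_CONFIG = SimulationConfig(
    n_chrom=1, chrom_length=300_000, control_chrom_length=60_000,
    n_genes=30, n_tes=40, n_dmrs_per_class=10, n_target_tes=8,
    n_hyper_only_tes=5, n_degs_per_genotype=10,
)


@pytest.fixture(scope="session")
def analysis_config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_dataset():
    """The full-scale study: 2 x 1 Mb chromosomes, ~30x coverage, planted
    DMRs/DEGs/smRNA-target TEs per the default configuration."""
    return simulate_dataset(seed=DEFAULT_SEED)


@pytest.fixture(scope="session")
def small_dataset():
    return simulate_dataset(SMALL_CONFIG, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def ss_dmr_calls(default_dataset, analysis_config):
    """DMR call tables for the SS stress-vs-control comparison, per context."""
    a = default_dataset.reports["SS-C"]
    b = default_dataset.reports["SS-S"]
    control = default_dataset.genome.control_chrom
    a = a[a["chrom"] != control]
    b = b[b["chrom"] != control]
    out = {}
    for context in ("CG", "CHG", "CHH"):
        bins = dmr.aggregate_bins(a, b, context, analysis_config)
        out[context] = dmr.call_dmrs(dmr.test_bins(bins), analysis_config)
    return out


@pytest.fixture(scope="session")
def ss_control_calls(default_dataset, analysis_config):
    """mC calls for the SS-C sample (error rate from the control chromosome)."""
    report = default_dataset.reports["SS-C"]
    control_chrom = default_dataset.genome.control_chrom
    est = methylome.estimate_conversion_error(report[report["chrom"] == control_chrom])
    return methylome.call_methylcytosines(
        report[report["chrom"] != control_chrom], est.error_rate, analysis_config
    )
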