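"""Differentially methylated 100-bp region detection.

The genome is tiled with disjoint fixed bins anchored at coordinate 0.
Within one sequence context, a bin is tested when both samples have at
least ``min_cytosines_per_bin`` cytosines covered by at least
``min_reads_per_cytosine`` reads.  Qualifying sites' counts are pooled
(read-weighted) per sample; the per-bin test is a two-sided Fisher's
exact test on the pooled 2x2 count table, with Benjamini-Hochberg
q-values computed across all tested bins of the context.  A DMR requires
q <= 0.01 and a pooled level difference of at least 25% (CG, CHG) or 15%
(CHH); hyper means higher methylation in stress than control.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig

BIN_COLUMNS = ["chrom", "start", "context", "n_sites_a", "n_sites_b",
               "meth_a", "unmeth_a", "meth_b", "unmeth_b", "level_a", "level_b", "tested"]


def aggregate_bins(
    sites_a: pd.DataFrame, sites_b: pd.DataFrame, context: str,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Pool per-cytosine counts of one context into the fixed bin grid.

    Sample A is the control, sample B the stress sample.  Both strands
    contribute; a cytosine belongs to the single bin containing its
    position.  Only qualifying cytosines (coverage >= threshold) are
    pooled, and a bin is flagged ``tested`` when both samples hold the
    minimum number of qualifying cytosines.
    """
    config = config or AnalysisConfig()
    chroms_a, chroms_b = set(sites_a["chrom"]), set(sites_b["chrom"])
    if chroms_a != chroms_b:
        raise ValueError(f"samples cover different chromosome sets: {chroms_a ^ chroms_b}")

    def pool(sites: pd.DataFrame) -> pd.DataFrame:
        sub = sites[sites["context"] == context].copy()
        cov = sub["n_meth"] + sub["n_unmeth"]
        sub = sub[cov >= config.min_reads_per_cytosine]
        if sub.empty:
            return pd.DataFrame(columns=["chrom", "start", "n_sites", "meth", "unmeth"])
        sub["start"] = (sub["pos"] // config.bin_size) * config.bin_size
        g = sub.groupby(["chrom", "start"], observed=True).agg(
            n_sites=("pos", "size"), meth=("n_meth", "sum"), unmeth=("n_unmeth", "sum")
        )
        return g.reset_index()

    a, b = pool(sites_a), pool(sites_b)
    bins = a.merge(b, on=["chrom", "start"], how="outer", suffixes=("_a", "_b"))
    for col in ("n_sites_a", "meth_a", "unmeth_a", "n_sites_b", "meth_b", "unmeth_b"):
        bins[col] = bins[col].fillna(0).astype(int)
    bins["context"] = context
    tot_a = bins["meth_a"] + bins["unmeth_a"]
    tot_b = bins["meth_b"] + bins["unmeth_b"]
    with np.errstate(invalid="ignore"):
        bins["level_a"] = np.where(tot_a > 0, bins["meth_a"] / np.maximum(tot_a, 1), np.nan)
        bins["level_b"] = np.where(tot_b > 0, bins["meth_b"] / np.maximum(tot_b, 1), np.nan)
    bins["tested"] = (
        (bins["n_sites_a"] >= config.min_cytosines_per_bin)
        & (bins["n_sites_b"] >= config.min_cytosines_per_bin)
        & (tot_a > 0) & (tot_b > 0)
    )
    return bins.sort_values(["chrom", "start"], ignore_index=True)[BIN_COLUMNS]


def fisher_exact_two_sided(meth_a: int, unmeth_a: int, meth_b: int, unmeth_b: int) -> float:
    """Two-sided Fisher's exact p for the pooled 2x2 table."""
    return float(stats.fisher_exact([[meth_a, unmeth_a], [meth_b, unmeth_b]])[1])


def test_bins(bins: pd.DataFrame) -> pd.DataFrame:
    """Fisher's exact p-value for every tested bin (NaN otherwise)."""
    out = bins.copy()
    p = np.full(len(out), np.nan)
    cols = out[["meth_a", "unmeth_a", "meth_b", "unmeth_b"]].to_numpy()
    for i in np.flatnonzero(out["tested"].to_numpy()):
        ma, ua, mb, ub = cols[i]
        p[i] = fisher_exact_two_sided(ma, ua, mb, ub)
    out["p_value"] = p
    return out


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def call_dmrs(bins: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """BH-correct tested bins (within this context) and apply the level-
    difference and q-value gates.  Returns the tested bins with ``diff``,
    ``q_value``, ``is_dmr`` and ``direction`` columns."""
    config = config or AnalysisConfig()
    if "p_value" not in bins.columns:
        bins = test_bins(bins)
    out = bins[bins["tested"]].copy()
    if out.empty:
        out["diff"] = out["q_value"] = pd.Series(dtype=float)
        out["is_dmr"] = pd.Series(dtype=bool)
        out["direction"] = pd.Series(dtype=object)
        return out
    contexts = out["context"].unique()
    if len(contexts) != 1:
        raise ValueError("call_dmrs expects bins of a single context")
    thresh = config.diff_min(contexts[0])
    out["diff"] = out["level_b"] - out["level_a"]
    out["q_value"] = bh_qvalues(out["p_value"].to_numpy())
    out["is_dmr"] = (out["q_value"] <= config.q_max) & (out["diff"].abs() >= thresh)
    out["direction"] = np.where(out["diff"] > 0, "hyper", "hypo")
    return out.reset_index(drop=True)


def dmr_counts(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Per-direction DMR tallies (the stacked-bar counts of a context)."""
    sub = dmrs[dmrs["is_dmr"]]
    return (
        sub.groupby(["context", "direction"], observed=True).size()
        .rename("n_dmrs").reset_index()
    )


def level_difference_distribution(
    diffs: np.ndarray, grid_size: int = 512
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density of DMR level differences on [-1, 1].

    Returns (grid, density); empty arrays when fewer than 2 DMRs.  A
    degenerate (zero-variance) input yields a narrow Gaussian spike at
    the common value.
    """
    diffs = np.asarray(diffs, dtype=float)
    grid = np.linspace(-1, 1, grid_size)
    if len(diffs) < 2:
        return np.array([]), np.array([])
    if np.ptp(diffs) == 0:
        dens = stats.norm.pdf(grid, loc=diffs[0], scale=0.01)
    else:
        dens = stats.gaussian_kde(diffs)(grid)
    return grid, dens
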