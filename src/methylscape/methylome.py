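"""Methylcytosine calling and global methylome statistics.

A cytosine is called methylated (mC) by a one-sided binomial test of its
methylated read count against the bisulfite conversion-error rate:
p = P(X >= n_meth | n, error).  Sites pass at p <= 1e-4 with coverage
>= 3 (defaults).  The error rate itself is the pooled methylated-read
fraction on a biologically unmethylated control sequence (chloroplast).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .config import AnalysisConfig
from .genome import CONTEXTS, GenomeAssembly


@dataclass
class ConversionEstimate:
    error_rate: float
    efficiency: float
    ci_low: float
    ci_high: float
    n_meth: int
    n_total: int


def estimate_conversion_error(control_sites: pd.DataFrame) -> ConversionEstimate:
    """Pooled error rate sum(n_meth)/sum(coverage) over control-chromosome
    sites, with a Wilson binomial confidence interval."""
    n_meth = int(control_sites["n_meth"].sum())
    n_total = n_meth + int(control_sites["n_unmeth"].sum())
    if n_total == 0:
        raise ValueError("control sites have zero total coverage")
    rate = n_meth / n_total
    lo, hi = proportion_confint(n_meth, n_total, alpha=0.05, method="wilson")
    return ConversionEstimate(rate, 1.0 - rate, float(lo), float(hi), n_meth, n_total)


def call_methylcytosines(
    sites: pd.DataFrame, error_rate: float, config: AnalysisConfig | None = None
) -> pd.DataFrame:
    """Binomial mC calls on a per-cytosine report.

    Adds ``coverage``, ``level``, ``p_value`` and ``is_mc``.  p-values are
    only computed at coverage >= min_coverage (the coverage filter
    precedes testing); below it sites are kept with is_mc=False and NaN p.
    """
    config = config or AnalysisConfig()
    if not 0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    calls = sites.copy()
    cov = (calls["n_meth"] + calls["n_unmeth"]).to_numpy()
    calls["coverage"] = cov
    with np.errstate(invalid="ignore", divide="ignore"):
        calls["level"] = np.where(cov > 0, calls["n_meth"] / np.maximum(cov, 1), np.nan)
    testable = cov >= config.min_coverage
    p = np.full(len(calls), np.nan)
    m = calls["n_meth"].to_numpy()[testable]
    n = cov[testable]
    p[testable] = stats.binom.sf(m - 1, n, error_rate)
    calls["p_value"] = p
    calls["is_mc"] = testable & (p <= config.mc_pvalue_max)
    return calls


def context_composition(calls: pd.DataFrame) -> dict:
    """Per-context share of mCs and level summaries over mC sites.

    Returns shares over {CG, CHG, CHH} (summing to 1 of all mCs), per-
    context level quartiles/means, and per-strand mean levels.  Empty if
    the sample has no mCs.
    """
    mc = calls[calls["is_mc"]]
    if mc.empty:
        return {"n_mc": 0, "shares": {}, "levels": {}, "strand_means": {}}
    counts = mc.groupby("context", observed=False).size().reindex(CONTEXTS, fill_value=0)
    shares = (counts / counts.sum()).to_dict()
    levels = {}
    for ctx, sub in mc.groupby("context", observed=True):
        q = sub["level"].quantile([0.25, 0.5, 0.75])
        levels[str(ctx)] = {
            "mean": float(sub["level"].mean()),
            "q25": float(q.loc[0.25]), "median": float(q.loc[0.5]), "q75": float(q.loc[0.75]),
            "n": int(len(sub)),
        }
    strand_means = {
        f"{ctx}:{strand}": float(sub["level"].mean())
        for (ctx, strand), sub in mc.groupby(["context", "strand"], observed=True)
    }
    return {"n_mc": int(len(mc)), "shares": {str(k): float(v) for k, v in shares.items()},
            "levels": levels, "strand_means": strand_means}


def chromosomal_density(
    calls: pd.DataFrame, genome: GenomeAssembly, window: int | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """mC counts in fixed windows tiling each chromosome, per context and
    strand.  The final partial window is retained and flagged."""
    config = config or AnalysisConfig()
    window = window or config.density_window
    if window <= 0:
        raise ValueError("window must be positive")
    mc = calls[calls["is_mc"]]
    rows = []
    for chrom, L in genome.chrom_lengths.items():
        sub = mc[mc["chrom"] == chrom]
        starts = np.arange(0, L, window)
        grouped = sub.groupby(
            [sub["pos"] // window, "context", "strand"], observed=False
        ).size()
        for w, ws in enumerate(starts):
            we = min(ws + window, L)
            for ctx in CONTEXTS:
                for strand in "+-":
                    rows.append(
                        (chrom, int(ws), int(we), ctx, strand,
                         int(grouped.get((w, ctx, strand), 0)), we - ws < window)
                    )
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "context", "strand", "n_mc", "partial"]
    )
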