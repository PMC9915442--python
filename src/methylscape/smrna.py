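"""Small-RNA / transposable-element methylation analysis.

Quantifies the RdDM signature: 24-nt (and 21-nt) small-RNA density per
kb of TE, enrichment over CHH-hypermethylated TEs (Wilcoxon rank-sum),
the CWA (CAA/CTA, CMT2) versus non-CWA (DRM/RdDM) CHH sub-context
density split by smRNA association, methylated-TE frequency in gene
sets (Fisher's exact), and positional base-frequency matrices of 24-nt
reads (the 3'-end C/T signature of AGO4 loading).
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .genome import CWA_TRINUCLEOTIDES


def collapse_reads(raw_sequences: list[str]) -> pd.DataFrame:
    """Collapse identical sequences into unique reads with multiplicities."""
    counts = Counter(raw_sequences)
    return pd.DataFrame(
        {"sequence": list(counts), "count": list(counts.values())}
    ).sort_values("sequence", ignore_index=True)


def size_distribution(reads: pd.DataFrame) -> pd.Series:
    """Read-length histogram weighted by collapsed counts, as fractions."""
    if reads.empty:
        return pd.Series(dtype=float, name="fraction")
    total = reads.groupby("length")["count"].sum()
    return (total / total.sum()).rename("fraction")


def te_smrna_density(
    reads: pd.DataFrame, tes: pd.DataFrame, length: int | None = None
) -> tuple[pd.DataFrame, float]:
    """Per-TE and aggregate smRNA density (collapsed counts per kb of TE body).

    A read associates with a TE when its midpoint lies inside the TE
    body.  The aggregate pools counts over the set: sum(counts) /
    sum(TE lengths in kb).
    """
    if tes.empty:
        raise ValueError("empty TE set: density undefined")
    sub = reads if length is None else reads[reads["length"] == length]
    per_te = pd.Series(0.0, index=tes["id"].to_numpy())
    counts = pd.Series(0, index=tes["id"].to_numpy(), dtype=int)
    for chrom, rsub in sub.groupby("chrom", observed=True):
        tsub = tes[tes["chrom"] == chrom].sort_values("start")
        if tsub.empty:
            continue
        mids = ((rsub["start"] + rsub["end"]) // 2).to_numpy()
        starts, ends = tsub["start"].to_numpy(), tsub["end"].to_numpy()
        j = np.searchsorted(starts, mids, side="right") - 1
        ok = (j >= 0) & (mids < ends[np.clip(j, 0, None)])
        if ok.any():
            hits = pd.Series(rsub["count"].to_numpy()[ok]).groupby(
                tsub["id"].to_numpy()[j[ok]]
            ).sum()
            counts.loc[hits.index] += hits
    kb = (tes["end"] - tes["start"]).to_numpy() / 1000
    per_te = pd.DataFrame(
        {"id": tes["id"].to_numpy(), "n_reads": counts.to_numpy(),
         "length_kb": kb, "density": counts.to_numpy() / kb}
    )
    aggregate = float(per_te["n_reads"].sum() / per_te["length_kb"].sum())
    return per_te, aggregate


def rank_sum_test(x, y, exact_max: int = 12) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration over all rank splits (mid-ranks for ties) when both
    groups have at most ``exact_max`` observations; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if len(x) <= exact_max and len(y) <= exact_max:
        pooled = np.concatenate([x, y])
        ranks = stats.rankdata(pooled)
        w_obs = ranks[: len(x)].sum()
        mu = len(x) * ranks.mean()
        dev = abs(w_obs - mu)
        hits = total = 0
        for comb in combinations(range(len(pooled)), len(x)):
            w = sum(ranks[i] for i in comb)
            total += 1
            if abs(w - mu) >= dev - 1e-9:
                hits += 1
        return hits / total
    return float(stats.mannwhitneyu(x, y, alternative="two-sided",
                                    method="asymptotic", use_continuity=False).pvalue)


def compare_density(
    focus_tes: pd.DataFrame, reference_tes: pd.DataFrame, reads: pd.DataFrame,
    length: int = 24, config: AnalysisConfig | None = None,
) -> dict:
    """Per-kb smRNA density of a focal TE set against a reference set with
    a two-sided rank-sum test on the per-TE densities.

    The headline comparison is CHH-hypermethylated TEs against all TEs;
    any two non-empty sets work (e.g. targets vs the disjoint rest for a
    null calibration).
    """
    config = config or AnalysisConfig()
    per_a, agg_a = te_smrna_density(reads, focus_tes, length)
    per_b, agg_b = te_smrna_density(reads, reference_tes, length)
    p = rank_sum_test(per_a["density"], per_b["density"], config.wilcoxon_exact_max)
    return {
        "aggregate_focus": agg_a, "aggregate_reference": agg_b,
        "ratio": agg_a / agg_b if agg_b > 0 else np.inf,
        "mean_focus": float(per_a["density"].mean()),
        "mean_reference": float(per_b["density"].mean()),
        "p_value": p, "n_focus": len(per_a), "n_reference": len(per_b),
    }


def smrna_associated_tes(reads: pd.DataFrame, tes: pd.DataFrame, length: int = 24) -> set[str]:
    """TE ids with >= 1 overlapping unique read of the given length
    (midpoint-in-body rule, regardless of count)."""
    per_te, _ = te_smrna_density(reads, tes, length)
    return set(per_te.loc[per_te["n_reads"] > 0, "id"])


def _te_site_mask(sites: pd.DataFrame, tes: pd.DataFrame) -> np.ndarray:
    mask = np.zeros(len(sites), dtype=bool)
    pos = sites["pos"].to_numpy()
    for chrom, idx in sites.groupby("chrom", observed=True).indices.items():
        tsub = tes[tes["chrom"] == chrom].sort_values("start")
        if tsub.empty:
            continue
        p = pos[idx]
        starts, ends = tsub["start"].to_numpy(), tsub["end"].to_numpy()
        j = np.searchsorted(starts, p, side="right") - 1
        ok = (j >= 0) & (p < ends[np.clip(j, 0, None)])
        mask[idx] = ok
    return mask


def cwa_split_density(
    te_sets: dict[str, pd.DataFrame], calls_by_sample: dict[str, pd.DataFrame],
) -> pd.DataFrame:
    """Methylation density per (TE group x sample x context stratum).

    For each named TE group (e.g. "associated" / "not_associated") and
    sample, computes called-mC / covered-cytosine densities for the CHH
    CWA and non-CWA sub-contexts and for CG and CHG, within TE bodies.
    Strata with zero covered sites get NaN density and a flag.
    """
    rows = []
    for group, tes in te_sets.items():
        for sample, calls in calls_by_sample.items():
            body = calls[_te_site_mask(calls, tes)]
            covered = body[body["coverage"] >= 1]
            chh = covered[covered["context"] == "CHH"]
            cwa_mask = chh["trinucleotide"].isin(CWA_TRINUCLEOTIDES)
            strata = {
                "CHH:CWA": chh[cwa_mask], "CHH:non-CWA": chh[~cwa_mask],
                "CG": covered[covered["context"] == "CG"],
                "CHG": covered[covered["context"] == "CHG"],
            }
            for name, sub in strata.items():
                n_cov = len(sub)
                n_mc = int(sub["is_mc"].sum())
                rows.append((group, sample, name, n_mc, n_cov,
                             n_mc / n_cov if n_cov else np.nan, n_cov == 0))
    return pd.DataFrame(
        rows, columns=["group", "sample", "stratum", "n_mc", "n_covered", "density", "undefined"]
    )


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    odds, p = stats.fisher_exact([[a, b], [c, d]])
    return float(odds), float(p)


def te_frequency_enrichment(
    gene_sets: dict[str, pd.DataFrame], tes: pd.DataFrame, calls: pd.DataFrame,
    flank: int | None = None, config: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Frequency of genes harboring a methylated TE, per gene set, with
    pairwise Fisher tests between sets.

    A TE is methylated when its body contains >= 1 called mC; a gene
    harbors a TE when the TE body overlaps the gene +/- flank window.
    Empty sets are skipped.
    """
    config = config or AnalysisConfig()
    flank = config.flank if flank is None else flank
    mc_sites = calls[calls["is_mc"]]
    meth_te_mask = np.zeros(len(tes), dtype=bool)
    for i, te in enumerate(tes.itertuples()):
        sub = mc_sites[mc_sites["chrom"] == te.chrom]
        pos = sub["pos"].to_numpy()
        if ((pos >= te.start) & (pos < te.end)).any():
            meth_te_mask[i] = True
    mtes = tes[meth_te_mask]
    freq_rows = []
    harboring: dict[str, set] = {}
    for name, genes in gene_sets.items():
        if genes.empty:
            continue
        harb = set()
        for g in genes.itertuples():
            sub = mtes[mtes["chrom"] == g.chrom]
            if ((sub["end"].to_numpy() > g.start - flank)
                    & (sub["start"].to_numpy() < g.end + flank)).any():
                harb.add(g.id)
        harboring[name] = harb
        freq_rows.append((name, len(genes), len(harb), len(harb) / len(genes)))
    freqs = pd.DataFrame(freq_rows, columns=["set", "n_genes", "n_harboring", "frequency"])
    pair_rows = []
    names = freqs["set"].tolist()
    for a, b in combinations(names, 2):
        na = int(freqs.loc[freqs["set"] == a, "n_genes"].iloc[0])
        nb = int(freqs.loc[freqs["set"] == b, "n_genes"].iloc[0])
        ha, hb = len(harboring[a]), len(harboring[b])
        odds, p = fisher_exact_2x2(ha, na - ha, hb, nb - hb)
        pair_rows.append((a, b, odds, p))
    pairs = pd.DataFrame(pair_rows, columns=["set_a", "set_b", "odds_ratio", "p_value"])
    return freqs, pairs


def base_frequency_matrix(reads: pd.DataFrame, length: int = 24) -> pd.DataFrame:
    """4 x length positional base-frequency matrix of equal-length reads,
    weighted by collapsed counts; every column sums to 1."""
    if reads.empty:
        raise ValueError("no reads")
    if (reads["length"] != length).any():
        raise ValueError(f"all reads must be exactly {length} nt")
    mat = np.zeros((4, length), dtype=float)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq, count in zip(reads["sequence"], reads["count"]):
        for j, b in enumerate(seq):
            mat[base_idx[b], j] += count
    mat /= mat.sum(axis=0, keepdims=True)
    return pd.DataFrame(mat, index=["A", "C", "G", "T"], columns=range(1, length + 1))


def reads_on_tes(reads: pd.DataFrame, tes: pd.DataFrame) -> pd.DataFrame:
    """Reads whose midpoint lies in a TE body of the set."""
    keep = np.zeros(len(reads), dtype=bool)
    mids = ((reads["start"] + reads["end"]) // 2).to_numpy()
    chroms = reads["chrom"].to_numpy()
    for chrom in np.unique(chroms):
        tsub = tes[tes["chrom"] == chrom].sort_values("start")
        if tsub.empty:
            continue
        m = chroms == chrom
        starts, ends = tsub["start"].to_numpy(), tsub["end"].to_numpy()
        j = np.searchsorted(starts, mids[m], side="right") - 1
        keep[m] = (j >= 0) & (mids[m] < ends[np.clip(j, 0, None)])
    return reads[keep]
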