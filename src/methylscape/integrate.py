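"""Differential expression and methylation-expression integration.

DEGs are called per genotype between stress and control with a pooled-
variance two-sample t-test on log2(x+1) replicate values (at two
replicates per condition a pooled test keeps its nominal degrees of
freedom, where an unequal-variance test loses essentially all power);
the gates are the standard ones: p <= 0.05 and fold change >= 1.5 (or
<= 1/1.5), the fold change computed on replicate means with a
pseudo-count of 1.  DEGs are
clustered by k-means (k = 5) on z-scored group-mean profiles.  A dmDEG
is a DEG with at least one associated DMR in its promoter, gene body or
downstream flank; cross-tabulating dmDEGs over context x region x DMR
direction x DEG direction gives the direction structure, and per-gene
level differences give the CG/CHG/CHH inter-context correlations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .config import GENOTYPES, SAMPLES, AnalysisConfig


def sample_columns(expression: pd.DataFrame, group: str) -> list[str]:
    cols = [c for c in expression.columns if c == group or c.startswith(group + "_")]
    if not cols:
        raise ValueError(f"no expression columns for sample group {group!r}")
    return cols


def call_degs(
    expression: pd.DataFrame, genotype: str, config: AnalysisConfig | None = None,
    control_group: str | None = None, stress_group: str | None = None,
) -> pd.DataFrame:
    """t-test DEG calling for one genotype's stress-vs-control contrast.

    ``control_group``/``stress_group`` override the default
    ``{genotype}-C`` vs ``{genotype}-S`` pairing (the genotype-vs-genotype
    contrast is the same operation with different columns).
    """
    config = config or AnalysisConfig()
    control_group = control_group or f"{genotype}-C"
    stress_group = stress_group or f"{genotype}-S"
    xc = expression[sample_columns(expression, control_group)].to_numpy(dtype=float)
    xs = expression[sample_columns(expression, stress_group)].to_numpy(dtype=float)
    if xc.shape[1] < 2 or xs.shape[1] < 2:
        raise ValueError(
            "DEG calling needs >= 2 replicates per condition; for an "
            "unreplicated design use a fold-change-only screen explicitly"
        )
    if (xc < 0).any() or (xs < 0).any():
        raise ValueError("expression values must be non-negative")
    mean_c, mean_s = xc.mean(axis=1), xs.mean(axis=1)
    fc = (mean_s + 1.0) / (mean_c + 1.0)
    with np.errstate(invalid="ignore"):
        t = stats.ttest_ind(np.log2(xs + 1), np.log2(xc + 1), axis=1, equal_var=True)
    p = np.where(np.isnan(t.pvalue), 1.0, t.pvalue)
    out = pd.DataFrame(
        {"gene_id": expression.index, "genotype": genotype,
         "mean_control": mean_c, "mean_stress": mean_s,
         "fold_change": fc, "log2fc": np.log2(fc), "p_value": p}
    ).set_index("gene_id")
    out["is_deg"] = (out["p_value"] <= config.deg_p_max) & (
        (out["fold_change"] >= config.deg_fold_change_min)
        | (out["fold_change"] <= 1.0 / config.deg_fold_change_min)
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def kmeans_clusters(
    expression: pd.DataFrame, deg_ids: list[str], k: int | None = None, seed: int = 0,
    config: AnalysisConfig | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """K-means over z-scored 4-group mean profiles of the DEG union.

    Returns (gene -> cluster label Series, per-cluster mean profiles).
    Deterministic for a given seed (k-means++ with 100 restarts).
    """
    config = config or AnalysisConfig()
    k = k or config.kmeans_k
    ids = pd.Index(sorted(set(deg_ids)))
    if len(ids) < k:
        raise ValueError(f"{len(ids)} genes < k={k} clusters")
    groups = pd.DataFrame(
        {g: expression.loc[ids, sample_columns(expression, g)].mean(axis=1) for g in SAMPLES}
    )
    z = groups.sub(groups.mean(axis=1), axis=0)
    sd = groups.std(axis=1, ddof=0).replace(0, 1.0)
    z = z.div(sd, axis=0)
    km = KMeans(n_clusters=k, n_init=100, random_state=int(seed) % (2**31), init="k-means++")
    labels = km.fit_predict(z.to_numpy())
    assignment = pd.Series(labels, index=ids, name="cluster")
    profiles = z.groupby(assignment).mean()
    return assignment, profiles


def identify_dmdegs(degs: pd.DataFrame, associations: pd.DataFrame) -> pd.DataFrame:
    """DEGs with >= 1 associated DMR in any genic region.

    ``associations`` is the annotate-module output; only gene-kind links
    count.  Returns one row per (dmDEG, DMR association) with the DEG
    direction attached.
    """
    called = degs[degs["is_deg"]]
    gene_links = associations[associations["kind"] == "gene"]
    links = gene_links[gene_links["feature_id"].isin(called.index)].copy()
    if links.empty:
        return pd.DataFrame(
            columns=list(gene_links.columns) + ["deg_direction", "log2fc"]
        )
    links["deg_direction"] = links["feature_id"].map(called["direction"])
    links["log2fc"] = links["feature_id"].map(called["log2fc"])
    return links.reset_index(drop=True)


def direction_crosstab(dmdeg_links: pd.DataFrame) -> pd.DataFrame:
    """Counts over context x region x DMR direction x DEG direction.

    Marginal sums equal the total number of dmDEG associations.
    """
    if dmdeg_links.empty:
        return pd.DataFrame(columns=["context", "region", "direction", "deg_direction", "n"])
    return (
        dmdeg_links.groupby(["context", "region", "direction", "deg_direction"], observed=True)
        .size().rename("n").reset_index()
    )


def _compartment_levels(
    sites: pd.DataFrame, genes: pd.DataFrame, flank: int
) -> pd.DataFrame:
    """Pooled methylation level per (gene, compartment, context); compartments
    are the gene body and the union of the two flanks."""
    rows = []
    for chrom, csub in sites.groupby("chrom", observed=True):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        csub = csub.sort_values("pos")
        pos = csub["pos"].to_numpy()
        meth = csub["n_meth"].to_numpy()
        unmeth = csub["n_unmeth"].to_numpy()
        ctx = csub["context"].to_numpy()
        for g in gsub.itertuples():
            for comp, lo, hi in (
                ("gene_body", g.start, g.end),
                ("flank_up", g.start - flank, g.start),
                ("flank_down", g.end, g.end + flank),
            ):
                i0, i1 = np.searchsorted(pos, [lo, hi])
                if i0 == i1:
                    continue
                sub_ctx = ctx[i0:i1]
                for context in ("CG", "CHG", "CHH"):
                    m = sub_ctx == context
                    tm, tu = meth[i0:i1][m].sum(), unmeth[i0:i1][m].sum()
                    if tm + tu > 0:
                        compartment = "gene_body" if comp == "gene_body" else "flank"
                        rows.append((g.id, compartment, context, tm, tu))
    df = pd.DataFrame(rows, columns=["gene_id", "compartment", "context", "meth", "unmeth"])
    if df.empty:
        return df.assign(level=pd.Series(dtype=float))
    g = df.groupby(["gene_id", "compartment", "context"], observed=True).sum().reset_index()
    g["level"] = g["meth"] / (g["meth"] + g["unmeth"])
    return g


def context_correlation(
    sites_control: pd.DataFrame, sites_stress: pd.DataFrame, genes: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Pearson correlation between per-gene CG/CHG/CHH level differences
    (stress - control), within the gene body and the flank compartments.

    Returns rows (compartment, context_a, context_b, r, p, n); pairs with
    fewer than 3 genes or a zero-variance vector are flagged with NaN r.
    """
    config = config or AnalysisConfig()
    lc = _compartment_levels(sites_control, genes, config.flank)
    ls = _compartment_levels(sites_stress, genes, config.flank)
    merged = lc.merge(ls, on=["gene_id", "compartment", "context"], suffixes=("_c", "_s"))
    merged["diff"] = merged["level_s"] - merged["level_c"]
    wide = merged.pivot_table(
        index=["gene_id", "compartment"], columns="context", values="diff", observed=True
    )
    rows = []
    for compartment, sub in wide.groupby(level="compartment"):
        for a, b in (("CG", "CHG"), ("CG", "CHH"), ("CHG", "CHH")):
            if a not in sub.columns or b not in sub.columns:
                continue
            pair = sub[[a, b]].dropna()
            n = len(pair)
            if n < 3 or pair[a].std() == 0 or pair[b].std() == 0:
                rows.append((compartment, a, b, np.nan, np.nan, n))
                continue
            r, p = stats.pearsonr(pair[a], pair[b])
            rows.append((compartment, a, b, float(r), float(p), n))
    return pd.DataFrame(rows, columns=["compartment", "context_a", "context_b", "r", "p_value", "n"])
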