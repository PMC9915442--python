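"""DMR-to-feature association and metagene methylation-density profiles.

A DMR is assigned to a feature region by its mid-position: the gene body
(or TE body) if the midpoint falls inside the feature, the promoter
(upstream for TEs) if within the flank 5' of the start on the feature's
strand, and downstream if within the flank 3' of the end.  A DMR whose
midpoint lands in several features' windows yields one association per
feature.

Metagene profiles average methylation density (called mCs / covered
cytosines of the context) over length-scaled feature bodies (40
proportional bins by default) plus fixed 100-bp flank bins, oriented so
that bin 0 of the body is always the 5' end.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .config import AnalysisConfig

GENE_REGIONS = ("promoter", "gene_body", "downstream")
TE_REGIONS = ("upstream", "te_body", "downstream")


def dmr_midpoint(start: np.ndarray, end: np.ndarray) -> np.ndarray:
    return (np.asarray(start) + np.asarray(end)) // 2


def associate_dmrs(
    dmrs: pd.DataFrame, features: pd.DataFrame, flank: int | None = None,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Associate DMR bins with gene/TE regions by DMR mid-position.

    ``dmrs`` needs columns chrom/start/context/direction (bins of width
    ``bin_size``).  Returns one row per (DMR, feature) pair with the
    region label; region vocabulary depends on the feature kind.
    """
    config = config or AnalysisConfig()
    flank = config.flank if flank is None else flank
    rows = []
    if dmrs.empty or features.empty:
        return pd.DataFrame(
            columns=["chrom", "start", "context", "direction", "feature_id", "kind", "region"]
        )
    dm = dmrs.copy()
    dm["mid"] = dmr_midpoint(dm["start"], dm["start"] + config.bin_size)
    for chrom, dsub in dm.groupby("chrom", observed=True):
        fsub = features[features["chrom"] == chrom]
        if fsub.empty:
            continue
        mids = dsub["mid"].to_numpy()[:, None]
        fs = fsub["start"].to_numpy()[None, :]
        fe = fsub["end"].to_numpy()[None, :]
        plus = (fsub["strand"] == "+").to_numpy()[None, :]
        in_body = (mids >= fs) & (mids < fe)
        before = (mids >= fs - flank) & (mids < fs)   # 5' window on + strand
        after = (mids >= fe) & (mids < fe + flank)
        upstream = np.where(plus, before, after)
        downstream = np.where(plus, after, before)
        for di, fi in zip(*np.nonzero(in_body | upstream | downstream)):
            feat = fsub.iloc[fi]
            if in_body[di, fi]:
                region = "gene_body" if feat.kind == "gene" else "te_body"
            elif upstream[di, fi]:
                region = "promoter" if feat.kind == "gene" else "upstream"
            else:
                region = "downstream"
            d = dsub.iloc[di]
            rows.append((chrom, int(d.start), d.context, d.get("direction"),
                         feat.id, feat.kind, region))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "context", "direction", "feature_id", "kind", "region"]
    )


def association_counts(associations: pd.DataFrame) -> pd.DataFrame:
    """Per (kind x context x region x direction) DMR tallies."""
    return (
        associations.groupby(["kind", "context", "region", "direction"], observed=True)
        .size().rename("n_dmrs").reset_index()
    )


@dataclass
class MetageneProfile:
    """Aggregated density profile: ``flank_bins`` upstream bins, ``n_body_bins``
    length-scaled body bins, ``flank_bins`` downstream bins (5'->3')."""

    context: str
    mc: np.ndarray        # called-mC counts per bin
    covered: np.ndarray   # covered-cytosine counts per bin
    n_body_bins: int
    flank_bins: int
    n_features: int
    n_skipped: int

    @property
    def density(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.covered > 0, self.mc / np.maximum(self.covered, 1), np.nan)

    @property
    def body_slice(self) -> slice:
        return slice(self.flank_bins, self.flank_bins + self.n_body_bins)

    @property
    def flank_density_mean(self) -> float:
        d = self.density
        flanks = np.concatenate([d[: self.flank_bins], d[self.flank_bins + self.n_body_bins:]])
        return float(np.nanmean(flanks)) if len(flanks) else float("nan")

    @property
    def body_density_mean(self) -> float:
        return float(np.nanmean(self.density[self.body_slice]))


def metagene_profile(
    calls: pd.DataFrame, features: pd.DataFrame, context: str,
    config: AnalysisConfig | None = None,
) -> MetageneProfile:
    """Length-scaled methylation-density profile over one feature kind.

    ``calls`` must carry coverage and is_mc (the covered-but-unmethylated
    sites are the density denominator).  Features shorter than the body
    bin count (in bp) are skipped and counted.
    """
    config = config or AnalysisConfig()
    nb, fb = config.n_body_bins, config.flank
    fbins = config.flank // config.flank_bin_size
    total_bins = nb + 2 * fbins
    mc_acc = np.zeros(total_bins, dtype=np.int64)
    cov_acc = np.zeros(total_bins, dtype=np.int64)
    sub = calls[(calls["context"] == context) & (calls["coverage"] >= 1)]
    n_used = n_skipped = 0
    for chrom, csub in sub.groupby("chrom", observed=True):
        fsub = features[features["chrom"] == chrom]
        if fsub.empty:
            continue
        pos = csub["pos"].to_numpy()
        order = np.argsort(pos)
        pos = pos[order]
        is_mc = csub["is_mc"].to_numpy()[order]
        for feat in fsub.itertuples():
            if feat.end - feat.start < nb:
                n_skipped += 1
                continue
            n_used += 1
            lo, hi = feat.start - fb, feat.end + fb
            i0, i1 = np.searchsorted(pos, [lo, hi])
            p = pos[i0:i1]
            if len(p) == 0:
                continue
            rel = np.empty(len(p), dtype=np.int64)
            left = p < feat.start
            right = p >= feat.end
            body = ~(left | right)
            rel[left] = (p[left] - lo) // config.flank_bin_size
            rel[body] = fbins + (p[body] - feat.start) * nb // (feat.end - feat.start)
            rel[right] = fbins + nb + (p[right] - feat.end) // config.flank_bin_size
            if feat.strand == "-":
                rel = total_bins - 1 - rel
            np.add.at(cov_acc, rel, 1)
            np.add.at(mc_acc, rel, is_mc[i0:i1].astype(np.int64))
    return MetageneProfile(context, mc_acc, cov_acc, nb, fbins, n_used, n_skipped)


def expression_classes(expression: pd.DataFrame, n_classes: int = 5) -> pd.Series:
    """Quintile classes of mean log2(x+1) expression; class 1 is lowest.

    Ties are broken by stable gene-id (input) order.  With fewer genes
    than classes, fewer classes result.
    """
    mean_expr = np.log2(expression + 1).mean(axis=1)
    order = np.argsort(mean_expr.to_numpy(), kind="stable")
    n_classes = min(n_classes, len(mean_expr))
    labels = np.empty(len(mean_expr), dtype=int)
    for k, idx in enumerate(np.array_split(order, n_classes), start=1):
        labels[idx] = k
    return pd.Series(labels, index=expression.index, name="expression_class")


def expression_class_profiles(
    expression: pd.DataFrame, calls: pd.DataFrame, genes: pd.DataFrame, context: str,
    config: AnalysisConfig | None = None, n_classes: int = 5,
) -> dict[int, MetageneProfile]:
    """One metagene profile per expression quintile of the gene set."""
    config = config or AnalysisConfig()
    common = genes[genes["id"].isin(expression.index)]
    classes = expression_classes(expression.loc[common["id"].unique()], n_classes)
    return {
        k: metagene_profile(calls, common[common["id"].map(classes) == k], context, config)
        for k in sorted(classes.unique())
    }


def class_trend_spearman(profiles: dict[int, MetageneProfile]) -> float:
    """Spearman correlation of mean body density against class rank."""
    ks = sorted(profiles)
    dens = [profiles[k].body_density_mean for k in ks]
    return float(_stats.spearmanr(ks, dens).statistic)
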