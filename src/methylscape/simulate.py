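"""Synthetic four-sample WGBS study generator with a ground-truth manifest.

The generator emulates the structure of a two-genotype (SS, ST) x
two-condition (control, salinity stress) plant methylome experiment at
~30x coverage: high gene-body CG methylation coupled to expression rank,
elevated TE-body CHH methylation, a biologically unmethylated control
chromosome (the chloroplast's role, used to estimate bisulfite
conversion error), planted 100-bp differentially methylated bins, planted
differentially expressed genes, and 24-nt small RNAs concentrated on a
subset of CHH-hypermethylated TEs with a C/T bias at their 3' end.

Everything planted is recorded in a :class:`TruthManifest`, which is
sufficient to compute every recovery metric downstream.  All outputs are
bit-identical across runs for the same seed and configuration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as msio
from .config import GENOTYPES, SAMPLES, SimulationConfig, config_to_dict
from .genome import CWA_TRINUCLEOTIDES, GenomeAssembly, enumerate_cytosines, reverse_complement

CONTROL_CHROM = "chrC"
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# fixed stage tags so each generator op has its own independent stream
_STAGES = {"genome": 11, "features": 23, "expr_baseline": 31, "degs": 37,
           "methylome": 41, "expression": 53, "smrna": 61}


def _rng(seed: int, stage: str, extra: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STAGES[stage], extra]))


class PlacementError(RuntimeError):
    """Feature density infeasible for the requested genome."""


# ----------------------------------------------------------------------
# truth manifest


@dataclass
class TruthManifest:
    """Ground truth of everything the generator planted."""

    planted_dmrs: pd.DataFrame   # chrom, bin_start, context, direction, level_control, level_stress, source
    planted_degs: pd.DataFrame   # gene_id, genotype, log2fc_true, direction
    smrna_target_tes: list[str]
    chh_hyper_only_tes: list[str]
    conversion_error_true: float
    seed: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        d = self.planted_dmrs
        if len(d):
            if (d["bin_start"] % 100 != 0).any():
                raise ValueError("planted DMR bins must be aligned to 100-bp boundaries")
            if d.duplicated(subset=["chrom", "bin_start"]).any():
                raise ValueError("planted DMR bins must be disjoint")

    def to_json(self, path) -> None:
        obj = {
            "planted_dmrs": self.planted_dmrs.to_dict(orient="records"),
            "planted_degs": self.planted_degs.to_dict(orient="records"),
            "smrna_target_tes": list(self.smrna_target_tes),
            "chh_hyper_only_tes": list(self.chh_hyper_only_tes),
            "conversion_error_true": self.conversion_error_true,
            "seed": self.seed,
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        obj = json.loads(Path(path).read_text())
        return cls(
            planted_dmrs=pd.DataFrame(obj["planted_dmrs"], columns=_DMR_COLS),
            planted_degs=pd.DataFrame(obj["planted_degs"], columns=_DEG_COLS),
            smrna_target_tes=obj["smrna_target_tes"],
            chh_hyper_only_tes=obj["chh_hyper_only_tes"],
            conversion_error_true=obj["conversion_error_true"],
            seed=obj["seed"],
            warnings=obj.get("warnings", []),
        )


_DMR_COLS = ["chrom", "bin_start", "context", "direction", "level_control", "level_stress", "source"]
_DEG_COLS = ["gene_id", "genotype", "log2fc_true", "direction"]


# ----------------------------------------------------------------------
# genome


def generate_genome(
    seed: int,
    n_chrom: int = 2,
    chrom_length: int = 1_000_000,
    control_chrom_length: int = 100_000,
) -> GenomeAssembly:
    """I.i.d. uniform-base chromosomes chr1..chrN plus an unmethylated
    control chromosome (excluded from feature placement)."""
    if chrom_length < 50_000:
        raise ValueError("chrom_length must be >= 50,000")
    rng = _rng(seed, "genome")
    seqs = {}
    for i in range(n_chrom):
        codes = rng.integers(0, 4, size=chrom_length)
        seqs[f"chr{i + 1}"] = _BASES[codes].tobytes().decode("ascii")
    codes = rng.integers(0, 4, size=control_chrom_length)
    seqs[CONTROL_CHROM] = _BASES[codes].tobytes().decode("ascii")
    return GenomeAssembly(seqs, control_chrom=CONTROL_CHROM)


# ----------------------------------------------------------------------
# features


def generate_features(
    genome: GenomeAssembly,
    seed: int,
    n_genes: int = 200,
    n_tes: int = 200,
    te_in_gene_frac: float = 0.4,
    gene_length_range: tuple[int, int] = (1000, 5000),
    te_length_range: tuple[int, int] = (300, 1500),
    flank: int = 2000,
    host_weights: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Place non-overlapping gene bodies and TEs on the analysis chromosomes.

    Genes are placed in evenly spaced slots (guaranteeing disjoint bodies
    that fit with their 2-kb flanks inside the chromosome).  A Bernoulli
    fraction of TEs is placed overlapping a gene +/- flank window — the
    host gene drawn with the given per-gene weights (default uniform) —
    and the rest go into the intergenic gaps.  TEs never overlap each
    other.
    """
    rng = _rng(seed, "features")
    chroms = genome.analysis_chroms
    lengths = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    gene_counts = _proportional_counts(n_genes, lengths)
    rows = []
    gidx = 0
    for chrom, L, n_c in zip(chroms, lengths.astype(int), gene_counts):
        if n_c == 0:
            continue
        usable = L - 2 * flank
        slot = usable // n_c
        if slot < gene_length_range[1]:
            raise PlacementError(
                f"{chrom}: {n_c} genes of up to {gene_length_range[1]} bp do not fit"
            )
        for i in range(n_c):
            glen = int(rng.integers(gene_length_range[0], gene_length_range[1] + 1))
            start = flank + i * slot + int(rng.integers(0, slot - glen + 1))
            gidx += 1
            rows.append((f"gene{gidx:04d}", chrom, start, start + glen,
                         "+" if rng.random() < 0.5 else "-", "gene"))
    genes = pd.DataFrame(rows, columns=msio.FEATURE_COLUMNS)

    te_rows = []
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    gaps = _gene_flank_gaps(genes, {c: len(genome.sequences[c]) for c in chroms}, flank)
    in_gene = rng.random(n_tes) < te_in_gene_frac
    gene_w = np.ones(len(genes))
    if host_weights and len(genes):
        gene_w = genes["id"].map(lambda g: host_weights.get(g, 1.0)).to_numpy(dtype=float)
    gene_w = gene_w / gene_w.sum() if len(genes) else gene_w
    tidx = 0
    for k in range(n_tes):
        tlen = int(rng.integers(te_length_range[0], te_length_range[1] + 1))
        placed_ok = False
        if in_gene[k] and len(genes):
            for _ in range(200):
                g = genes.iloc[int(rng.choice(len(genes), p=gene_w))]
                lo = max(0, g.start - flank)
                hi = min(len(genome.sequences[g.chrom]), g.end + flank)
                if hi - lo < tlen:
                    continue
                s = int(rng.integers(lo, hi - tlen + 1))
                if _overlaps_any(placed[g.chrom], s, s + tlen):
                    continue
                tidx += 1
                te_rows.append((f"te{tidx:04d}", g.chrom, s, s + tlen,
                                "+" if rng.random() < 0.5 else "-", "TE"))
                placed[g.chrom].append((s, s + tlen))
                placed_ok = True
                break
        if not placed_ok:
            fits = [(i, c, gs, ge) for i, (c, gs, ge) in enumerate(gaps) if ge - gs >= tlen]
            if not fits:
                raise PlacementError(f"no intergenic gap fits a {tlen}-bp TE")
            weights = np.array([ge - gs - tlen + 1 for _, _, gs, ge in fits], dtype=float)
            j = int(rng.choice(len(fits), p=weights / weights.sum()))
            i, c, gs, ge = fits[j]
            s = gs + int(rng.integers(0, ge - gs - tlen + 1))
            tidx += 1
            te_rows.append((f"te{tidx:04d}", c, s, s + tlen,
                            "+" if rng.random() < 0.5 else "-", "TE"))
            placed[c].append((s, s + tlen))
            gaps[i] = (c, gs, s)
            gaps.append((c, s + tlen, ge))
    tes = pd.DataFrame(te_rows, columns=msio.FEATURE_COLUMNS)
    out = pd.concat([genes, tes], ignore_index=True)
    out = out.sort_values(["chrom", "start"], kind="stable", ignore_index=True)
    msio.validate_features(out)
    return out


def _proportional_counts(total: int, weights: np.ndarray) -> list[int]:
    raw = weights / weights.sum() * total
    counts = np.floor(raw).astype(int)
    rema = raw - counts
    for i in np.argsort(-rema)[: total - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def _gene_flank_gaps(genes: pd.DataFrame, chrom_lengths: dict, flank: int) -> list:
    gaps = []
    for chrom, L in chrom_lengths.items():
        sub = genes[genes["chrom"] == chrom].sort_values("start")
        cursor = 0
        for row in sub.itertuples():
            lo = max(0, row.start - flank)
            if lo > cursor:
                gaps.append((chrom, cursor, lo))
            cursor = max(cursor, min(L, row.end + flank))
        if cursor < L:
            gaps.append((chrom, cursor, L))
    return gaps


def _overlaps_any(intervals: list[tuple[int, int]], s: int, e: int) -> bool:
    return any(s < ie and is_ < e for is_, ie in intervals)


# ----------------------------------------------------------------------
# methylome


class _SiteIndex:
    """Fast (chrom, position-range) -> row-index lookups on a sorted site table."""

    def __init__(self, sites: pd.DataFrame):
        self.pos = sites["pos"].to_numpy()
        chroms = sites["chrom"].to_numpy()
        names, starts = np.unique(chroms, return_index=True)
        order = np.argsort(starts)
        names, starts = names[order], starts[order]
        ends = np.append(starts[1:], len(chroms))
        self.bounds = {n: (int(s), int(e)) for n, s, e in zip(names, starts, ends)}

    def range(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        if chrom not in self.bounds:
            return np.empty(0, dtype=int)
        s, e = self.bounds[chrom]
        i0 = s + np.searchsorted(self.pos[s:e], lo)
        i1 = s + np.searchsorted(self.pos[s:e], hi)
        return np.arange(i0, i1)


def _te_grid_bins(start: int, end: int, bin_size: int = 100):
    return range((start // bin_size) * bin_size, ((end + bin_size - 1) // bin_size) * bin_size, bin_size)


def generate_methylome(
    genome: GenomeAssembly,
    features: pd.DataFrame,
    cfg: SimulationConfig,
    seed: int,
    expression_rank: dict[str, float] | None = None,
    planted_degs: pd.DataFrame | None = None,
):
    """Simulate per-cytosine reports for the four samples.

    Per-site true methylation probabilities come from context- and
    compartment-dependent baselines (gene-body CG scaled by the gene's
    expression rank when given); planted bins shift the stress
    probability; the control chromosome is fully unmethylated, so only
    conversion error yields methylated reads there.  Read totals are
    Poisson(coverage) and methylated counts Binomial(n, p + (1-p)*err).

    Returns ``(reports, planted_dmrs, target_tes, hyper_only_tes, warnings)``.
    """
    rng = _rng(seed, "methylome")
    warnings_out: list[str] = []
    sites = enumerate_cytosines(genome)
    n = len(sites)
    index = _SiteIndex(sites)
    ctx_codes = sites["context"].cat.codes.to_numpy()  # CG=0, CHG=1, CHH=2
    pos = sites["pos"].to_numpy()
    is_cwa = sites["trinucleotide"].isin(CWA_TRINUCLEOTIDES).to_numpy()

    # site mosaic: each cytosine is methylated (at the context's level) with a
    # compartment-dependent fraction, or fully unmethylated.  The mosaic is
    # drawn once so all four samples share the same underlying methylome.
    frac = np.empty(n, dtype=np.float64)
    level = np.empty(n, dtype=np.float64)
    genes = features[features["kind"] == "gene"]
    tes = features[features["kind"] == "TE"]
    for chrom, (s, e) in index.bounds.items():
        cpos = pos[s:e]
        if chrom == genome.control_chrom:
            frac[s:e] = 0.0
            level[s:e] = 0.0
            continue
        L = len(genome.sequences[chrom])
        comp = np.zeros(L, dtype=np.int8)  # 0 bg, 1 gene body, 2 TE body
        cgf = np.full(L, cfg.p_background["CG"][0], dtype=np.float32)
        lo, hi = cfg.cg_gene_frac_range
        for g in genes[genes["chrom"] == chrom].itertuples():
            comp[g.start:g.end] = 1
            r = expression_rank.get(g.id, 0.5) if expression_rank else 0.5
            cgf[g.start:g.end] = lo + (hi - lo) * r
        for t in tes[tes["chrom"] == chrom].itertuples():
            comp[t.start:t.end] = 2
        scomp = comp[cpos]
        c = ctx_codes[s:e]
        f = np.empty(e - s, dtype=np.float64)
        lv = np.empty(e - s, dtype=np.float64)
        cg = c == 0
        f[cg] = np.where(scomp[cg] == 2, cfg.p_te_body["CG"][0], cgf[cpos][cg])
        lv[cg] = np.where(scomp[cg] == 2, cfg.p_te_body["CG"][1], cfg.cg_level)
        for code, name in ((1, "CHG"), (2, "CHH")):
            m = c == code
            choices = [cfg.p_te_body[name], cfg.p_gene_body[name], cfg.p_background[name]]
            f[m] = np.select([scomp[m] == 2, scomp[m] == 1], [choices[0][0], choices[1][0]],
                             default=choices[2][0])
            lv[m] = np.select([scomp[m] == 2, scomp[m] == 1], [choices[0][1], choices[1][1]],
                              default=choices[2][1])
        frac[s:e] = f
        level[s:e] = lv
    mosaic = rng.random(n) < frac
    p_ctrl = np.where(mosaic, level, 0.0)
    p_stress = p_ctrl.copy()

    # ---- plant differential methylation (bin-exact, recorded in the manifest)
    occupied: set[tuple[str, int]] = set()
    dmr_rows = []
    ctx_to_code = {"CG": 0, "CHG": 1, "CHH": 2}

    te_ids = tes["id"].tolist()
    if cfg.n_target_tes + cfg.n_hyper_only_tes > len(te_ids):
        raise ValueError("not enough TEs for the requested target/hyper-only sets")
    chosen = rng.choice(len(te_ids), size=cfg.n_target_tes + cfg.n_hyper_only_tes, replace=False)
    target_tes = [te_ids[i] for i in chosen[: cfg.n_target_tes]]
    hyper_only_tes = [te_ids[i] for i in chosen[cfg.n_target_tes:]]
    te_by_id = tes.set_index("id")
    # expected pooled bin level within a TE: fraction methylated x level
    te_frac, te_level = cfg.p_te_body["CHH"]
    base_chh = te_frac * te_level
    # smRNA-targeted TEs gain CHH methylation at NEW sites (a de novo,
    # RdDM-like density gain biased to non-CWA); every bin overlapping the
    # body is shifted for all its CHH sites
    for tid in target_tes:
        t = te_by_id.loc[tid]
        for b in _te_grid_bins(int(t.start), int(t.end)):
            if (t.chrom, b) in occupied:
                continue
            occupied.add((t.chrom, b))
            idx = index.range(t.chrom, b, b + 100)
            idx = idx[ctx_codes[idx] == 2]
            shift = cfg.te_chh_shift * np.where(is_cwa[idx], cfg.cwa_shift_frac, 1.0)
            p_stress[idx] = p_stress[idx] + shift
            dmr_rows.append((t.chrom, b, "CHH", "hyper", base_chh,
                             base_chh + cfg.te_chh_shift, "te_target"))
    # non-targeted hypermethylated TEs gain LEVEL on their existing mosaic
    # of methylated sites (density unchanged); the shift acts on interior
    # grid bins so the manifest is exactly bin-resolved
    level_shift = cfg.te_chh_shift / te_frac
    for tid in hyper_only_tes:
        t = te_by_id.loc[tid]
        lo = ((int(t.start) + 99) // 100) * 100
        hi = (int(t.end) // 100) * 100
        for b in range(lo, hi, 100):
            if (t.chrom, b) in occupied:
                continue
            occupied.add((t.chrom, b))
            idx = index.range(t.chrom, b, b + 100)
            idx = idx[(ctx_codes[idx] == 2) & mosaic[idx]]
            p_stress[idx] = p_stress[idx] + level_shift
            dmr_rows.append((t.chrom, b, "CHH", "hyper", base_chh,
                             base_chh + cfg.te_chh_shift, "te_hyper"))

    if cfg.couple_promoter_chh and planted_degs is not None and len(planted_degs):
        lc, ls = cfg.dmr_levels["CHH"]
        gene_by_id = genes.set_index("id")
        up_genes = planted_degs.loc[planted_degs["direction"] == "up", "gene_id"].unique()
        for gid in up_genes:
            g = gene_by_id.loc[gid]
            anchor = int(g.start) - 300 if g.strand == "+" else int(g.end) + 299
            b = (anchor // 100) * 100
            if b < 0 or b + 100 > len(genome.sequences[g.chrom]) or (g.chrom, b) in occupied:
                continue
            occupied.add((g.chrom, b))
            idx = index.range(g.chrom, b, b + 100)
            idx = idx[ctx_codes[idx] == 2]
            p_ctrl[idx], p_stress[idx] = lc, ls
            dmr_rows.append((g.chrom, b, "CHH", "hyper", lc, ls, "promoter"))

    chroms = genome.analysis_chroms
    weights = np.array([len(genome.sequences[c]) for c in chroms], dtype=float)
    weights /= weights.sum()
    for context in ("CG", "CHG", "CHH"):
        lc, ls = cfg.dmr_levels[context]
        for direction in ("hyper", "hypo"):
            a, b_ = (lc, ls) if direction == "hyper" else (ls, lc)
            planted = 0
            attempts = 0
            while planted < cfg.n_dmrs_per_class:
                attempts += 1
                if attempts > 50 * max(cfg.n_dmrs_per_class, 1):
                    raise PlacementError("could not place requested planted DMR bins")
                chrom = chroms[int(rng.choice(len(chroms), p=weights))]
                bstart = int(rng.integers(0, len(genome.sequences[chrom]) // 100)) * 100
                if (chrom, bstart) in occupied:
                    continue
                occupied.add((chrom, bstart))
                idx = index.range(chrom, bstart, bstart + 100)
                idx = idx[ctx_codes[idx] == ctx_to_code[context]]
                p_ctrl[idx], p_stress[idx] = a, b_
                dmr_rows.append((chrom, bstart, context, direction, a, b_, "background"))
                planted += 1

    if cfg.gene_shift_sd > 0:
        lam = cfg.gene_shift_loading
        resid = np.sqrt(max(0.0, 1 - lam**2))
        for g in genes.itertuples():
            f, e1, e2 = rng.normal(0, cfg.gene_shift_sd, size=3)
            idx = index.range(g.chrom, g.start, g.end)
            for code, delta in ((0, lam * f + resid * e1), (1, lam * f + resid * e2)):
                # shift the methylated mosaic only: the pooled gene-body level
                # difference stays proportional to delta for either sign
                sel = idx[(ctx_codes[idx] == code) & mosaic[idx]]
                p_stress[sel] = p_stress[sel] + delta

    for arr, name in ((p_ctrl, "control"), (p_stress, "stress")):
        out = (arr < 0) | (arr > 1)
        if out.any():
            warnings_out.append(f"{int(out.sum())} {name} probabilities clipped to [0,1]")
            np.clip(arr, 0.0, 1.0, out=arr)

    # ---- draw read counts per sample
    err = cfg.conversion_error
    reports = {}
    for k, sample in enumerate(SAMPLES):
        srng = _rng(seed, "methylome", extra=100 + k)
        p = p_ctrl if sample.endswith("-C") else p_stress
        cov = srng.poisson(cfg.coverage, size=n)
        meth = srng.binomial(cov, p + (1.0 - p) * err)
        reports[sample] = pd.DataFrame(
            {"chrom": sites["chrom"], "pos": pos, "strand": sites["strand"],
             "n_meth": meth, "n_unmeth": cov - meth,
             "context": sites["context"], "trinucleotide": sites["trinucleotide"]}
        )
    planted_dmrs = pd.DataFrame(dmr_rows, columns=_DMR_COLS)
    return reports, planted_dmrs, target_tes, hyper_only_tes, warnings_out


# ----------------------------------------------------------------------
# expression


def draw_expression_baseline(gene_ids: list[str], cfg: SimulationConfig, seed: int) -> pd.Series:
    rng = _rng(seed, "expr_baseline")
    return pd.Series(rng.lognormal(cfg.log_expr_mean, cfg.log_expr_sd, size=len(gene_ids)),
                     index=pd.Index(gene_ids, name="gene_id"))


def choose_planted_degs(gene_ids: list[str], cfg: SimulationConfig, seed: int) -> pd.DataFrame:
    rng = _rng(seed, "degs")
    rows = []
    lfc = float(np.log2(cfg.deg_fold_change))
    for genotype in GENOTYPES:
        k = min(cfg.n_degs_per_genotype, len(gene_ids))
        ids = rng.choice(gene_ids, size=k, replace=False)
        half = k // 2
        for i, gid in enumerate(ids):
            up = i < k - half  # first ceil(k/2) up, rest down
            rows.append((gid, genotype, lfc if up else -lfc, "up" if up else "down"))
    return pd.DataFrame(rows, columns=_DEG_COLS)


def generate_expression(
    baseline: pd.Series, planted_degs: pd.DataFrame, cfg: SimulationConfig, seed: int
) -> pd.DataFrame:
    """FPKM-like matrix: replicated samples per group with log-normal noise
    of the configured CV; planted DEGs get the multiplicative fold change
    in their genotype's stress samples."""
    rng = _rng(seed, "expression")
    sigma = float(np.sqrt(np.log1p(cfg.expression_cv**2)))
    cols = {}
    fc = {}
    for row in planted_degs.itertuples():
        fc[(row.gene_id, row.genotype)] = 2.0**row.log2fc_true
    for sample in SAMPLES:
        genotype, cond = sample.split("-")
        mult = np.ones(len(baseline))
        if cond == "S":
            for i, gid in enumerate(baseline.index):
                if (gid, genotype) in fc:
                    mult[i] = fc[(gid, genotype)]
        for r in range(1, cfg.n_replicates + 1):
            noise = rng.lognormal(-(sigma**2) / 2, sigma, size=len(baseline))
            cols[f"{sample}_{r}"] = baseline.to_numpy() * mult * noise
    return pd.DataFrame(cols, index=baseline.index)


# ----------------------------------------------------------------------
# small RNA


def generate_smrnas(
    genome: GenomeAssembly,
    features: pd.DataFrame,
    target_tes: list[str],
    cfg: SimulationConfig,
    seed: int,
) -> dict[str, pd.DataFrame]:
    """Per-sample collapsed smRNA reads (BED-style table).

    Background reads fall uniformly over the analysis chromosomes with a
    size distribution peaked at 24 nt; smRNA-targeted TEs get 24-nt and
    21-nt reads at ``smrna_te_enrichment``-fold the background density
    (boosted further under stress), with a C/T bias at the two 3'
    terminal positions of the 24-nt reads.
    """
    tes = features[features["kind"] == "TE"].set_index("id")
    lengths = np.array(sorted(cfg.smrna_length_probs))
    probs = np.array([cfg.smrna_length_probs[int(l)] for l in lengths], dtype=float)
    probs /= probs.sum()
    out = {}
    for k, sample in enumerate(SAMPLES):
        rng = _rng(seed, "smrna", extra=k)
        rows = []
        for chrom in genome.analysis_chroms:
            seq = genome.sequences[chrom]
            L = len(seq)
            n_bg = rng.poisson(L / 1000 * cfg.smrna_reads_per_kb)
            ls = rng.choice(lengths, size=n_bg, p=probs)
            starts = rng.integers(0, L - int(lengths.max()), size=n_bg)
            strands = rng.random(n_bg) < 0.5
            for s, l, plus in zip(starts, ls, strands):
                rows.append((chrom, int(s), int(s + l), "+" if plus else "-", False))
        boost = cfg.smrna_stress_boost if sample.endswith("-S") else 1.0
        extra_mult = max(0.0, cfg.smrna_te_enrichment * boost - 1.0)
        for tid in target_tes:
            t = tes.loc[tid]
            kb = (t.end - t.start) / 1000
            for l in (24, 21):
                lam = cfg.smrna_reads_per_kb * cfg.smrna_length_probs.get(l, 0) * kb * extra_mult
                n_extra = rng.poisson(lam)
                if t.end - t.start <= l:
                    continue
                starts = rng.integers(t.start, t.end - l, size=n_extra)
                strands = rng.random(n_extra) < 0.5
                for s, plus in zip(starts, strands):
                    rows.append((t.chrom, int(s), int(s + l), "+" if plus else "-", l == 24))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "bias3p"])
        seqs = []
        for row in df.itertuples():
            s = genome.sequences[row.chrom][row.start:row.end]
            if row.strand == "-":
                s = reverse_complement(s)
            if row.bias3p:
                tail = "".join(
                    rng.choice(["C", "T"]) if rng.random() < cfg.smrna_3p_ct_bias
                    else rng.choice(["A", "G"])
                    for _ in range(2)
                )
                s = s[:-2] + tail
            seqs.append(s)
        df["sequence"] = seqs
        df["count"] = 1 + rng.poisson(0.3, size=len(df))
        df = (
            df.groupby(["chrom", "start", "end", "strand"], as_index=False)
            .agg(sequence=("sequence", "first"), count=("count", "sum"))
        )
        df["length"] = df["end"] - df["start"]
        out[sample] = df[msio.SMRNA_COLUMNS].sort_values(
            ["chrom", "start", "end", "strand"], ignore_index=True
        )
    return out


# ----------------------------------------------------------------------
# orchestration


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    seed: int
    genome: GenomeAssembly
    features: pd.DataFrame
    reports: dict[str, pd.DataFrame]
    expression: pd.DataFrame
    smrnas: dict[str, pd.DataFrame]
    manifest: TruthManifest

    @property
    def genes(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "gene"].reset_index(drop=True)

    @property
    def tes(self) -> pd.DataFrame:
        return self.features[self.features["kind"] == "TE"].reset_index(drop=True)

    def write(self, outdir) -> dict[str, str]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"genome": str(outdir / "genome.fa"), "features": str(outdir / "features.gff3"),
                 "expression": str(outdir / "expression.tsv"), "manifest": str(outdir / "manifest.json")}
        msio.write_fasta(self.genome, paths["genome"])
        msio.write_features_gff3(self.features, paths["features"])
        msio.write_expression_table(self.expression, paths["expression"])
        self.manifest.to_json(paths["manifest"])
        for sample in SAMPLES:
            p = outdir / f"cx_report_{sample}.tsv.gz"
            msio.write_cytosine_report(self.reports[sample], p)
            paths[f"report_{sample}"] = str(p)
            b = outdir / f"smrna_{sample}.bed"
            msio.write_smrna_bed(self.smrnas[sample], b)
            paths[f"smrna_{sample}"] = str(b)
        return paths


def simulate_dataset(cfg: SimulationConfig | None = None, seed: int = 0) -> SimulatedDataset:
    """Generate the full four-sample study: genome, features, methylomes,
    expression, small RNAs, and the truth manifest."""
    cfg = cfg or SimulationConfig()
    genome = generate_genome(seed, cfg.n_chrom, cfg.chrom_length, cfg.control_chrom_length)
    # gene ids are deterministic, so DEGs can be chosen before placement and
    # up-DEG genes weighted as TE hosts (the Fig-4A-style coupling)
    gene_ids = [f"gene{i:04d}" for i in range(1, cfg.n_genes + 1)]
    planted_degs = choose_planted_degs(gene_ids, cfg, seed)
    host_weights = {g: cfg.te_deg_host_weight for g in set(planted_degs["gene_id"])}
    features = generate_features(
        genome, seed, cfg.n_genes, cfg.n_tes, cfg.te_in_gene_frac,
        cfg.gene_length_range, cfg.te_length_range, host_weights=host_weights,
    )
    assert set(features.loc[features["kind"] == "gene", "id"]) == set(gene_ids), \
        "gene id universe mismatch"
    baseline = draw_expression_baseline(gene_ids, cfg, seed)
    ranks = baseline.rank(method="first")
    rank_frac = ((ranks - 1) / max(1, len(ranks) - 1)).to_dict() if len(ranks) else {}
    reports, planted_dmrs, target_tes, hyper_only, warns = generate_methylome(
        genome, features, cfg, seed, expression_rank=rank_frac, planted_degs=planted_degs
    )
    expression = generate_expression(baseline, planted_degs, cfg, seed)
    smrnas = generate_smrnas(genome, features, target_tes, cfg, seed)
    manifest = TruthManifest(
        planted_dmrs=planted_dmrs, planted_degs=planted_degs,
        smrna_target_tes=target_tes, chh_hyper_only_tes=hyper_only,
        conversion_error_true=cfg.conversion_error, seed=seed, warnings=warns,
    )
    return SimulatedDataset(cfg, seed, genome, features, reports, expression, smrnas, manifest)


def null_config(**overrides) -> SimulationConfig:
    """A configuration with nothing planted (for calibration runs)."""
    base = dict(n_dmrs_per_class=0, n_target_tes=0, n_hyper_only_tes=0,
                n_degs_per_genotype=0, couple_promoter_chh=False)
    base.update(overrides)
    return SimulationConfig(**base)
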