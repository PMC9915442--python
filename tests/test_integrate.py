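"""DEG calling, clustering, dmDEG intersection and context correlation."""

import numpy as np
import pandas as pd
import pytest

from methylscape import annotate, integrate
from methylscape.config import AnalysisConfig, SimulationConfig
from methylscape.simulate import CONTROL_CHROM, simulate_dataset


def _expr(values: dict) -> pd.DataFrame:
    return pd.DataFrame(values, index=pd.Index(
        [f"g{i}" for i in range(len(next(iter(values.values()))))], name="gene_id"
    ))


def _flat_expr(mean_c, mean_s, genotype="SS", eps=1e-3):
    return _expr({
        f"{genotype}-C_1": [mean_c - eps], f"{genotype}-C_2": [mean_c + eps],
        f"{genotype}-S_1": [mean_s - eps], f"{genotype}-S_2": [mean_s + eps],
    })


class TestCallDegs:
    def test_fold_change_gate_pass(self):
        degs = integrate.call_degs(_flat_expr(10, 16), "SS")
        row = degs.iloc[0]
        assert row["fold_change"] == pytest.approx(17 / 11, rel=1e-3)
        assert bool(row["is_deg"]) and row["direction"] == "up"

    def test_fold_change_gate_blocks(self):
        degs = integrate.call_degs(_flat_expr(10, 14), "SS")
        assert not degs["is_deg"].any()  # FC 1.36 < 1.5 regardless of p

    def test_single_replicate_rejected(self):
        expr = _expr({"SS-C_1": [10.0], "SS-S_1": [30.0]})
        with pytest.raises(ValueError, match="replicates"):
            integrate.call_degs(expr, "SS")

    def test_scale_invariance(self, default_dataset):
        expr = default_dataset.expression
        a = integrate.call_degs(expr, "SS")
        b = integrate.call_degs(expr * 1000.0, "SS")
        assert (a["is_deg"] == b["is_deg"]).mean() > 0.995
        planted = set(default_dataset.manifest.planted_degs.query("genotype=='SS'")["gene_id"])
        assert set(a.index[a["is_deg"]]) & planted == set(b.index[b["is_deg"]]) & planted

    def test_planted_recovery_and_false_calls(self, default_dataset):
        from methylscape.evaluate import deg_recovery
        rec = {g: deg_recovery(integrate.call_degs(default_dataset.expression, g),
                               default_dataset.manifest, g) for g in ("SS", "ST")}
        recovered = sum(r["n_recovered"] for r in rec.values())
        planted = sum(r["n_planted"] for r in rec.values())
        assert recovered / planted >= 0.95
        assert all(r["false_call_rate"] <= 0.07 for r in rec.values())


class TestKmeans:
    def test_repeated_patterns_zero_within_ss(self):
        rng = np.random.default_rng(4)
        patterns = np.array([[1, 0, 0, 0], [0, 1, 0, 0], [0, 0, 1, 0],
                             [0, 0, 0, 1], [1, 1, 0, 0]], dtype=float) * 50 + 5
        rows = np.repeat(patterns, 6, axis=0)
        ids = [f"g{i}" for i in range(len(rows))]
        cols = {}
        for j, g in enumerate(("SS-C", "SS-S", "ST-C", "ST-S")):
            for r in (1, 2):
                cols[f"{g}_{r}"] = rows[:, j]
        expr = pd.DataFrame(cols, index=ids)
        assignment, profiles = integrate.kmeans_clusters(expr, ids, k=5, seed=0)
        # each repeated pattern lands in its own cluster
        labels = assignment.loc[ids].to_numpy()
        pattern_of = np.repeat(np.arange(5), 6)
        assert pd.Series(labels).groupby(pattern_of).nunique().max() == 1
        assert len(set(labels)) == 5

    def test_deterministic_given_seed(self, default_dataset):
        degs = integrate.call_degs(default_dataset.expression, "SS")
        ids = sorted(degs.index[degs["is_deg"]])
        a1, _ = integrate.kmeans_clusters(default_dataset.expression, ids, seed=9)
        a2, _ = integrate.kmeans_clusters(default_dataset.expression, ids, seed=9)
        assert (a1 == a2).all()

    def test_beats_random_assignments(self, default_dataset):
        degs = integrate.call_degs(default_dataset.expression, "SS")
        ids = sorted(degs.index[degs["is_deg"]])
        expr = default_dataset.expression
        groups = pd.DataFrame({g: expr.loc[ids, [f"{g}_1", f"{g}_2"]].mean(axis=1)
                               for g in ("SS-C", "SS-S", "ST-C", "ST-S")})
        z = groups.sub(groups.mean(axis=1), axis=0).div(
            groups.std(axis=1, ddof=0).replace(0, 1.0), axis=0
        ).to_numpy()
        assignment, _ = integrate.kmeans_clusters(expr, ids, k=5, seed=9)

        def wss(labels):
            return sum(((z[labels == c] - z[labels == c].mean(axis=0)) ** 2).sum()
                       for c in np.unique(labels))

        fitted = wss(assignment.to_numpy())
        rng = np.random.default_rng(11)
        for _ in range(100):
            assert fitted <= wss(rng.integers(0, 5, size=len(z)))

    def test_too_few_rows_rejected(self):
        expr = _flat_expr(10, 20)
        with pytest.raises(ValueError):
            integrate.kmeans_clusters(expr, list(expr.index), k=5, seed=0)


class TestDmDegs:
    def _assoc(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "context", "direction",
                                           "feature_id", "kind", "region"])

    def _degs(self, ids, flags, directions=None):
        directions = directions or ["up"] * len(ids)
        return pd.DataFrame({"is_deg": flags, "direction": directions,
                             "log2fc": [1.0] * len(ids)},
                            index=pd.Index(ids, name="gene_id"))

    def test_single_link(self):
        degs = self._degs(["g1"], [True])
        assoc = self._assoc([("chr1", 0, "CG", "hyper", "g1", "gene", "gene_body")])
        links = integrate.identify_dmdegs(degs, assoc)
        assert list(links["feature_id"]) == ["g1"]

    def test_no_dmr_no_dmdeg(self):
        degs = self._degs(["g1"], [True])
        assoc = self._assoc([("chr1", 0, "CG", "hyper", "g2", "gene", "gene_body")])
        assert integrate.identify_dmdegs(degs, assoc).empty

    def test_non_deg_excluded(self):
        degs = self._degs(["g1"], [False])
        assoc = self._assoc([("chr1", 0, "CG", "hyper", "g1", "gene", "gene_body")])
        assert integrate.identify_dmdegs(degs, assoc).empty

    def test_equals_bruteforce_intersection(self, default_dataset, ss_dmr_calls):
        degs = integrate.call_degs(default_dataset.expression, "SS")
        dmrs = pd.concat([t[t["is_dmr"]] for t in ss_dmr_calls.values()],
                         ignore_index=True)
        assoc = annotate.associate_dmrs(dmrs, default_dataset.features)
        links = integrate.identify_dmdegs(degs, assoc)
        got = set(links["feature_id"])
        # oracle: brute-force set intersection of called DEGs and genes with
        # any associated DMR
        deg_set = set(degs.index[degs["is_deg"]])
        genes_with_dmr = set(assoc.loc[assoc["kind"] == "gene", "feature_id"])
        assert got == deg_set & genes_with_dmr

    def test_commutes_with_context_filtering(self, default_dataset, ss_dmr_calls):
        degs = integrate.call_degs(default_dataset.expression, "SS")
        dmrs = pd.concat([t[t["is_dmr"]] for t in ss_dmr_calls.values()],
                         ignore_index=True)
        assoc = annotate.associate_dmrs(dmrs, default_dataset.features)
        filtered_first = integrate.identify_dmdegs(degs, assoc[assoc["context"] == "CHH"])
        all_links = integrate.identify_dmdegs(degs, assoc)
        filtered_after = all_links[all_links["context"] == "CHH"]
        key = ["feature_id", "chrom", "start"]
        assert set(map(tuple, filtered_first[key].itertuples(index=False))) == set(
            map(tuple, filtered_after[key].itertuples(index=False))
        )


class TestDirectionCrosstab:
    def test_single_cell(self):
        links = pd.DataFrame({"context": ["CG"], "region": ["gene_body"],
                              "direction": ["hypo"], "deg_direction": ["up"]})
        tab = integrate.direction_crosstab(links)
        assert len(tab) == 1 and tab["n"].iloc[0] == 1

    def test_marginals_conserved(self, default_dataset, ss_dmr_calls):
        degs = integrate.call_degs(default_dataset.expression, "SS")
        dmrs = pd.concat([t[t["is_dmr"]] for t in ss_dmr_calls.values()],
                         ignore_index=True)
        assoc = annotate.associate_dmrs(dmrs, default_dataset.features)
        links = integrate.identify_dmdegs(degs, assoc)
        tab = integrate.direction_crosstab(links)
        assert tab["n"].sum() == len(links)

    def test_promoter_chh_hyper_up_cell_dominates(self, default_dataset, ss_dmr_calls):
        """The generator plants promoter CHH-hyper bins on up-DEGs, so that
        cell tops the (CHH, promoter) stratum."""
        degs = integrate.call_degs(default_dataset.expression, "SS")
        dmrs = pd.concat([t[t["is_dmr"]] for t in ss_dmr_calls.values()],
                         ignore_index=True)
        assoc = annotate.associate_dmrs(dmrs, default_dataset.features)
        links = integrate.identify_dmdegs(degs, assoc)
        tab = integrate.direction_crosstab(links)
        chh_prom = tab[(tab["context"] == "CHH") & (tab["region"] == "promoter")]
        top = chh_prom.sort_values("n", ascending=False).iloc[0]
        assert top["direction"] == "hyper" and top["deg_direction"] == "up"


class TestContextCorrelation:
    def test_identical_and_mirrored_vectors(self):
        rng = np.random.default_rng(21)
        # build two tiny reports whose per-gene diffs are exactly equal (CG vs
        # CHG) by giving both contexts the same counts
        rows_c, rows_s = [], []
        genes = pd.DataFrame({"id": [f"g{i}" for i in range(5)], "chrom": "chr1",
                              "start": np.arange(5) * 10_000 + 2000,
                              "end": np.arange(5) * 10_000 + 6000,
                              "strand": "+", "kind": "gene"})
        for i in range(5):
            base = 2000 + i * 10_000
            for j in range(10):
                m_c, m_s = int(rng.integers(0, 10)), int(rng.integers(0, 10))
                for ctx, tri in (("CG", "CGA"), ("CHG", "CAG")):
                    rows_c.append(("chr1", base + j * 100, "+", m_c, 10 - m_c, ctx, tri))
                    rows_s.append(("chr1", base + j * 100, "+", m_s, 10 - m_s, ctx, tri))
        cols = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]
        out = integrate.context_correlation(
            pd.DataFrame(rows_c, columns=cols), pd.DataFrame(rows_s, columns=cols),
            genes,
        )
        body = out[(out["compartment"] == "gene_body") & (out["context_a"] == "CG")
                   & (out["context_b"] == "CHG")]
        assert body["r"].iloc[0] == pytest.approx(1.0)

    def test_coupled_generator_gene_body_correlation(self):
        """With the shared latent factor at loading 0.8, gene-body CG and CHG
        level differences correlate (latent r = 0.8^2 = 0.64, so r > 0.5).

        The CHG gene-body methylated fraction is raised for this scenario:
        the latent shift acts on methylated sites, so the per-gene pooled
        difference scales with that fraction, and at the default 0.05 the
        binomial counting noise (~0.003 sd on a pooled gene-body level)
        would attenuate the observable correlation below the latent value.
        """
        cfg = SimulationConfig(
            n_chrom=1, chrom_length=400_000, control_chrom_length=60_000,
            n_genes=60, n_tes=20, n_dmrs_per_class=0, n_target_tes=0,
            n_hyper_only_tes=0, n_degs_per_genotype=0, couple_promoter_chh=False,
            gene_shift_sd=0.08, gene_shift_loading=0.8,
            p_gene_body={"CHG": (0.30, 0.75), "CHH": (0.005, 0.45)},
        )
        ds = simulate_dataset(cfg, seed=17)
        a = ds.reports["SS-C"]
        b = ds.reports["SS-S"]
        a, b = a[a["chrom"] != CONTROL_CHROM], b[b["chrom"] != CONTROL_CHROM]
        out = integrate.context_correlation(a, b, ds.genes)
        body = out[(out["compartment"] == "gene_body") & (out["context_a"] == "CG")
                   & (out["context_b"] == "CHG")]
        assert body["r"].iloc[0] > 0.5

    def test_zero_variance_flagged(self):
        cols = ["chrom", "pos", "strand", "n_meth", "n_unmeth", "context", "trinucleotide"]
        rows = [("chr1", 2000 + i * 3000 + j, "+", 5, 5, ctx, tri)
                for i in range(3) for j in range(5)
                for ctx, tri in (("CG", "CGA"), ("CHG", "CAG"))]
        genes = pd.DataFrame({"id": ["g0", "g1", "g2"], "chrom": "chr1",
                              "start": [2000, 5000, 8000], "end": [4000, 7000, 10000],
                              "strand": "+", "kind": "gene"})
        df = pd.DataFrame(rows, columns=cols)
        out = integrate.context_correlation(df, df.copy(), genes)
        assert out["r"].isna().all()  # all diffs are exactly zero
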