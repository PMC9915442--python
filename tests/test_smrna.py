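"""Small-RNA quantification: collapsing, densities, rank-sum against an
independent enumeration oracle, CWA split, TE-frequency enrichment and
base-frequency matrices."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methylscape import annotate, integrate, smrna
from methylscape.simulate import CONTROL_CHROM


def ranksum_oracle(x, y):
    """Independent oracle: enumerate every label assignment and compute the
    Mann-Whitney U from pairwise comparisons (ties count half)."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(idx):
        a = [pooled[i] for i in idx]
        b = [pooled[i] for i in range(len(pooled)) if i not in idx]
        return sum((ai > bi) + 0.5 * (ai == bi) for ai in a for bi in b)

    u_obs = u_stat(tuple(range(nx)))
    mu = nx * (len(pooled) - nx) / 2
    dev = abs(u_obs - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), nx):
        total += 1
        if abs(u_stat(idx) - mu) >= dev - 1e-9:
            hits += 1
    return hits / total


def _tes(rows):
    return pd.DataFrame(rows, columns=["id", "chrom", "start", "end", "strand", "kind"])


def _reads(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "sequence", "count", "strand"])
    df["length"] = df["end"] - df["start"]
    return df


class TestCollapse:
    def test_multiplicities(self):
        out = smrna.collapse_reads(["ACGT", "ACGT", "TTTT"])
        assert dict(zip(out["sequence"], out["count"])) == {"ACGT": 2, "TTTT": 1}

    def test_empty(self):
        assert smrna.collapse_reads([]).empty

    @given(st.lists(st.text(alphabet="ACGT", min_size=2, max_size=4), max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_counts_conserved(self, seqs):
        out = smrna.collapse_reads(seqs)
        assert out["count"].sum() == len(seqs)


class TestSizeDistribution:
    def test_all_24(self):
        reads = _reads([("chr1", 0, 24, "A" * 24, 3, "+")])
        dist = smrna.size_distribution(reads)
        assert dict(dist) == {24: 1.0}

    def test_fractions_sum_to_one(self, small_dataset):
        dist = smrna.size_distribution(small_dataset.smrnas["ST-S"])
        assert dist.sum() == pytest.approx(1.0, abs=1e-12)


class TestTeDensity:
    def test_counts_per_kb(self):
        tes = _tes([("t1", "chr1", 1000, 3000, "+", "TE")])
        reads = _reads([("chr1", 1500 + i, 1524 + i, "A" * 24, 1, "+") for i in range(4)])
        per_te, agg = smrna.te_smrna_density(reads, tes, 24)
        assert agg == pytest.approx(2.0)  # 4 reads over 2 kb

    def test_no_reads_zero(self):
        tes = _tes([("t1", "chr1", 1000, 3000, "+", "TE")])
        per_te, agg = smrna.te_smrna_density(_reads([]), tes, 24)
        assert agg == 0.0

    def test_midpoint_rule(self):
        tes = _tes([("t1", "chr1", 1000, 2000, "+", "TE")])
        # read straddles the start: midpoint 998 -> outside
        outside = _reads([("chr1", 986, 1010, "A" * 24, 1, "+")])
        _, agg = smrna.te_smrna_density(outside, tes, 24)
        assert agg == 0.0
        inside = _reads([("chr1", 990, 1014, "A" * 24, 1, "+")])
        _, agg = smrna.te_smrna_density(inside, tes, 24)
        assert agg > 0

    def test_empty_te_set_flagged(self):
        with pytest.raises(ValueError):
            smrna.te_smrna_density(_reads([]), _tes([]), 24)


class TestRankSum:
    def test_extreme_split(self):
        # A = {1,2,3} vs B = {4,5,6}: 2 of the 20 splits are as extreme
        assert smrna.rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_multisets(self):
        assert smrna.rank_sum_test([1, 2, 2], [1, 2, 2]) == pytest.approx(1.0)

    def test_matches_enumeration_oracle_small_groups(self):
        rng = np.random.default_rng(31)
        for _ in range(25):
            nx, ny = rng.integers(2, 7, size=2)
            x = rng.integers(0, 6, size=nx).astype(float)  # heavy ties
            y = rng.integers(0, 6, size=ny).astype(float)
            assert smrna.rank_sum_test(x, y) == pytest.approx(ranksum_oracle(x, y))

    def test_asymptotic_branch_reasonable(self):
        rng = np.random.default_rng(32)
        x = rng.normal(0, 1, 40)
        y = rng.normal(1.2, 1, 40)
        p = smrna.rank_sum_test(x, y)
        assert 0 < p < 0.01


class TestCwaSplit:
    def test_site_count_conservation(self, small_dataset, analysis_config):
        from methylscape import methylome
        rep = small_dataset.reports["SS-S"]
        calls = methylome.call_methylcytosines(
            rep[rep["chrom"] != CONTROL_CHROM], 0.005, analysis_config
        )
        tes = small_dataset.tes
        split = smrna.cwa_split_density({"all": tes}, {"SS-S": calls})
        by = split.set_index("stratum")["n_covered"]
        chh_total = calls[
            smrna._te_site_mask(calls, tes) & (calls["context"] == "CHH")
            & (calls["coverage"] >= 1)
        ]
        assert by["CHH:CWA"] + by["CHH:non-CWA"] == len(chh_total)

    def test_degenerate_stratum_flagged(self):
        calls = pd.DataFrame({
            "chrom": ["chr1"] * 3, "pos": [10, 20, 30], "strand": "+",
            "context": ["CHH"] * 3, "trinucleotide": ["CAA", "CTA", "CAA"],
            "coverage": 30, "is_mc": [True, False, True],
        })
        tes = _tes([("t1", "chr1", 0, 100, "+", "TE")])
        split = smrna.cwa_split_density({"g": tes}, {"s": calls})
        row = split.set_index("stratum")
        assert bool(row.loc["CHH:non-CWA", "undefined"])
        assert row.loc["CHH:CWA", "density"] == pytest.approx(2 / 3)

    def test_noncwa_density_higher_in_associated_stress(self, default_dataset,
                                                        analysis_config):
        """Targeted TEs get a non-CWA-biased CHH gain under stress, so the
        smRNA-associated group shows the higher non-CWA density."""
        from methylscape import methylome
        rep = default_dataset.reports["SS-S"]
        calls = methylome.call_methylcytosines(
            rep[rep["chrom"] != CONTROL_CHROM], 0.005, analysis_config
        )
        m = default_dataset.manifest
        tes = default_dataset.tes
        te_sets = {
            "associated": tes[tes["id"].isin(m.smrna_target_tes)],
            "not_associated": tes[tes["id"].isin(m.chh_hyper_only_tes)],
        }
        split = smrna.cwa_split_density(te_sets, {"SS-S": calls})
        dens = split.set_index(["group", "stratum"])["density"]
        assert dens[("associated", "CHH:non-CWA")] > dens[("not_associated", "CHH:non-CWA")]
        # within the associated group the DRM-pathway signature: non-CWA
        # density exceeds CWA density
        assert dens[("associated", "CHH:non-CWA")] > dens[("associated", "CHH:CWA")]


class TestTeFrequency:
    def _calls_all_mc(self, tes):
        rows = [("chr1", (te.start + te.end) // 2, "+", "CG", "CGA", 30, True)
                for te in tes.itertuples()]
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context",
                                           "trinucleotide", "coverage", "is_mc"])

    def test_identical_sets_null(self):
        genes = pd.DataFrame({"id": ["g1", "g2"], "chrom": "chr1",
                              "start": [0, 10_000], "end": [1000, 11_000],
                              "strand": "+", "kind": "gene"})
        tes = _tes([("t1", "chr1", 500, 800, "+", "TE")])
        calls = self._calls_all_mc(tes)
        freqs, pairs = smrna.te_frequency_enrichment(
            {"A": genes, "B": genes}, tes, calls
        )
        row = pairs.iloc[0]
        assert row["odds_ratio"] == pytest.approx(1.0) and row["p_value"] == pytest.approx(1.0)

    def test_full_vs_half(self):
        genes = pd.DataFrame({"id": [f"g{i}" for i in range(4)], "chrom": "chr1",
                              "start": np.arange(4) * 20_000,
                              "end": np.arange(4) * 20_000 + 1000,
                              "strand": "+", "kind": "gene"})
        tes = _tes([("t1", "chr1", 500, 800, "+", "TE"),
                    ("t2", "chr1", 20_500, 20_800, "+", "TE")])
        calls = self._calls_all_mc(tes)
        freqs, _ = smrna.te_frequency_enrichment(
            {"all": genes, "harboring": genes.iloc[:2]}, tes, calls
        )
        f = freqs.set_index("set")["frequency"]
        assert f["harboring"] == 1.0 and f["all"] == 0.5

    def test_dmdeg_enrichment_on_synthetic(self, default_dataset, ss_dmr_calls,
                                           ss_control_calls, analysis_config):
        """TE hosting is planted preferentially on DEG genes, so the dmDEG
        set shows a strongly enriched methylated-TE frequency."""
        degs = integrate.call_degs(default_dataset.expression, "SS", analysis_config)
        dmrs = pd.concat([t[t["is_dmr"]] for t in ss_dmr_calls.values()],
                         ignore_index=True)
        assoc = annotate.associate_dmrs(dmrs, default_dataset.features)
        dmdeg_ids = set(integrate.identify_dmdegs(degs, assoc)["feature_id"])
        genes = default_dataset.genes
        sets = {"PCGs": genes,
                "dmDEGs": genes[genes["id"].isin(dmdeg_ids)]}
        freqs, pairs = smrna.te_frequency_enrichment(
            sets, default_dataset.tes, ss_control_calls, config=analysis_config
        )
        f = freqs.set_index("set")["frequency"]
        assert f["dmDEGs"] / f["PCGs"] >= 3
        assert pairs.iloc[0]["p_value"] < 0.01


class TestBaseFrequency:
    def test_single_base(self):
        reads = _reads([("chr1", 0, 24, "A" * 24, 1, "+")])
        mat = smrna.base_frequency_matrix(reads, 24)
        assert (mat.loc["A"] == 1.0).all()

    def test_equal_mixture(self):
        reads = _reads([("chr1", 0, 24, "A" * 24, 2, "+"),
                        ("chr1", 30, 54, "C" * 24, 2, "+")])
        mat = smrna.base_frequency_matrix(reads, 24)
        assert np.allclose(mat.loc["A"], 0.5) and np.allclose(mat.loc["C"], 0.5)

    def test_columns_sum_to_one(self, small_dataset):
        reads = small_dataset.smrnas["SS-C"]
        reads24 = reads[reads["length"] == 24]
        mat = smrna.base_frequency_matrix(reads24, 24)
        assert np.allclose(mat.sum(axis=0), 1.0)

    def test_mixed_lengths_rejected(self):
        reads = _reads([("chr1", 0, 24, "A" * 24, 1, "+"),
                        ("chr1", 0, 21, "A" * 21, 1, "+")])
        with pytest.raises(ValueError):
            smrna.base_frequency_matrix(reads, 24)

    def test_3prime_ct_bias_on_target_reads(self, default_dataset):
        """24-nt reads over smRNA-target TEs carry the planted 3' C/T bias."""
        tes = default_dataset.tes
        targets = tes[tes["id"].isin(default_dataset.manifest.smrna_target_tes)]
        reads = default_dataset.smrnas["SS-S"]
        on_target = smrna.reads_on_tes(reads[reads["length"] == 24], targets)
        mat = smrna.base_frequency_matrix(on_target, 24)
        assert mat.loc["C", 24] + mat.loc["T", 24] >= 0.7
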