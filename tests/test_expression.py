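"""Normalization, trio thresholds, fragment expression, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chromoscope import effects as fx
from chromoscope import expression as xp
from chromoscope import rearrangements as rx


def sheet(rows):
    return pd.DataFrame(rows, columns=["sample", "individual", "cell_type", "replicate"])


TRIO = sheet(
    [
        ("p1", "patient", "NPC", "p1"),
        ("f1", "father", "NPC", "f1"),
        ("m1", "mother", "NPC", "m1"),
    ]
)


class TestSizeFactors:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            # identical samples
            ([[5, 5], [7, 7], [100, 100]], [1.0, 1.0]),
            # hand-computed median-of-ratios: geomeans (2*4)^.5, (4*8)^.5
            ([[2, 4], [4, 8]], [2 ** -0.5, 2 ** 0.5]),
            # all per-feature ratios are 1/2 and 2
            ([[1, 4], [4, 16], [9, 36]], [0.5, 2.0]),
            # single feature, three samples: geomean (2*4*8)^(1/3) = 4
            ([[2, 4, 8]], [0.5, 1.0, 2.0]),
        ],
    )
    def test_hand_computed_values(self, matrix, expected):
        counts = pd.DataFrame(matrix)
        np.testing.assert_allclose(xp.size_factors(counts).values, expected, rtol=1e-12)

    def test_no_all_positive_feature_is_an_error(self):
        counts = pd.DataFrame([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="filter"):
            xp.size_factors(counts)

    @settings(max_examples=25, deadline=None)
    @given(
        st.integers(min_value=0, max_value=2 ** 31 - 1),
        st.floats(min_value=0.1, max_value=10.0),
    )
    def test_scaling_equivariance(self, seed, c):
        """Scaling one sample by c scales its factor relative to the others by c.

        The geometric-mean reference includes the scaled sample, so the
        absolute factor moves by c^(1 - 1/m); factor ratios move by exactly
        c, and the normalized counts of every sample are unchanged.
        """
        rng = np.random.default_rng(seed)
        counts = pd.DataFrame(rng.poisson(50, size=(40, 4)).astype(float) + 1)
        m = counts.shape[1]
        base = xp.size_factors(counts)
        scaled = counts.copy()
        scaled[0] = scaled[0] * c
        factors = xp.size_factors(scaled)
        np.testing.assert_allclose(factors[0] / base[0], c ** (1 - 1 / m), rtol=1e-9)
        np.testing.assert_allclose(
            (factors[0] / factors[1]) / (base[0] / base[1]), c, rtol=1e-9
        )
        # normalized counts shift by the global constant c^(1/m) only:
        # relative expression between samples and features is unchanged
        np.testing.assert_allclose(
            scaled / factors, (counts / base) * c ** (1 / m), rtol=1e-9
        )

    def test_idempotence_on_separable_fixture(self):
        """Factors of an already-normalized matrix are all 1 (exact when the
        matrix is feature-baseline x sample-scale, so the factor geometric
        mean is 1; renormalizing general data yields equal factors at the
        old factors' geometric mean instead)."""
        rng = np.random.default_rng(3)
        base = rng.poisson(100, size=60).astype(float) + 1
        counts = pd.DataFrame(np.outer(base, [0.5, 0.8, 1.0, 1.6, 2.5]))
        norm = counts / xp.size_factors(counts)
        np.testing.assert_allclose(xp.size_factors(norm).values, 1.0, atol=1e-9)
        # general matrices: renormalized factors are equal across samples
        noisy = pd.DataFrame(rng.poisson(100, size=(60, 5)).astype(float) + 1)
        renorm = xp.size_factors(noisy / xp.size_factors(noisy))
        np.testing.assert_allclose(renorm.values, renorm.values[0], rtol=1e-12)

    def test_matches_independent_deseq_implementation(self):
        """Cross-check against pydeseq2's median-of-ratios estimator."""
        pydeseq2 = pytest.importorskip("pydeseq2.dds")
        rng = np.random.default_rng(11)
        counts = pd.DataFrame(
            rng.poisson([40, 90, 200, 350], size=(100, 4)),
            columns=[f"s{i}" for i in range(4)],
        )
        counts.index = [f"g{i}" for i in range(100)]
        meta = pd.DataFrame({"condition": ["A", "A", "B", "B"]}, index=counts.columns)
        dds = pydeseq2.DeseqDataSet(
            counts=counts.T, metadata=meta, design="~condition", quiet=True
        )
        dds.fit_size_factors()
        np.testing.assert_allclose(
            xp.size_factors(counts).values, dds.obs["size_factors"].values, rtol=1e-8
        )


class TestMergeGroups:
    def test_merging_sample_with_itself_is_identity(self):
        norm = pd.DataFrame({"a": [1.0, 2.0]}, index=["g1", "g2"])
        s = sheet([("a", "patient", "NPC", "r1")])
        merged, _ = xp.merge_groups(norm, s)
        np.testing.assert_allclose(merged.iloc[:, 0], norm["a"])

    def test_two_members_average(self):
        norm = pd.DataFrame({"a": [10.0], "b": [30.0]})
        s = sheet([("a", "patient", "NPC", "r1"), ("b", "patient", "NPC", "r1")])
        merged, groups = xp.merge_groups(norm, s)
        assert merged.shape[1] == 1
        assert merged.iloc[0, 0] == 20.0
        assert groups["members"].iloc[0] == "a,b"

    def test_npc_days_merge_per_line(self, fig1_counts):
        gene_counts, _, samples = fig1_counts
        merged, groups = xp.merge_groups(gene_counts / 1.0, samples)
        # 3 blood + 5 iPSC lines + 5 NPC lines = 13 groups
        assert merged.shape[1] == 13
        npc = groups[groups["cell_type"] == "NPC"]
        assert all("," in m for m in npc["members"])  # day 7 + day 10 merged


class TestTrioCompare:
    def compare(self, patient, father, mother, **kw):
        norm = pd.DataFrame({"p1": [patient], "f1": [father], "m1": [mother]}, index=["g"])
        return xp.trio_compare(norm, TRIO, **kw).iloc[0]

    def test_threefold_up(self):
        rec = self.compare(30.0, 10.0, 10.0, pseudocount=0.0)
        assert rec["log2_fc"] == pytest.approx(np.log2(3), abs=1e-12)
        assert rec["effect"] == "up"

    def test_more_than_ten_rule_is_strict(self):
        rec = self.compare(9.0, 9.0, 9.0)
        assert rec["effect"] == "not_expressed"
        rec10 = self.compare(10.0, 10.0, 10.0)
        assert rec10["effect"] == "not_expressed"  # "more than ten" excludes 10
        rec11 = self.compare(10.5, 10.5, 10.5)
        assert rec11["effect"] == "none"

    def test_equal_expression_no_effect(self):
        rec = self.compare(100.0, 100.0, 100.0)
        assert rec["log2_fc"] == 0.0 and rec["effect"] == "none"

    def test_parent_mean_and_per_parent_columns(self):
        rec = self.compare(80.0, 20.0, 60.0, pseudocount=0.0)
        assert rec["norm_mean_parents"] == 40.0
        assert rec["log2_fc"] == pytest.approx(1.0)
        assert rec["log2_fc_vs_father"] == pytest.approx(2.0)
        assert rec["log2_fc_vs_mother"] == pytest.approx(np.log2(80 / 60))

    def test_log2fc_invariant_to_library_scaling(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.poisson(200, size=(50, 3)) + 1.0, columns=["p1", "f1", "m1"]
        )
        a = xp.trio_compare(counts / xp.size_factors(counts), TRIO, pseudocount=0.0)
        b = xp.trio_compare(
            (counts * 7.0) / xp.size_factors(counts * 7.0), TRIO, pseudocount=0.0
        )
        np.testing.assert_allclose(a["log2_fc"], b["log2_fc"], atol=1e-12)

    def test_npc_only_positional_pattern(self, fig1_comparisons):
        """The planted NPC-only gene is up in NPC and silent in blood."""
        comp, _ = fig1_comparisons
        tw = comp[comp["feature"] == "TWIST1L"].set_index("cell_type")["effect"]
        assert tw["NPC"] == "up"
        assert tw["blood"] == "not_expressed"
        assert tw["iPSC"] == "none"


class TestFragmentExpression:
    def fragments(self):
        j = rx.BreakendJunction("j1", "chr1", 100, "left", "chr1", 200, "right")
        rset = rx.assemble_derivatives([j], chrom_lengths={"chr1": 1000})
        g = fx.GeneModel(
            "g", "g", "chr1", 40, 160, "+", [(50, 70), (80, 95), (120, 140)]
        )
        return fx.fragment_gene(g, rset)

    def test_all_exons_one_fragment_equals_gene(self):
        frags = [f for f in self.fragments() if f.part == "5prime"]
        counts = pd.DataFrame(
            {"p1": [10, 20, 5], "f1": [8, 16, 4], "m1": [12, 24, 6]},
            index=["g|e0", "g|e1", "g|e2"],
        )
        out = xp.fragment_counts(counts, frags)
        np.testing.assert_allclose(out.loc["g|5prime"], counts.iloc[:2].sum())

    def test_fragment_sum_equals_gene_total_without_splits(self):
        frags = self.fragments()
        counts = pd.DataFrame(
            {"p1": [10, 20, 5], "f1": [8, 16, 4], "m1": [12, 24, 6]},
            index=["g|e0", "g|e1", "g|e2"],
        )
        out = xp.fragment_counts(counts, frags)
        np.testing.assert_allclose(out.sum(axis=0), counts.sum(axis=0))

    def test_opposite_fragment_effects_recovered(self, fig1_counts, fig1_effects):
        """Planted 5' up / 3' down on the FOXP1L-like gene come back with
        opposite signs, and the 3' dosage loss is near its planted 50%."""
        _, exon_counts, samples = fig1_counts
        frags = [f for e in fig1_effects for f in e.fragments]
        comp = xp.fragment_expression(exon_counts, frags, samples)
        fox = comp[comp["gene_id"] == "FOXP1L"]
        up = fox[fox["part"] == "5prime"]["log2_fc"]
        down = fox[fox["part"] == "3prime"]["log2_fc"]
        assert (up > 0).all() and (down < 0).all()
        ratio = (
            fox[fox["part"] == "3prime"]["norm_mean_patient"]
            / fox[fox["part"] == "3prime"]["norm_mean_parents"]
        ).mean()
        assert (1 - ratio) * 100 == pytest.approx(50, abs=10)


class TestVarianceTopClustering:
    def test_identical_samples_merge_at_zero(self):
        norm = pd.DataFrame({"a": [1.0, 5.0, 9.0], "b": [1.0, 5.0, 9.0]})
        res = xp.variance_top_clustering(norm, n=3)
        assert res.linkage[0, 2] == 0.0

    def test_single_feature_no_error(self):
        norm = pd.DataFrame({"a": [1.0, 5.0], "b": [2.0, 50.0], "c": [1.5, 7.0]})
        res = xp.variance_top_clustering(norm, n=1)
        assert res.features == [1] or len(res.features) == 1

    def test_n_larger_than_features_warns_and_uses_all(self):
        norm = pd.DataFrame(np.arange(12.0).reshape(4, 3))
        with pytest.warns(UserWarning, match="using all"):
            res = xp.variance_top_clustering(norm, n=500)
        assert len(res.features) == 4

    def test_samples_cluster_by_cell_type(self, fig1_counts):
        """iPSC and NPC samples separate cleanly, and day 7/10 NPC profiles
        are so alike that every cross-day NPC pair merges below any
        iPSC-to-NPC merge (the rationale for merging the days downstream)."""
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform

        gene_counts, _, samples = fig1_counts
        norm = gene_counts / xp.size_factors(gene_counts)
        sub = samples[samples["cell_type"].isin(["iPSC", "NPC"])]
        res = xp.variance_top_clustering(norm[sub["sample"]], n=400)
        by_ct = sub.set_index("sample")["cell_type"]
        labels = {ct: set(res.labels[by_ct[by_ct == ct].index]) for ct in ("iPSC", "NPC")}
        assert labels["iPSC"].isdisjoint(labels["NPC"])
        coph = squareform(cophenet(res.linkage))
        cols = list(norm[sub["sample"]].columns)
        npc = [cols.index(s) for s in by_ct[by_ct == "NPC"].index]
        ipsc = [cols.index(s) for s in by_ct[by_ct == "iPSC"].index]
        within_npc = coph[np.ix_(npc, npc)].max()
        across = coph[np.ix_(ipsc, npc)].min()
        assert within_npc < across
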